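#!/usr/bin/env python
"""Sizer-or-timer discrimination from growth/accumulation tracks.

A sizer's nodal signal stops accumulating when growth stops and its
accumulation rate tracks the growth rate across cells; a timer's signal
keeps rising regardless. The Monte-Carlo robustness test asks how often
the measured positive growth/accumulation correlation would vanish if
every point were re-drawn within its measurement errors.
"""

import json
from pathlib import Path

from nodescale.pipeline import run_sizer_timer_test

SEED = 20246
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    sizer = run_sizer_timer_test({"seed": SEED, "n_reps": 1_000_000})
    timer = run_sizer_timer_test({"seed": SEED, "n_reps": 200_000,
                                  "division_rule": "timer"})
    report = {"sizer_truth": sizer, "timer_truth": timer}
    (OUT / "sizer_timer.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"sizer-coupled tracks: slope {sizer['growing_slope']:.2f}, "
          f"P(no positive correlation) = {sizer['p_no_positive_correlation']:.2e}, "
          f"arrested accumulation {sizer['arrested_mean_accumulation_rate']:.2f} "
          f"vs growing {sizer['growing_mean_accumulation_rate']:.2f} "
          f"-> verdict: {sizer['verdict']}")
    print(f"timer-coupled tracks: arrested cells still accumulate at "
          f"{timer['arrested_mean_accumulation_rate']:.2f} "
          f"-> verdict: {timer['verdict']}")
    print("wrote results/sizer_timer.json")


if __name__ == "__main__":
    main()
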