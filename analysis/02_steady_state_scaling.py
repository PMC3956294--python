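#!/usr/bin/env python
"""Evaluate the steady-state models of nodal accumulation across cell
lengths and quantify their size-scaling.

Model I (uniform cortical intermediate) and Model II (cytoplasmic
modification) both predict nodal density rising roughly in proportion to
membrane area; the direct-to-node null model predicts no scaling at all.
"""

from pathlib import Path

import pandas as pd
import numpy as np

from nodescale.geometry import spherocylinder
from nodescale.steady import (
    ModificationModelParams,
    UniformModelParams,
    model1_closed_form,
    model1_direct_null,
    model2_closed_form,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    p1 = UniformModelParams(cyt_slope=0.0)
    p2 = ModificationModelParams()
    rows = []
    for L in np.linspace(7.0, 14.0, 29):
        g = spherocylinder(L, 1.5, 3.0)
        rows.append({
            "L_um": L,
            "A_cor_um2": g.A_cor,
            "rho_nod_model1": model1_closed_form(p1, g).rho_nod,
            "rho_nod_model2": model2_closed_form(p2, g).rho_nod,
            "rho_nod_null": model1_direct_null(p1, g).rho_nod,
            "rho_cor_model1": model1_closed_form(p1, g).rho_cor,
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "steady_state_scaling.csv", index=False)
    r1 = df["rho_nod_model1"].iloc[-1] / df["rho_nod_model1"].iloc[0]
    r2 = df["rho_nod_model2"].iloc[-1] / df["rho_nod_model2"].iloc[0]
    rn = df["rho_nod_null"].iloc[-1] / df["rho_nod_null"].iloc[0]
    print("nodal density ratio, L = 14 vs 7 um:")
    print(f"  Model I (uniform cortical pool): {r1:.3f}  (~twofold)")
    print(f"  Model II (modification):         {r2:.3f}")
    print(f"  direct-to-node null:             {rn:.3f}  (no size sensing)")
    print("wrote results/steady_state_scaling.csv")


if __name__ == "__main__":
    main()
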