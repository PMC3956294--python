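"""Config-driven figure-level analyses wiring generators, models and stats.

Three end-to-end analyses, each reproducible from a YAML config with an
explicit seed:

* scaling analysis — generate a population, attach model-derived medial
  profiles, measure band intensities, bin by length and fit the one-free-
  prefactor scaling curve;
* division-size analysis — generate differently shaped strains dividing
  by a common rule, compare cross-strain length/area/volume distributions
  by Jensen-Shannon distance;
* sizer-vs-timer test — compare growth-arrested and growing tracks and
  run the Monte-Carlo correlation-robustness test.

Reports are plain dicts (JSON-serializable) embedding the config hash and
package version; writing to disk is the caller's or the CLI's job.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import spherocylinder
from .steady import (
    ModificationModelParams,
    UniformModelParams,
    fit_scaling_prefactor,
    model1_closed_form,
    model1_direct_null,
    model2_closed_form,
)
from .profiles import medial_band_intensity
from .stats import (
    correlation_robustness,
    histogram_pair,
    js_distance,
    linear_fit,
    bin_by_length,
)
from .synthetic import (
    StrainSpec,
    SyntheticCell,
    gen_cdr2_profiles,
    gen_growth_tracks,
    gen_population,
)

__all__ = [
    "ConfigError",
    "load_config",
    "validate_config",
    "config_hash",
    "run_scaling_analysis",
    "run_division_size_analysis",
    "run_sizer_timer_test",
]


class ConfigError(ValueError):
    """Run configuration is structurally invalid."""


_DEFAULTS: dict = {
    "seed": None,                 # mandatory, no default
    "model": "model1",
    "n_cells": 100,
    "noise": 0.05,
    "bin_width": 1.0,
    "L_range": [7.0, 14.0],
    "R": 1.5,
    "w_nod": 3.0,
    "strains": [
        {"name": "wt", "R_mean": 1.5},
        {"name": "fat", "R_mean": 1.75},
        {"name": "thin", "R_mean": 1.3},
    ],
    "division_rule": "sizer-area",
    "threshold": 150.0,
    "threshold_cv": 0.05,
    "n_tracks": 21,
    "n_reps": 100_000,
}


def load_config(path) -> dict:
    """Load and validate a YAML run config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    """Structural validation; fills defaults, requires an explicit seed."""
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **cfg}
    if merged["seed"] is None:
        raise ConfigError("config must set an explicit integer seed")
    if not isinstance(merged["seed"], (int, np.integer)):
        raise ConfigError(f"seed must be an integer, got {merged['seed']!r}")
    if merged["model"] not in ("model1", "model2", "direct-null"):
        raise ConfigError(f"unknown model {merged['model']!r}")
    for key in ("n_cells", "n_tracks", "n_reps"):
        if not isinstance(merged[key], (int, np.integer)) or merged[key] < 1:
            raise ConfigError(f"{key} must be a positive integer")
    for key in ("noise", "bin_width", "R", "w_nod", "threshold", "threshold_cv"):
        if not isinstance(merged[key], (int, float)) or merged[key] < 0:
            raise ConfigError(f"{key} must be a non-negative number")
    if (not isinstance(merged["L_range"], (list, tuple))
            or len(merged["L_range"]) != 2
            or merged["L_range"][0] >= merged["L_range"][1]):
        raise ConfigError("L_range must be [lo, hi] with lo < hi")
    if not isinstance(merged["strains"], list) or len(merged["strains"]) < 1:
        raise ConfigError("strains must be a non-empty list of mappings")
    return merged


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _report_header(cfg: dict) -> dict:
    return {"config_hash": config_hash(cfg), "package_version": __version__}


def _solver(model: str):
    if model == "model1":
        return model1_closed_form, UniformModelParams()
    if model == "model2":
        return model2_closed_form, ModificationModelParams()
    return model1_direct_null, UniformModelParams()


def run_scaling_analysis(cfg: dict) -> dict:
    """Nodal-density-vs-length scaling on a synthetic population.

    Generates cells uniformly covering the length range, attaches medial
    cdr2p profiles computed from the configured steady-state model,
    measures 3-um medial band intensities, bins them by length and fits
    the model's single free prefactor.
    """
    cfg = validate_config(cfg)
    rng = np.random.default_rng(cfg["seed"])
    solve, params = _solver(cfg["model"])
    R, w_nod = cfg["R"], cfg["w_nod"]
    lengths = rng.uniform(*cfg["L_range"], size=cfg["n_cells"])
    rows = []
    for i, L in enumerate(lengths):
        geom = spherocylinder(L, R, min(w_nod, L - 2 * R))
        ss = solve(params, geom)
        cell = SyntheticCell(id=f"scal-{i:04d}", L=float(L), R=R)
        profs = gen_cdr2_profiles(
            cell, rho_cor=ss.rho_cor, rho_nod=ss.rho_nod,
            noise=cfg["noise"], seed=int(rng.integers(2**31)),
        )
        total, _ = medial_band_intensity(profs["axial"], width=min(3.0, L))
        rows.append({"length_um": float(L), "band_intensity": total,
                     "rho_nod_true": ss.rho_nod})
    df = pd.DataFrame(rows)
    binned = bin_by_length(df, value="band_intensity", bin_width=cfg["bin_width"])

    def predicted_signal(L: float) -> float:
        """Noise-free forward model of the measured band intensity."""
        geom = spherocylinder(L, R, min(w_nod, L - 2 * R))
        ss = solve(params, geom)
        twin = SyntheticCell(id="twin", L=float(L), R=R)
        profs = gen_cdr2_profiles(twin, rho_cor=ss.rho_cor,
                                  rho_nod=ss.rho_nod, noise=0.0, seed=0)
        return medial_band_intensity(profs["axial"], width=min(3.0, L))[0]

    fit = fit_scaling_prefactor(
        df["length_um"], df["band_intensity"], model=cfg["model"],
        R=R, w_nod=w_nod, curve=predicted_signal,
    )
    trend = linear_fit(df["length_um"], df["band_intensity"])
    return {
        **_report_header(cfg),
        "n_cells": int(len(df)),
        "model": cfg["model"],
        "prefactor": fit["prefactor"],
        "r2": fit["r2"],
        "trend_slope": trend["slope"],
        "cells": df.to_dict(orient="list"),
        "binned": binned.to_dict(orient="list"),
    }


def run_division_size_analysis(cfg: dict) -> dict:
    """Division-size distributions across strains of different girth.

    For each configured strain, generate a population dividing by the
    configured rule, then compare the cross-strain distributions of
    length, area and volume by pairwise Jensen-Shannon distance. Under an
    area sizer, the area distances come out smallest: differently shaped
    cells divide at the same surface area but different lengths and
    volumes. Means are also reported normalized to the fat (widest)
    strain.
    """
    cfg = validate_config(cfg)
    rng = np.random.default_rng(cfg["seed"])
    pops = {}
    for spec_kwargs in cfg["strains"]:
        spec = StrainSpec(
            division_rule=cfg["division_rule"], threshold=cfg["threshold"],
            threshold_cv=cfg["threshold_cv"], **spec_kwargs,
        )
        cells = gen_population(spec, cfg["n_cells"], seed=int(rng.integers(2**31)))
        pops[spec.name] = pd.DataFrame({
            "length_um": [c.L for c in cells],
            "area_um2": [c.geometry.A_cor for c in cells],
            "volume_um3": [c.geometry.V for c in cells],
        })
    names = list(pops)
    quantities = {"length": "length_um", "area": "area_um2", "volume": "volume_um3"}
    js = {q: {} for q in quantities}
    for q, col in quantities.items():
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                pair = histogram_pair(pops[a][col], pops[b][col], bins=30)
                js[q][f"{a}|{b}"] = js_distance(pair)
    mean_js = {q: float(np.mean(list(v.values()))) for q, v in js.items()}
    ref = "fat" if "fat" in pops else names[0]
    means = {
        name: {q: float(pops[name][col].mean()) for q, col in quantities.items()}
        for name in names
    }
    normalized = {
        name: {q: means[name][q] / means[ref][q] for q in quantities}
        for name in names
    }
    return {
        **_report_header(cfg),
        "division_rule": cfg["division_rule"],
        "strain_means": means,
        "normalized_to": ref,
        "normalized_means": normalized,
        "js_distance": js,
        "mean_js_distance": mean_js,
        "most_conserved": min(mean_js, key=mean_js.get),
    }


def run_sizer_timer_test(cfg: dict) -> dict:
    """Sizer-vs-timer discrimination on growth tracks.

    A sizer stops accumulating when growth stops; a timer keeps going.
    Compares accumulation in growth-arrested vs growing synthetic tracks
    and runs the Monte-Carlo robustness test on the growing set's
    growth-rate/accumulation-rate correlation.
    """
    cfg = validate_config(cfg)
    rng = np.random.default_rng(cfg["seed"])
    coupling = "timer" if cfg["division_rule"] == "timer" else "sizer"
    growing = gen_growth_tracks(
        n=cfg["n_tracks"], coupling=coupling, seed=int(rng.integers(2**31)),
    )
    # growth arrest: growth rate pinned at ~0
    arrested = gen_growth_tracks(
        n=cfg["n_tracks"], coupling=coupling, seed=int(rng.integers(2**31)),
        rate_mean=1e-3, rate_sd=0.0,
    )
    arrested_acc = float(np.mean([p.accumulation_rate for p in arrested]))
    growing_acc = float(np.mean([p.accumulation_rate for p in growing]))
    fit = linear_fit(
        [p.growth_rate for p in growing],
        [p.accumulation_rate for p in growing],
    )
    prob = correlation_robustness(
        growing, n_reps=cfg["n_reps"], seed=int(rng.integers(2**31)),
    )
    return {
        **_report_header(cfg),
        "coupling": coupling,
        "arrested_mean_accumulation_rate": arrested_acc,
        "growing_mean_accumulation_rate": growing_acc,
        "growing_slope": fit["slope"],
        "growing_r2": fit["r2"],
        "p_no_positive_correlation": prob,
        "verdict": "sizer" if arrested_acc < 0.2 * growing_acc else "timer",
    }
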