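"""Statistical procedures: distribution comparison, robustness tests, fits.

The Jensen-Shannon distance (base-2 logarithms, so it is bounded on
[0, 1]) quantifies how similar the division-size distributions of
differently shaped strains are for each candidate size variable (length,
area, volume): the variable the cell actually senses should show the
smallest cross-strain distances. The Monte-Carlo correlation-robustness
test asks how often a measured positive slope between growth rate and
nodal accumulation rate would disappear if every data point were
re-drawn within its own measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import linregress

__all__ = [
    "DistributionPair",
    "RatePair",
    "StatsError",
    "js_distance",
    "histogram_pair",
    "correlation_robustness",
    "linear_fit",
    "bin_by_length",
    "select_matched_subset",
]


class StatsError(ValueError):
    """Invalid input to a statistical procedure."""


@dataclass(frozen=True)
class DistributionPair:
    """Two probability mass functions on shared bin edges."""

    edges: np.ndarray
    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        p = np.asarray(self.p, dtype=float)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)
        if p.shape != q.shape or p.ndim != 1:
            raise StatsError("p and q must be 1-D arrays of equal length")
        if edges.size != p.size + 1:
            raise StatsError("need len(edges) == len(p) + 1")
        if np.any(p < 0) or np.any(q < 0):
            raise StatsError("probability masses must be non-negative")


@dataclass(frozen=True)
class RatePair:
    """A growth-rate / accumulation-rate measurement with per-cell errors."""

    growth_rate: float          # um/h
    growth_err: float
    accumulation_rate: float    # a.u./h
    accumulation_err: float

    def __post_init__(self) -> None:
        if self.growth_err < 0 or self.accumulation_err < 0:
            raise StatsError("measurement errors must be non-negative")


def js_distance(d: DistributionPair) -> float:
    """Jensen-Shannon distance sqrt(JSD(p, q)) with base-2 logarithms.

    Exactly 0 for identical distributions and exactly 1 for distributions
    with no shared support. Inputs must already be normalized; masses that
    do not sum to one are an error, never silently renormalized.
    """
    for name, v in (("p", d.p), ("q", d.q)):
        s = float(np.sum(v))
        if abs(s - 1.0) > 1e-9:
            raise StatsError(f"{name} must sum to 1 (got {s!r}); renormalize explicitly")
    val = float(jensenshannon(d.p, d.q, base=2.0))
    if np.isnan(val):  # scipy returns nan for p == q in some versions
        val = 0.0
    return min(val, 1.0)


def histogram_pair(a, b, bins=None) -> DistributionPair:
    """Bin two continuous samples onto shared edges as a DistributionPair.

    Edges default to Freedman-Diaconis on the pooled sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if bins is None:
        edges = np.histogram_bin_edges(pooled, bins="fd")
    else:
        edges = np.histogram_bin_edges(pooled, bins=bins)
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    return DistributionPair(edges=edges, p=p / p.sum(), q=q / q.sum())


def correlation_robustness(
    pairs, n_reps: int = 10**6, seed: int | None = None, chunk: int = 10**5
) -> float:
    """Probability that a positive growth/accumulation slope is absent.

    For each replicate, every pair is re-drawn from Gaussians centered on
    its measured values with the measured errors as widths (both members
    perturbed), an ordinary least-squares slope is fit, and the returned
    value is the fraction of replicates with slope <= 0. Fully vectorized
    in chunks; the same seed always gives the identical estimate.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise StatsError(f"need >= 3 rate pairs, got {len(pairs)}")
    gx = np.array([p.growth_rate for p in pairs])
    gex = np.array([p.growth_err for p in pairs])
    ay = np.array([p.accumulation_rate for p in pairs])
    aey = np.array([p.accumulation_err for p in pairs])
    if not (np.all(np.isfinite(gex)) and np.all(np.isfinite(aey))):
        raise StatsError("measurement errors must be finite")
    if np.var(gx) == 0:
        raise StatsError("zero variance in growth rate across pairs")
    rng = np.random.default_rng(seed)
    n = gx.size
    hits = 0
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        x = gx + gex * rng.standard_normal((m, n))
        y = ay + aey * rng.standard_normal((m, n))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.sum(xc * xc, axis=1)
        slope = np.where(denom > 0, np.sum(xc * yc, axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
        hits += int(np.count_nonzero(slope <= 0))
        done += m
    return hits / n_reps


def linear_fit(x, y) -> dict:
    """Ordinary least-squares line fit.

    Returns ``slope``, ``intercept``, ``r2`` (1 - SS_res/SS_tot) and
    ``slope_err`` (standard error of the slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError(f"need >= 3 matched points, got {x.size}")
    if np.var(x) == 0:
        raise StatsError("zero variance in x")
    res = linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "slope_err": float(res.stderr),
    }


def bin_by_length(
    records: pd.DataFrame, value: str, length: str = "length_um",
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Per-length-bin mean, SD, SEM and count of a measured value.

    Bins are half-open [k*w, (k+1)*w); empty bins are omitted. Mirrors the
    1-um length binning used for nodal-density scaling plots.
    """
    df = records[[length, value]].dropna()
    idx = np.floor(df[length].to_numpy() / bin_width).astype(int)
    out = (
        df.assign(_bin=idx)
        .groupby("_bin")[value]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out["bin_left"] = out["_bin"] * bin_width
    out["bin_right"] = (out["_bin"] + 1) * bin_width
    return out[["bin_left", "bin_right", "mean", "sd", "sem", "n"]]


def select_matched_subset(
    cells: pd.DataFrame, quantity: str, strain: str = "strain",
    f_range: tuple[float, float] = (0.10, 0.20), f_step: float = 0.002,
    match_tol: float = 0.01,
) -> dict:
    """Select per-strain cell subsets matched on mean area or volume.

    For each strain, cells within ``mean ± f*mean`` of that strain's own
    mean of ``quantity`` are candidates, with the fraction f scanned over
    ``f_range`` independently per strain and chosen so the subset mean
    lands closest to the cross-strain target (the grand mean of strain
    means). Succeeds when all subset means agree with the target within
    ``match_tol`` (1% by default); otherwise the best achievable selection
    is returned with ``matched=False``.

    Returns a dict with ``subset`` (DataFrame), ``achieved_f`` and
    ``subset_means`` per strain, ``matched`` flag and ``target``.
    """
    strains = cells[strain].unique()
    if strains.size < 2:
        raise StatsError(f"need >= 2 strains, got {strains.size}")
    target = float(np.mean([cells.loc[cells[strain] == s, quantity].mean()
                            for s in strains]))
    fs = np.arange(f_range[0], f_range[1] + f_step / 2, f_step)
    chosen_f, means, parts = {}, {}, []
    for s in strains:
        grp = cells[cells[strain] == s]
        center = float(grp[quantity].mean())
        best = None
        for f in fs:
            sel = grp[np.abs(grp[quantity] - center) <= f * center]
            if len(sel) == 0:
                continue
            m = float(sel[quantity].mean())
            if best is None or abs(m - target) < abs(best[1] - target):
                best = (float(f), m, sel)
        if best is None:  # degenerate strain: keep everything
            best = (float(fs[-1]), center, grp)
        chosen_f[s], means[s], sel = best
        parts.append(sel)
    matched = all(abs(m - target) <= match_tol * target for m in means.values())
    return {
        "subset": pd.concat(parts, ignore_index=True),
        "achieved_f": chosen_f,
        "subset_means": means,
        "subset_sizes": {s: int((parts[i][strain] == s).sum()) for i, s in enumerate(strains)},
        "matched": matched,
        "target": target,
    }
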