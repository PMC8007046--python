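"""Statistics over per-seeding-event divergence series.

The divergence series orders seeding events by seed index (equivalently
by the primary size fraction at dissemination) and records, per event,
the measured and tree-based divergence quantities. This module provides
the running summaries, regressions, heteroscedasticity testing,
zigzag/valley segmentation of the B_m series, and the permutation test
associating subclonal expansions with B_m drops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .sim import TumorState


def running_stats(series: pd.DataFrame, window: int = 20,
                  y_col: str = "B_m") -> pd.DataFrame:
    """Centered moving mean and std over seed-index order (edges use
    truncated windows)."""
    if window < 2:
        raise ValueError("window must be >= 2")
    if len(series) < 2:
        raise ValueError("series too short")
    y = series[y_col]
    roll = y.rolling(window, center=True, min_periods=1)
    out = series.copy()
    out[f"{y_col}_runmean"] = roll.mean().to_numpy()
    out[f"{y_col}_runstd"] = roll.std(ddof=0).to_numpy()
    return out


def variance_explained(series: pd.DataFrame, x_col: str, y_col: str):
    """OLS of y on x: (R^2, slope, (slope CI low, high)) with a 95% CI."""
    import statsmodels.api as sm

    if len(series) < 10:
        raise ValueError("need >= 10 points")
    x = series[x_col].to_numpy(dtype=float)
    y = series[y_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)[1]
    return float(fit.rsquared), float(fit.params[1]), (float(ci[0]), float(ci[1]))


def heteroscedasticity_test(series: pd.DataFrame, y_col: str = "B_m",
                            x_col: Optional[str] = None) -> float:
    """White's test p-value for heteroscedasticity of y along the seeding
    order (auxiliary regression of squared OLS residuals on the regressor
    and its square)."""
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_white

    if len(series) < 20:
        raise ValueError("need >= 20 points")
    y = series[y_col].to_numpy(dtype=float)
    x = (series[x_col].to_numpy(dtype=float) if x_col is not None
         else np.arange(len(y), dtype=float))
    if np.ptp(x) == 0:
        raise ValueError("degenerate design matrix")
    X = sm.add_constant(x)
    resid = sm.OLS(y, X).fit().resid
    _, p_value, _, _ = het_white(resid, X)
    return float(p_value)


# ---------------------------------------------------------------------------
# subclonal expansions
# ---------------------------------------------------------------------------

@dataclass
class ExpansionEvent:
    """A cell whose descendants reach >= ``threshold`` of the final
    sampled population (a subclonal expansion founder)."""

    cell_id: int
    t_birth: float
    size_fraction_at_birth: float   # primary size at birth / final size
    sampled_fraction: float         # of the final sampled population


def detect_expansions(tumor: TumorState, sampled_cells: np.ndarray,
                      threshold: float = 0.05) -> list[ExpansionEvent]:
    """All cells whose sampled-descendant fraction reaches ``threshold``.

    Nested qualifying ancestors are each reported as separate events."""
    sampled_cells = np.asarray(sampled_cells, dtype=np.int64)
    if sampled_cells.size == 0:
        raise ValueError("empty sample")
    n = tumor.n_cells
    w = np.zeros(n, dtype=np.int64)
    w[np.unique(sampled_cells)] = 1
    total = int(w.sum())
    counts = K.subtree_counts(tumor.parent[:n], w)
    final_size = tumor.n_alive
    hits = np.flatnonzero(counts >= threshold * total)
    return [
        ExpansionEvent(
            cell_id=int(c),
            t_birth=float(tumor.t_birth[c]),
            size_fraction_at_birth=float(tumor.size_at_birth[c] / final_size),
            sampled_fraction=float(counts[c] / total),
        )
        for c in hits
    ]


# ---------------------------------------------------------------------------
# zigzag / valley segmentation
# ---------------------------------------------------------------------------

@dataclass
class Phase:
    start: int        # index into the series
    end: int          # inclusive
    direction: str    # "increasing" | "decreasing" | "flat"


def zigzag_partition(values: Sequence[float], change_pct: float = 0.10
                     ) -> list[Phase]:
    """Alternating increasing/decreasing phases of a series, keeping only
    reversals that exceed ``change_pct`` (relative to the preceding
    extremum, or absolute where the extremum is 0)."""
    y = np.asarray(values, dtype=float)
    n = y.size
    if n == 0:
        return []
    if np.ptp(y) == 0:
        return [Phase(0, n - 1, "flat")]

    def moved(a, b):
        ref = abs(a)
        return abs(b - a) > change_pct * (ref if ref > 0 else 1.0)

    pivots = [0]
    direction = 0  # unknown
    ext_idx = 0
    for i in range(1, n):
        if direction == 0:
            if moved(y[ext_idx], y[i]):
                direction = 1 if y[i] > y[ext_idx] else -1
                ext_idx = i
            elif (y[i] - y[ext_idx]) * (1 if y[i] >= y[ext_idx] else -1) >= 0:
                # track the running extremum candidate loosely
                pass
        elif direction == 1:
            if y[i] >= y[ext_idx]:
                ext_idx = i
            elif moved(y[ext_idx], y[i]):
                pivots.append(ext_idx)
                direction = -1
                ext_idx = i
        else:
            if y[i] <= y[ext_idx]:
                ext_idx = i
            elif moved(y[ext_idx], y[i]):
                pivots.append(ext_idx)
                direction = 1
                ext_idx = i
    pivots.append(n - 1)
    pivots = sorted(set(pivots))
    phases = []
    for a, b in zip(pivots, pivots[1:]):
        if y[b] > y[a]:
            d = "increasing"
        elif y[b] < y[a]:
            d = "decreasing"
        else:
            d = "flat"
        phases.append(Phase(a, b, d))
    return phases


def valley_detection(values: Sequence[float], window: int = 20,
                     n_randomizations: int = 1000, quantile: float = 0.05,
                     rng: Optional[np.random.Generator] = None,
                     literal_mean_fraction: bool = False) -> list[tuple]:
    """Intervals where the observed running mean falls below the
    ``quantile`` envelope of running means of shuffled series.

    With ``literal_mean_fraction`` the alternative reading — below
    ``quantile`` times the randomized mean — is used instead. Returns
    (start, end) index pairs (inclusive)."""
    rng = np.random.default_rng(rng)
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 20:
        raise ValueError("series too short for valley detection")
    obs = pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    rand_means = np.empty((n_randomizations, n))
    for b in range(n_randomizations):
        perm = rng.permutation(y)
        rand_means[b] = (pd.Series(perm)
                         .rolling(window, center=True, min_periods=1)
                         .mean().to_numpy())
    if literal_mean_fraction:
        env = quantile * rand_means.mean(axis=0)
    else:
        env = np.quantile(rand_means, quantile, axis=0)
    below = obs < env
    intervals = []
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            intervals.append((i, j))
            i = j + 1
        else:
            i += 1
    return intervals


def cooccurrence_test(event_positions: Sequence[float],
                      intervals: Sequence[tuple],
                      domain_start: float = 0.2, domain_end: float = 1.0,
                      n_perm: int = 1000,
                      rng: Optional[np.random.Generator] = None) -> float:
    """One-sided permutation p-value for enrichment of events inside
    intervals, both expressed in tumor size-fraction coordinates.

    Restricted to fractions above ``domain_start`` (the primary beyond
    20% of its final size by default); the null circularly shifts each
    interval independently within the domain, preserving interval lengths
    and count (region-randomization)."""
    rng = np.random.default_rng(rng)
    ev = np.asarray([e for e in event_positions
                     if domain_start <= e <= domain_end], dtype=float)
    iv = [(max(a, domain_start), min(b, domain_end)) for a, b in intervals
          if b >= domain_start and a <= domain_end]
    width = domain_end - domain_start
    if width <= 0:
        raise ValueError("empty domain")
    if ev.size == 0 or not iv:
        return 1.0
    x = ev - domain_start

    def overlap_count(shifts) -> int:
        c = 0
        for (a, b), s in zip(iv, shifts):
            a2 = (a - domain_start + s) % width
            b2 = a2 + (b - a)
            c += int(np.sum((x >= a2) & (x <= b2)))
            if b2 > width:  # wrap-around
                c += int(np.sum(x <= b2 - width))
        return c

    obs = overlap_count(np.zeros(len(iv)))
    hits = 0
    for _ in range(n_perm):
        if overlap_count(rng.uniform(0, width, size=len(iv))) >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def series_report(series: pd.DataFrame, window: int = 20,
                  change_pct: float = 0.10,
                  rng: Optional[np.random.Generator] = None) -> dict:
    """Bundle of the standard series statistics for one simulation."""
    rng = np.random.default_rng(rng)
    out: dict = {}
    if "bmd_variants" in series and "B_m" in series and len(series) >= 10:
        r2, slope, ci = variance_explained(series, "bmd_variants", "B_m")
        out["bm_on_bmd"] = {"r2": r2, "slope": slope, "slope_ci": ci}
    if "bmd_generations" in series and "B_m" in series and len(series) >= 10:
        r2, slope, ci = variance_explained(series, "bmd_generations", "B_m")
        out["bm_on_generations"] = {"r2": r2, "slope": slope, "slope_ci": ci}
    if "B_m" in series and len(series) >= 20:
        out["white_p_bm"] = heteroscedasticity_test(series, "B_m")
        stats = running_stats(series, window, "B_m")
        runmean = stats["B_m_runmean"].to_numpy()
        out["phases"] = [
            {"start": p.start, "end": p.end, "direction": p.direction}
            for p in zigzag_partition(runmean, change_pct)
        ]
        out["valleys"] = [
            [int(a), int(b)]
            for a, b in valley_detection(series["B_m"].to_numpy(),
                                         window=window, rng=rng)
        ]
    if "B_p" in series and len(series) >= 20:
        out["white_p_bp"] = heteroscedasticity_test(series, "B_p")
    return out
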