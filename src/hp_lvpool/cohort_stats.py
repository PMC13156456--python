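"""Cohort-level threshold sweeps and model-comparison statistics.

Sweeps a delivery metric across its threshold grid, correlating it with
the metabolic outcome at every grid point; identifies the most negative
correlation, a tolerance window around it, and the noise-dominated /
optimal / plateau regimes; and provides the paired-t, Fisher-Z,
rank-trend, and effect-size comparisons between models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SweepResult",
    "ComparisonStats",
    "pearson",
    "sweep",
    "compare_models",
    "voxel_count_trend",
    "cohens_d",
    "relative_correlation_change",
]


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-point cohort correlations with regime annotation."""

    grid: np.ndarray
    corr: np.ndarray
    argmin_alpha: float
    optimal_window: tuple[float, float]
    regime_labels: tuple[str, ...]
    n_used: np.ndarray
    model: str = ""


@dataclass(frozen=True)
class ComparisonStats:
    """Statistics comparing two sweeps over a shared grid."""

    t_stat: float
    t_df: int
    t_pvalue: float
    fisher_z: float
    fisher_pvalue: float
    fisher_alpha: float
    mean_corr_a: float
    sd_corr_a: float
    mean_corr_b: float
    sd_corr_b: float


def pearson(x, y) -> float:
    """Sample Pearson correlation, ``Cov(X, Y) / (STD_X * STD_Y)``, with the
    (n-1) convention used consistently in numerator and denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx ** 2).sum() / (n - 1))
    sy = np.sqrt((dy ** 2).sum() / (n - 1))
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((dx * dy).sum() / (n - 1) / (sx * sy))


def sweep(table: pd.DataFrame, model: str = "", *,
          grid_col: str = "grid", metric_col: str = "metric",
          outcome_col: str = "outcome", delta: float = 0.005) -> SweepResult:
    """Correlate a per-study metric with the outcome at every grid point.

    ``table`` is long-format with one row per (study, grid point).  Studies
    with a non-finite metric or outcome at a grid point are dropped at
    that point (with a logged count).  The optimal window is the
    contiguous run of grid points with ``corr <= min(corr) + delta`` that
    contains the argmin.  Points left of the window are labeled
    ``noise_dominated``; points right of it are ``plateau`` when the
    step-to-step change stays within ``delta``, else ``unstable``.
    """
    grid = np.sort(table[grid_col].unique())
    if grid.size == 0:
        raise ValueError("empty grid")
    corr = np.empty(grid.size)
    n_used = np.empty(grid.size, dtype=int)
    for i, g in enumerate(grid):
        sub = table[table[grid_col] == g]
        ok = np.isfinite(sub[metric_col]) & np.isfinite(sub[outcome_col])
        dropped = int((~ok).sum())
        if dropped:
            logger.info("sweep %s: dropped %d studies at grid point %s",
                        model, dropped, g)
        sub = sub[ok]
        if len(sub) < 4:
            raise ValueError(f"fewer than 4 usable studies at grid point {g}")
        corr[i] = pearson(sub[metric_col].to_numpy(),
                          sub[outcome_col].to_numpy())
        n_used[i] = len(sub)

    i_min = int(np.argmin(corr))
    in_win = corr <= corr[i_min] + delta
    lo = i_min
    while lo > 0 and in_win[lo - 1]:
        lo -= 1
    hi = i_min
    while hi < grid.size - 1 and in_win[hi + 1]:
        hi += 1

    labels = []
    for i in range(grid.size):
        if lo <= i <= hi:
            labels.append("optimal")
        elif i < lo:
            labels.append("noise_dominated")
        else:
            step = abs(corr[i] - corr[i - 1])
            labels.append("plateau" if step <= delta else "unstable")

    return SweepResult(grid=grid, corr=corr, argmin_alpha=float(grid[i_min]),
                       optimal_window=(float(grid[lo]), float(grid[hi])),
                       regime_labels=tuple(labels), n_used=n_used, model=model)


def compare_models(sweep_a: SweepResult, sweep_b: SweepResult,
                   n_studies: int, alpha_test: float) -> ComparisonStats:
    """Paired two-tailed t-test over the per-threshold correlation pairs,
    plus a Fisher Z-test of the two correlations at ``alpha_test`` using
    ``z = atanh(r)`` and ``SE = sqrt(2 / (n - 3))`` (equal-n form)."""
    if sweep_a.grid.shape != sweep_b.grid.shape or \
            not np.array_equal(sweep_a.grid, sweep_b.grid):
        raise ValueError("sweeps are on different grids")
    a, b = sweep_a.corr, sweep_b.corr
    diff = a - b
    if np.allclose(diff, 0):
        t_stat, t_p = 0.0, 1.0
    else:
        res = sps.ttest_rel(a, b)
        t_stat, t_p = float(res.statistic), float(res.pvalue)

    idx = int(np.nonzero(np.isclose(sweep_a.grid, alpha_test))[0][0])
    r1, r2 = float(a[idx]), float(b[idx])
    se = np.sqrt(2.0 / (n_studies - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p_z = float(2.0 * sps.norm.sf(abs(z)))

    return ComparisonStats(
        t_stat=t_stat, t_df=a.size - 1, t_pvalue=t_p,
        fisher_z=float(z), fisher_pvalue=p_z, fisher_alpha=float(alpha_test),
        mean_corr_a=float(a.mean()), sd_corr_a=float(a.std(ddof=1)),
        mean_corr_b=float(b.mean()), sd_corr_b=float(b.std(ddof=1)),
    )


def voxel_count_trend(sweep_result: SweepResult, mean_counts) -> dict:
    """Spearman rho (average-rank ties) and OLS slope/R^2 of the sweep
    correlations against the mean retained voxel count per grid point."""
    counts = np.asarray(list(mean_counts), dtype=float)
    if counts.shape != sweep_result.corr.shape:
        raise ValueError("counts must align with the sweep grid")
    if np.any(counts <= 0):
        raise ValueError("voxel counts must be positive")
    rho = float(sps.spearmanr(counts, sweep_result.corr).statistic)
    fit = sps.linregress(counts, sweep_result.corr)
    return {"spearman_rho": rho, "slope": float(fit.slope),
            "r2": float(fit.rvalue ** 2), "intercept": float(fit.intercept)}


def cohens_d(group_a, group_b) -> float:
    """Effect size ``(mean_a - mean_b) / pooled SD`` with the
    ``n_a + n_b - 2`` pooled-variance denominator."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                  / (a.size + b.size - 2))
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def relative_correlation_change(r_from: float, r_to: float) -> float:
    """Percent change in correlation magnitude between two thresholds:
    ``100 * (|r_to| - |r_from|) / |r_from|``."""
    if r_from == 0:
        raise ValueError("reference correlation is zero")
    return 100.0 * (abs(r_to) - abs(r_from)) / abs(r_from)
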