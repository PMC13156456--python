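"""Blood-pool pyruvate delivery models and normalized per-study metrics.

Three ways of summarizing delivered pyruvate inside the endocardial ROI:

* adaptive threshold model ``Pyr(alpha%)`` — AUC of the mean SNR time curve
  over voxels whose summed-pyruvate intensity is at or above
  ``alpha/100 * Imax + Imin``;
* percentile model ``Pyr(T%)`` — the same quantity over the top T% brightest
  voxels;
* peak intensity ``Imax``.

Per-study metrics normalize the rank-decay constant B (or Imax) by the
delivery term: ``B/Pyr(alpha%)``, ``Imax/Pyr(alpha%)``, ``B/Pyr(T%)``.

All thresholds are expressed in percent.  The threshold comparison is
inclusive (``>=``) so that at ``alpha = alpha_max`` exactly the maximal
voxel(s) survive; voxels tied at the threshold are all retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exponential_model import ExpFit, IntensityProfile
from .preprocess import DynamicSeries, NoiseEstimate, SnrCurve, snr_curve

__all__ = [
    "ThresholdSelection",
    "StudyMetrics",
    "alpha_max",
    "alpha_grid_upper",
    "select_threshold",
    "pyr_alpha_curve",
    "pyr_alpha_table",
    "percentile_model",
    "percentile_table",
    "study_metrics",
]


@dataclass
class ThresholdSelection:
    """Voxels retained by the adaptive threshold at one ``alpha``."""

    alpha: float
    threshold_value: float
    retained_mask: np.ndarray
    n_retained: int
    pyr_alpha: float | None = None


@dataclass
class StudyMetrics:
    """Normalized delivery metrics of one study across both model grids."""

    b_value: float
    i_max: float
    pyr_alpha: dict[int, float]
    pyr_t: dict[int, float]
    metric_numfit: dict[int, float]
    metric_peak: dict[int, float]
    metric_percentile: dict[int, float]
    lac_bic: float
    n_retained_alpha: dict[int, int] = field(default_factory=dict)
    n_retained_t: dict[int, int] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)
    alpha_max_value: float = 100.0


def alpha_max(i_max: float, i_min: float) -> float:
    """Largest usable threshold percentage of one study:
    ``(Imax - Imin) / Imax * 100``."""
    if i_max <= 0:
        raise ValueError(f"Imax must be positive, got {i_max}")
    if not 0 <= i_min <= i_max:
        raise ValueError(f"need 0 <= Imin <= Imax, got Imin={i_min}, Imax={i_max}")
    return (i_max - i_min) / i_max * 100.0


def alpha_grid_upper(alpha_maxes) -> int:
    """Largest integer threshold usable by every study of a cohort:
    ``floor(min(alpha_max))``."""
    values = np.asarray(list(alpha_maxes), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one study")
    m = float(values.min())
    if m < 1.0:
        raise ValueError(f"cohort minimum alpha_max={m:.3g} leaves no usable "
                         "integer threshold grid")
    return int(math.floor(m))


def select_threshold(sum_pyr: np.ndarray, endo: np.ndarray,
                     profile: IntensityProfile,
                     alpha: float) -> ThresholdSelection:
    """Retain masked voxels with summed pyruvate at or above
    ``alpha/100 * Imax + Imin``.

    If nothing survives (degenerate all-equal profile or ``alpha``
    beyond ``alpha_max``), the maximal voxel(s) are retained and a
    warning is emitted.
    """
    endo = np.asarray(endo, dtype=bool)
    if not endo.any():
        raise ValueError("endocardial mask is empty")
    thr = alpha / 100.0 * profile.i_max + profile.i_min
    retained = endo & (np.asarray(sum_pyr, dtype=float) >= thr)
    if not retained.any():
        warnings.warn(
            f"threshold {thr:.6g} at alpha={alpha} retains no voxel; "
            "falling back to the maximal voxel(s)", stacklevel=2)
        retained = endo & (np.asarray(sum_pyr, dtype=float) >= profile.i_max)
    return ThresholdSelection(alpha=float(alpha), threshold_value=float(thr),
                              retained_mask=retained,
                              n_retained=int(retained.sum()))


def pyr_alpha_curve(pyr: DynamicSeries, selection: ThresholdSelection,
                    noise: NoiseEstimate) -> SnrCurve:
    """Mean SNR time curve over the retained voxels; its AUC is
    ``Pyr(alpha%)`` and is stored back on the selection."""
    curve = snr_curve(pyr, selection.retained_mask, noise)
    selection.pyr_alpha = curve.auc
    return curve


def _sorted_prefix_curves(pyr: DynamicSeries, sum_pyr: np.ndarray,
                          endo: np.ndarray):
    """Voxel SNR-less time curves in descending summed-intensity order plus
    their prefix sums; shared by the vectorized table builders."""
    endo = np.asarray(endo, dtype=bool)
    vals = np.asarray(sum_pyr, dtype=float)[endo]
    order = np.argsort(-vals, kind="stable")
    curves = pyr.frames[:, endo].T[order]          # (N, F)
    prefix = np.cumsum(curves, axis=0)             # (N, F)
    return vals[order], prefix


def pyr_alpha_table(pyr: DynamicSeries, sum_pyr: np.ndarray,
                    endo: np.ndarray, profile: IntensityProfile,
                    noise: NoiseEstimate, alphas) -> pd.DataFrame:
    """Vectorized ``Pyr(alpha%)`` over a grid of thresholds.

    Because the retained set at any threshold is a prefix of the voxels
    sorted by summed intensity, all thresholds share one cumulative sum;
    the result is identical to looping ``select_threshold`` +
    ``pyr_alpha_curve`` (asserted by test).
    """
    if not pyr.flip_corrected:
        raise ValueError("pyr_alpha_table requires a flip-angle corrected series")
    alphas = np.asarray(list(alphas), dtype=float)
    sorted_vals, prefix = _sorted_prefix_curves(pyr, sum_pyr, endo)
    n = sorted_vals.size
    thr = alphas / 100.0 * profile.i_max + profile.i_min
    asc = sorted_vals[::-1]
    n_ret = n - np.searchsorted(asc, thr, side="left")
    n_ret = np.maximum(n_ret, 1)  # fallback: keep the maximal voxel
    aucs = np.empty(alphas.size)
    for k, m in enumerate(n_ret):
        curve = prefix[m - 1] / (m * noise.sigma)
        aucs[k] = np.trapezoid(curve)
    return pd.DataFrame({"alpha": alphas, "n_retained": n_ret.astype(int),
                         "pyr": aucs})


def percentile_model(pyr: DynamicSeries, sum_pyr: np.ndarray,
                     endo: np.ndarray, profile: IntensityProfile,
                     t: float, noise: NoiseEstimate) -> tuple[float, int]:
    """``Pyr(T%)``: mean-SNR AUC over the ``ceil(T/100 * N)`` (at least 1)
    brightest voxels.  Returns ``(auc, n_voxels)``."""
    if not 1 <= t <= 100:
        raise ValueError(f"T must be in [1, 100], got {t}")
    if not pyr.flip_corrected:
        raise ValueError("percentile_model requires a flip-angle corrected series")
    sorted_vals, prefix = _sorted_prefix_curves(pyr, sum_pyr, endo)
    k = max(1, math.ceil(t / 100.0 * sorted_vals.size))
    curve = prefix[k - 1] / (k * noise.sigma)
    return float(np.trapezoid(curve)), k


def percentile_table(pyr: DynamicSeries, sum_pyr: np.ndarray,
                     endo: np.ndarray, profile: IntensityProfile,
                     noise: NoiseEstimate, ts) -> pd.DataFrame:
    """Vectorized ``Pyr(T%)`` over a grid of percentiles."""
    if not pyr.flip_corrected:
        raise ValueError("percentile_table requires a flip-angle corrected series")
    ts = np.asarray(list(ts), dtype=float)
    sorted_vals, prefix = _sorted_prefix_curves(pyr, sum_pyr, endo)
    n = sorted_vals.size
    rows = []
    for t in ts:
        k = max(1, math.ceil(t / 100.0 * n))
        curve = prefix[k - 1] / (k * noise.sigma)
        rows.append((t, k, float(np.trapezoid(curve))))
    return pd.DataFrame(rows, columns=["t", "n_retained", "pyr"])


def study_metrics(fit: ExpFit,
                  pyr_alpha: dict[int, float],
                  pyr_t: dict[int, float],
                  outcome: float,
                  n_retained_alpha: dict[int, int] | None = None,
                  n_retained_t: dict[int, int] | None = None,
                  alpha_max_value: float = 100.0) -> StudyMetrics:
    """Assemble the normalized metrics ``B/Pyr(alpha%)``, ``Imax/Pyr(alpha%)``
    and ``B/Pyr(T%)``; grid points with ``Pyr = 0`` are set to NaN and
    flagged."""
    flagged: list[str] = []

    def _ratio(num: float, grid: dict[int, float], tag: str) -> dict[int, float]:
        out: dict[int, float] = {}
        for g, p in grid.items():
            if p == 0:
                out[g] = float("nan")
                flagged.append(f"{tag}@{g}")
            else:
                out[g] = num / p
        return out

    return StudyMetrics(
        b_value=fit.b_value,
        i_max=fit.i_max,
        pyr_alpha=dict(pyr_alpha),
        pyr_t=dict(pyr_t),
        metric_numfit=_ratio(fit.b_value, pyr_alpha, "numfit"),
        metric_peak=_ratio(fit.i_max, pyr_alpha, "peak"),
        metric_percentile=_ratio(fit.b_value, pyr_t, "percentile"),
        lac_bic=float(outcome),
        n_retained_alpha=dict(n_retained_alpha or {}),
        n_retained_t=dict(n_retained_t or {}),
        flagged=flagged,
        alpha_max_value=alpha_max_value,
    )
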