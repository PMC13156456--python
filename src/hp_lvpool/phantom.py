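"""Synthetic study and cohort generation.

Generates single studies whose summed-pyruvate intensity profile inside the
endocardial ROI follows the exponential rank-decay model exactly (plus
configurable perturbations), with a gamma-variate pyruvate bolus, delayed
lower-amplitude metabolite curves confined to the myocardial band, baseline
noise-only frames, and — at cohort level — a planted negative association
between the normalized delivery metric at a chosen threshold and the
metabolic outcome.

Spatial assignment is center-out radial: the brightest profile values are
placed nearest the ventricle center, ties broken by angle.  A single seed
fans out into per-study substreams so cohorts are reproducible
element-wise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import exponential_model as em
from . import preprocess as pp
from . import signal_models as sm
from .roi_geometry import MaskSet, build_masks

__all__ = [
    "PhantomSpec",
    "PhantomStudy",
    "make_study",
    "make_cohort",
    "write_study",
    "read_study",
]

PYR_FLIP = 5.0
MET_FLIP = 30.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic study.

    ``bolus`` is ``(t0, k, beta, amplitude)`` of the gamma-variate
    ``A * (t - t0)^k * exp(-(t - t0) / beta)`` driving the pyruvate frame
    weights.  ``coupling`` is ``(intercept, slope, noise_sd)`` of the
    metabolic-outcome model used at cohort level.

    Shape perturbations (all off by default, so the sorted profile is
    exactly exponential):

    * ``shape_gamma`` — rank-stretching exponent; 1.0 keeps the pure
      exponential ``Imax * exp(-B (j-1))``.
    * ``profile_noise_cv`` — multiplicative log-normal roughness of the
      profile, smoothed over ``profile_noise_corr * N`` ranks.
    * ``noise_floor_frac`` — per-study intensity floor as a fraction of
      ``Imax``, emulating the magnitude-image noise floor that real sorted
      profiles flatten into.
    """

    grid_size: int = 100
    n_pyr_frames: int = 44
    n_met_frames: int = 22
    baseline_frames: int = 30
    lv_center: tuple[float, float] = (50.0, 50.0)
    endo_radii: tuple[float, float] = (8.6, 8.4)
    angle: float = 0.0
    endo_scale: float = 0.80
    mid_myo_shrink: float = 0.10
    planted_B: float = 0.0105
    planted_Imax: float = 1286.0
    bolus: tuple[float, float, float, float] = (8.0, 3.0, 3.5, 1.0)
    noise_sigma: float = 0.0
    coupling: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0
    shape_gamma: float = 1.0
    profile_noise_cv: float = 0.0
    profile_noise_corr: float = 0.15
    noise_floor_frac: float = 0.0
    met_amplitude: float = 50.0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError(f"grid_size must be >= 16, got {self.grid_size}")
        if self.planted_B <= 0:
            raise ValueError("planted_B must be positive")
        if self.planted_Imax <= 0:
            raise ValueError("planted_Imax must be positive")
        if self.n_pyr_frames != 2 * self.n_met_frames:
            raise ValueError("n_pyr_frames must equal 2 * n_met_frames")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass
class PhantomStudy:
    """One synthetic study: three raw dynamic series, masks, and the planted
    ground truth."""

    pyruvate: pp.DynamicSeries
    lactate: pp.DynamicSeries
    bicarbonate: pp.DynamicSeries
    masks: MaskSet
    truth: dict = field(default_factory=dict)


def _gamma_variate(t: np.ndarray, t0: float, k: float, beta: float,
                   amplitude: float = 1.0) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    m = t > t0
    dt = t[m] - t0
    out[m] = amplitude * dt ** k * np.exp(-dt / beta)
    return out


def _radial_order(endo: np.ndarray, center: tuple[float, float]) -> tuple:
    """(rows, cols) of the endo voxels sorted center-out, ties by angle."""
    rr, cc = np.nonzero(endo)
    d = np.hypot(rr - center[0], cc - center[1])
    ang = np.arctan2(rr - center[0], cc - center[1])
    order = np.lexsort((ang, d))
    return rr[order], cc[order]


def _planted_profile(spec: PhantomSpec, n: int, rng: np.random.Generator
                     ) -> np.ndarray:
    """Descending intensity profile with the configured perturbations."""
    u = np.arange(n, dtype=float) / max(n - 1, 1)
    rate = spec.planted_B * (n - 1)
    prof = spec.planted_Imax * np.exp(-rate * u ** spec.shape_gamma)
    if spec.noise_floor_frac > 0:
        prof = np.maximum(prof, spec.noise_floor_frac * spec.planted_Imax)
    if spec.profile_noise_cv > 0:
        from scipy.ndimage import gaussian_filter1d
        z = gaussian_filter1d(rng.standard_normal(n),
                              sigma=max(spec.profile_noise_corr * n, 1.0),
                              mode="nearest")
        sd = z.std()
        if sd > 0:
            z /= sd
        cv = spec.profile_noise_cv
        prof = prof * np.exp(cv * z - 0.5 * cv ** 2)
        prof = np.sort(prof)[::-1]
    return prof


def _met_weights(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Clean lactate / bicarbonate temporal shapes on the metabolite grid;
    onset after the baseline heartbeats (two heartbeats per frame)."""
    t = np.arange(spec.n_met_frames, dtype=float)
    m0 = spec.baseline_frames // 2
    g_lac = _gamma_variate(t, m0 - 0.5, 1.5, 2.0)
    g_bic = _gamma_variate(t, m0 + 0.5, 1.5, 2.0)
    return g_lac, g_bic


def make_study(spec: PhantomSpec,
               rng: np.random.Generator | None = None,
               target_outcome: float | None = None) -> PhantomStudy:
    """Generate one synthetic study.

    The summed pyruvate image restricted to the endocardial mask, sorted
    descending, equals the planted profile (exactly exponential when all
    perturbations are off); brighter voxels sit nearer the ventricle
    center.  Frames before bolus onset contain only noise.  The raw series
    carry the acquisition flip-angle scaling (``sin(theta)``), so the
    planted intensities are recovered after flip-angle correction.

    ``target_outcome``, if given, scales the clean metabolite amplitudes so
    the mid-myocardial Lac+Bic SNR AUC equals it (requires
    ``noise_sigma > 0`` to define SNR).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    a_endo, b_endo = spec.endo_radii
    masks = build_masks(spec.lv_center,
                        (a_endo / spec.endo_scale, b_endo / spec.endo_scale),
                        angle=spec.angle, endo_scale=spec.endo_scale,
                        mid_myo_shrink=spec.mid_myo_shrink,
                        grid_size=spec.grid_size)
    n = int(masks.endo.sum())

    prof = _planted_profile(spec, n, rng)
    rr, cc = _radial_order(masks.endo, spec.lv_center)
    sum_img = np.zeros((spec.grid_size, spec.grid_size))
    sum_img[rr, cc] = prof

    t0, k, beta, amp = spec.bolus
    t = np.arange(spec.n_pyr_frames, dtype=float)
    g = _gamma_variate(t, t0, k, beta, amp)
    if g.sum() <= 0:
        raise ValueError("bolus curve is zero over the frame window")
    w = g / g.sum()
    pyr_clean = sum_img[None, :, :] * w[:, None, None]

    sin_pyr = np.sin(np.deg2rad(PYR_FLIP))
    sin_met = np.sin(np.deg2rad(MET_FLIP))
    pyr_raw = pyr_clean * sin_pyr
    if spec.noise_sigma > 0:
        pyr_raw = pyr_raw + rng.normal(0.0, spec.noise_sigma, pyr_raw.shape)

    # metabolites: uniform amplitude on the myocardial band, delayed bolus
    g_lac, g_bic = _met_weights(spec)
    if target_outcome is not None:
        if spec.noise_sigma <= 0:
            raise ValueError("target_outcome requires noise_sigma > 0")
        sigma_shared = spec.noise_sigma / sin_pyr
        denom = (np.trapezoid(g_lac) + (2.0 / 3.0) * np.trapezoid(g_bic))
        a_lac = target_outcome * sigma_shared / denom
    else:
        a_lac = spec.met_amplitude
    a_bic = (2.0 / 3.0) * a_lac

    band = masks.myo.astype(float)
    lac_raw = band[None, :, :] * (a_lac * g_lac)[:, None, None] * sin_met
    bic_raw = band[None, :, :] * (a_bic * g_bic)[:, None, None] * sin_met
    if spec.noise_sigma > 0:
        lac_raw = lac_raw + rng.normal(0.0, spec.noise_sigma, lac_raw.shape)
        bic_raw = bic_raw + rng.normal(0.0, spec.noise_sigma, bic_raw.shape)

    truth = asdict(spec)
    truth.update(n_roi=n, a_lac=a_lac, a_bic=a_bic,
                 target_outcome=target_outcome,
                 bolus_peak_frame=int(np.argmax(w)))

    return PhantomStudy(
        pyruvate=pp.DynamicSeries(pyr_raw, flip_angle=PYR_FLIP,
                                  metabolite="pyruvate", frame_interval=1),
        lactate=pp.DynamicSeries(lac_raw, flip_angle=MET_FLIP,
                                 metabolite="lactate", frame_interval=2),
        bicarbonate=pp.DynamicSeries(bic_raw, flip_angle=MET_FLIP,
                                     metabolite="bicarbonate",
                                     frame_interval=2),
        masks=masks, truth=truth)


def measure_delivery_metric(study: PhantomStudy, alpha: float
                            ) -> tuple[float, float, float]:
    """Run the minimal analysis chain on one study's pyruvate series and
    return ``(B_hat, Pyr(alpha), sigma_hat)``.

    Noise is estimated from the corrected pre-onset pyruvate frames over
    the extra-epicardial background, as in the full pipeline.
    """
    b_hat, pyr_auc, sigma = _measure_metric_grid(study, [alpha])
    return b_hat, float(pyr_auc[0]), sigma


def _measure_metric_grid(study: PhantomStudy, alphas
                         ) -> tuple[float, np.ndarray, float]:
    """``(B_hat, Pyr(alpha) per alpha, sigma_hat)`` over a threshold grid."""
    pyr = pp.flip_angle_correct(study.pyruvate)
    t0 = study.truth["bolus"][0]
    baseline = range(0, max(min(int(t0), 8), 2))
    noise = pp.estimate_noise(pyr, baseline, ~study.masks.epic)
    sum_img = pp.sum_pyruvate(pyr)
    profile = em.sort_roi(sum_img, study.masks.endo)
    fit = em.fit_exponential(profile)
    table = sm.pyr_alpha_table(pyr, sum_img, study.masks.endo, profile,
                               noise, alphas)
    return fit.b_value, table["pyr"].to_numpy(), noise.sigma


def _draw_study_spec(rng: np.random.Generator, base: PhantomSpec,
                     b_mean: float, b_sd: float,
                     b_range: tuple[float, float],
                     imax_range: tuple[float, float],
                     radii_range: tuple[float, float],
                     shape_jitter_sd: float,
                     profile_noise_cv: float,
                     noise_rel_range: tuple[float, float],
                     floor_range: tuple[float, float],
                     seed: int,
                     couple_b_to_shape: bool = False) -> PhantomSpec:
    gamma_draw = float(np.clip(rng.normal(1.0, shape_jitter_sd), 0.6, 1.5))
    if couple_b_to_shape:
        # draw B so the recovered rank-decay constant (which scales roughly
        # as 3 / (gamma + 2) for stretched profiles) stays decoupled from
        # the shape jitter; keeps the planted range while concentrating the
        # cohort variance in the threshold-localized shape heterogeneity
        b = float(np.clip(rng.normal(b_mean, b_sd) * (gamma_draw + 2.0) / 3.0,
                          *b_range))
    else:
        b = float(np.clip(rng.normal(b_mean, b_sd), *b_range))
    log_lo, log_hi = np.log(imax_range[0]), np.log(imax_range[1])
    imax = float(np.exp(rng.uniform(log_lo, log_hi)))
    radii = (float(rng.uniform(*radii_range)), float(rng.uniform(*radii_range)))
    gamma = gamma_draw
    sigma = imax * float(rng.uniform(*noise_rel_range))
    floor = float(rng.uniform(*floor_range))
    t0 = float(rng.uniform(8.0, 11.0))
    k = float(rng.uniform(2.5, 3.5))
    beta = float(rng.uniform(3.0, 4.0))
    center = (base.grid_size / 2.0, base.grid_size / 2.0)
    return PhantomSpec(
        grid_size=base.grid_size, n_pyr_frames=base.n_pyr_frames,
        n_met_frames=base.n_met_frames, baseline_frames=base.baseline_frames,
        lv_center=center, endo_radii=radii, angle=base.angle,
        endo_scale=base.endo_scale, mid_myo_shrink=base.mid_myo_shrink,
        planted_B=b, planted_Imax=imax, bolus=(t0, k, beta, 1.0),
        noise_sigma=sigma, seed=seed, shape_gamma=gamma,
        profile_noise_cv=profile_noise_cv,
        profile_noise_corr=base.profile_noise_corr,
        noise_floor_frac=floor)


def make_cohort(n_studies: int, metric_alpha_star: float, rho_target: float,
                seed: int, *,
                base_spec: PhantomSpec | None = None,
                b_mean: float = 0.0105, b_sd: float = 0.0036,
                b_range: tuple[float, float] = (0.0028, 0.0183),
                imax_range: tuple[float, float] = (126.0, 5577.0),
                radii_range: tuple[float, float] = (7.0, 9.9),
                shape_jitter_sd: float = 0.12,
                profile_noise_cv: float = 0.10,
                noise_rel_range: tuple[float, float] = (5e-5, 2e-4),
                floor_range: tuple[float, float] = (0.04, 0.12),
                outcome_scale: float = 400.0,
                outcome_cv: float = 0.25,
                null_coupling: bool = False,
                couple_b_to_shape: bool = False,
                orthogonal_noise: bool = True,
                orthogonal_grid=range(1, 64),
                ) -> tuple[list[PhantomStudy], pd.DataFrame]:
    """Generate a cohort of synthetic studies with a planted negative
    association between ``B/Pyr(alpha_star)`` and the metabolic outcome.

    Per-study parameters (B, Imax, ROI size, noise level, bolus timing,
    profile-shape jitter) are drawn from ranges emulating a realistic
    cohort.  The outcome of study i is

        y_i = a + b * m_i + eps_i

    where ``m_i`` is the study's measured ``B/Pyr(alpha_star)`` metric, the
    slope ``b`` is negative, and the noise scale is chosen so the sample
    correlation at ``alpha_star`` approaches ``rho_target``.  Metabolite
    amplitudes are scaled so the pipeline-measured Lac+Bic outcome
    reproduces ``y_i``.  ``null_coupling=True`` sets the slope to zero
    (outcome independent of the metric), for null-behavior checks.

    With ``orthogonal_noise`` (default), the noise term ``eps`` is drawn
    orthogonal in sample to the measured metric columns over
    ``orthogonal_grid``, a variance-control device that makes the planted
    optimum exactly identifiable by the threshold sweep: because the
    normalized delivery metrics at neighboring thresholds are intrinsically
    >95% correlated across studies, an i.i.d. noise draw would swamp the
    between-threshold correlation differences and leave the planted
    optimum localizable only by chance.  Set it to False to exercise the
    plain i.i.d. sampling behavior.

    Returns the studies and a truth table of all planted values.
    """
    if n_studies < 4:
        raise ValueError(f"need at least 4 studies, got {n_studies}")
    if not null_coupling and not -1.0 < rho_target < 0.0:
        raise ValueError(
            f"rho_target must be in (-1, 0) (negative association), "
            f"got {rho_target}")

    base = base_spec if base_spec is not None else PhantomSpec(
        grid_size=64, lv_center=(32.0, 32.0))
    ss = np.random.SeedSequence(seed)
    coupling_rng = np.random.default_rng(ss.spawn(1)[0])
    study_seeds = ss.spawn(n_studies)

    specs: list[PhantomSpec] = []
    met_rngs: list[np.random.Generator] = []
    grid = (sorted(set(list(orthogonal_grid) + [metric_alpha_star]))
            if orthogonal_noise else [metric_alpha_star])
    star_idx = grid.index(metric_alpha_star)
    metric_cols = np.empty((n_studies, len(grid)))
    b_hats = np.empty(n_studies)
    pyr_stars = np.empty(n_studies)
    sigma_hats = np.empty(n_studies)
    partial: list[PhantomStudy] = []

    for i, child in enumerate(study_seeds):
        draw_rng, pyr_rng, met_rng = (np.random.default_rng(s)
                                      for s in child.spawn(3))
        spec = _draw_study_spec(draw_rng, base, b_mean, b_sd, b_range,
                                imax_range, radii_range, shape_jitter_sd,
                                profile_noise_cv, noise_rel_range,
                                floor_range, seed,
                                couple_b_to_shape=couple_b_to_shape)
        specs.append(spec)
        met_rngs.append(met_rng)
        study = make_study(spec, rng=pyr_rng)  # placeholder metabolites
        partial.append(study)
        b_hat, pyr_grid, sig = _measure_metric_grid(study, grid)
        b_hats[i], sigma_hats[i] = b_hat, sig
        pyr_stars[i] = pyr_grid[star_idx]
        metric_cols[i] = b_hat / pyr_grid

    metrics = metric_cols[:, star_idx]
    mu, sd = metrics.mean(), metrics.std(ddof=1)
    u = (metrics - mu) / sd
    w = coupling_rng.standard_normal(n_studies)
    if orthogonal_noise:
        # full basis when n comfortably exceeds the grid; otherwise cap it
        # well below n so the projection leaves real noise
        if n_studies >= len(grid) + 20:
            k = len(grid)
        else:
            k = min(len(grid), max(1, n_studies // 2 - 1))
        idx = np.unique(np.round(np.linspace(0, len(grid) - 1, k)).astype(int))
        idx = np.unique(np.append(idx, star_idx))
        design = np.column_stack([np.ones(n_studies), metric_cols[:, idx]])
        coef, *_ = np.linalg.lstsq(design, w, rcond=None)
        resid = w - design @ coef
        resid_sd = resid.std(ddof=1)
        if resid_sd > 1e-8:
            w = (resid - resid.mean()) / resid_sd
    rho_eff = 0.0 if null_coupling else rho_target
    inner = rho_eff * u + np.sqrt(1.0 - rho_eff ** 2) * w
    y = outcome_scale * (1.0 + outcome_cv * inner)
    y = np.maximum(y, 0.02 * outcome_scale)
    slope = outcome_scale * outcome_cv * rho_eff / sd
    intercept = outcome_scale - slope * mu
    eps_sd = outcome_scale * outcome_cv * np.sqrt(1.0 - rho_eff ** 2)

    studies: list[PhantomStudy] = []
    rows = []
    for i, spec in enumerate(specs):
        # rebuild the metabolite series with the planted outcome; the
        # pyruvate part is reused untouched from the first pass
        sin_met = np.sin(np.deg2rad(MET_FLIP))
        g_lac, g_bic = _met_weights(spec)
        sigma_shared = spec.noise_sigma / np.sin(np.deg2rad(PYR_FLIP))
        denom = np.trapezoid(g_lac) + (2.0 / 3.0) * np.trapezoid(g_bic)
        a_lac = y[i] * sigma_shared / denom
        a_bic = (2.0 / 3.0) * a_lac
        band = partial[i].masks.myo.astype(float)
        met_rng = met_rngs[i]
        lac_raw = (band[None, :, :] * (a_lac * g_lac)[:, None, None] * sin_met
                   + met_rng.normal(0.0, spec.noise_sigma,
                                    (spec.n_met_frames, spec.grid_size,
                                     spec.grid_size)))
        bic_raw = (band[None, :, :] * (a_bic * g_bic)[:, None, None] * sin_met
                   + met_rng.normal(0.0, spec.noise_sigma,
                                    (spec.n_met_frames, spec.grid_size,
                                     spec.grid_size)))
        study = partial[i]
        study.lactate = pp.DynamicSeries(lac_raw, flip_angle=MET_FLIP,
                                         metabolite="lactate",
                                         frame_interval=2)
        study.bicarbonate = pp.DynamicSeries(bic_raw, flip_angle=MET_FLIP,
                                             metabolite="bicarbonate",
                                             frame_interval=2)
        study.truth.update(target_outcome=float(y[i]), a_lac=a_lac,
                           a_bic=a_bic, coupling=(float(intercept),
                                                  float(slope),
                                                  float(eps_sd)))
        studies.append(study)
        rows.append({
            "study_id": f"S{i:03d}", "subject_id": f"P{i // 2:03d}",
            "planted_B": spec.planted_B, "planted_Imax": spec.planted_Imax,
            "n_roi": study.truth["n_roi"], "noise_sigma": spec.noise_sigma,
            "shape_gamma": spec.shape_gamma,
            "noise_floor_frac": spec.noise_floor_frac,
            "b_hat": b_hats[i], "pyr_alpha_star": pyr_stars[i],
            "sigma_hat": sigma_hats[i], "metric_alpha_star": metrics[i],
            "outcome": float(y[i]),
        })

    truth = pd.DataFrame(rows)
    truth.attrs.update(alpha_star=metric_alpha_star, rho_target=rho_target,
                       intercept=float(intercept), slope=float(slope),
                       eps_sd=float(eps_sd), seed=seed)
    return studies, truth


# ---------------------------------------------------------------------------
# serialization: NIfTI volumes + JSON sidecar with run-length encoded masks

def _rle_encode(mask: np.ndarray) -> list[list[int]]:
    flat = np.asarray(mask, dtype=bool).ravel()
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], flat.view(np.int8),
                                                 [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        runs.append([int(start), int(stop - start)])
    return runs


def _rle_decode(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in runs:
        flat[start:start + length] = True
    return flat.reshape(shape)


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_study(study: PhantomStudy, out_dir, name: str) -> None:
    """Write a study as three NIfTI-1 2D+time volumes plus a JSON sidecar
    holding the run-length encoded masks and the planted truth."""
    import pathlib

    import nibabel as nib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for series in (study.pyruvate, study.lactate, study.bicarbonate):
        # store as (row, col, 1, frame) so frame is the NIfTI time axis
        data = np.transpose(series.frames, (1, 2, 0))[:, :, None, :]
        img = nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))
        nib.save(img, out / f"{name}_{series.metabolite}.nii")

    sidecar = {
        "grid_size": study.masks.grid_size,
        "masks": {k: _rle_encode(getattr(study.masks, k))
                  for k in ("epic", "endo", "myo", "mid_myo")},
        "series": {s.metabolite: {"flip_angle": s.flip_angle,
                                  "frame_interval": s.frame_interval}
                   for s in (study.pyruvate, study.lactate,
                             study.bicarbonate)},
        "truth": _sanitize(study.truth),
    }
    (out / f"{name}.json").write_text(json.dumps(sidecar, indent=1))


def read_study(in_dir, name: str) -> PhantomStudy:
    """Inverse of :func:`write_study`."""
    import pathlib

    import nibabel as nib

    src = pathlib.Path(in_dir)
    sidecar = json.loads((src / f"{name}.json").read_text())
    gs = sidecar["grid_size"]
    masks = MaskSet(grid_size=gs,
                    **{k: _rle_decode(v, (gs, gs))
                       for k, v in sidecar["masks"].items()})
    series = {}
    for met, meta in sidecar["series"].items():
        img = nib.load(src / f"{name}_{met}.nii")
        data = np.asarray(img.dataobj, dtype=float)[:, :, 0, :]
        frames = np.transpose(data, (2, 0, 1))
        series[met] = pp.DynamicSeries(frames, flip_angle=meta["flip_angle"],
                                       metabolite=met,
                                       frame_interval=meta["frame_interval"])
    truth = sidecar["truth"]
    for key in ("lv_center", "endo_radii", "bolus", "coupling"):
        if key in truth and isinstance(truth[key], list):
            truth[key] = tuple(truth[key])
    return PhantomStudy(pyruvate=series["pyruvate"], lactate=series["lactate"],
                        bicarbonate=series["bicarbonate"], masks=masks,
                        truth=truth)
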