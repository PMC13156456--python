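"""Preprocessing of dynamic 13C image series.

Brings raw series to the analysis grid (k-space zero-fill interpolation
plus rigid orientation ops), applies flip-angle correction, estimates the
study noise level from baseline frames, and computes SNR time curves,
their trapezoidal AUCs, the summed-pyruvate image, and the combined
myocardial metabolic outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DynamicSeries",
    "NoiseEstimate",
    "SnrCurve",
    "to_analysis_grid",
    "flip_angle_correct",
    "estimate_noise",
    "snr_curve",
    "sum_pyruvate",
    "metabolic_outcome",
]


@dataclass
class DynamicSeries:
    """One metabolite's 2D+time image stack.

    ``frames`` has shape (n_frames, rows, cols) in arbitrary units.
    ``frame_interval`` is the number of heartbeats per frame (1 for
    pyruvate, 2 for the reconstructed metabolite frames).  ``flip_angle``
    is the excitation flip angle in degrees.
    """

    frames: np.ndarray
    flip_angle: float
    metabolite: str = ""
    frame_interval: int = 1
    flip_corrected: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3D (frame, row, col), "
                             f"got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise ValueError("a dynamic series needs at least 2 frames")
        if not 0.0 < self.flip_angle <= 90.0:
            raise ValueError(f"flip_angle must be in (0, 90], got {self.flip_angle}")
        if self.frame_interval < 1:
            raise ValueError("frame_interval must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class NoiseEstimate:
    """Per-study noise standard deviation and its provenance."""

    sigma: float
    source_frames: tuple[int, ...] = ()
    source_region: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class SnrCurve:
    """Mean SNR per frame over a mask, with its trapezoidal AUC."""

    values: np.ndarray
    auc: float

    def __len__(self) -> int:
        return len(self.values)


def _kspace_resample(img: np.ndarray, out_size: int) -> np.ndarray:
    """Sinc-interpolate one frame to ``out_size`` by symmetric k-space
    zero-padding; the scaling preserves the mean intensity (DC) and the
    mean squared intensity exactly."""
    r, c = img.shape
    spec = np.fft.fftshift(np.fft.fft2(img))
    pad = np.zeros((out_size, out_size), dtype=complex)
    r0 = (out_size - r) // 2
    c0 = (out_size - c) // 2
    pad[r0:r0 + r, c0:c0 + c] = spec
    out = np.fft.ifft2(np.fft.ifftshift(pad)) * (out_size * out_size / (r * c))
    return np.abs(out)


def to_analysis_grid(series: DynamicSeries,
                     out_size: int = 100,
                     rot90: int = 0,
                     flip_lr: bool = False,
                     flip_ud: bool = False,
                     method: str = "kspace") -> DynamicSeries:
    """Zero-fill interpolate every frame to ``out_size`` x ``out_size`` and
    apply the stated rigid orientation operations identically to all frames.

    Non-square acquisitions (e.g. the half-scan 44x43 grid) are first
    zero-padded to square in the image domain.  ``method="bilinear"`` is an
    image-domain fallback using spline interpolation.
    """
    f, r, c = series.frames.shape
    if r > out_size or c > out_size:
        raise ValueError(f"raw grid {r}x{c} is larger than target {out_size}")

    side = max(r, c)
    frames = series.frames
    if r != c:  # pad to square before the FFT
        sq = np.zeros((f, side, side))
        sq[:, :r, :c] = frames
        frames = sq

    out = np.empty((f, out_size, out_size))
    if method == "kspace":
        for i in range(f):
            out[i] = _kspace_resample(frames[i], out_size)
    elif method == "bilinear":
        from scipy.ndimage import zoom
        for i in range(f):
            out[i] = zoom(frames[i], out_size / side, order=1,
                          grid_mode=True, mode="nearest")
    else:
        raise ValueError(f"unknown method {method!r}")

    for i in range(f):
        frame = np.rot90(out[i], k=rot90)
        if flip_lr:
            frame = np.fliplr(frame)
        if flip_ud:
            frame = np.flipud(frame)
        out[i] = frame

    return replace(series, frames=out)


def flip_angle_correct(series: DynamicSeries) -> DynamicSeries:
    """Divide every voxel by sin(flip angle); errors on double correction."""
    if series.flip_corrected:
        raise ValueError(f"series {series.metabolite!r} is already "
                         "flip-angle corrected")
    factor = 1.0 / np.sin(np.deg2rad(series.flip_angle))
    return replace(series, frames=series.frames * factor, flip_corrected=True)


def estimate_noise(series: DynamicSeries,
                   baseline_frames,
                   region: np.ndarray) -> NoiseEstimate:
    """Estimate the noise standard deviation from baseline (signal-free)
    frames over a spatial region.

    Each baseline frame's region mean is subtracted first, making the
    estimate invariant to constant offsets; sigma pools the demeaned
    samples with the appropriate degrees of freedom.  A single-voxel
    region falls back to the plain temporal sample SD.
    """
    baseline_frames = tuple(int(i) for i in baseline_frames)
    if len(baseline_frames) < 2:
        raise ValueError("need at least 2 baseline frames")
    region = np.asarray(region, dtype=bool)
    n_vox = int(region.sum())
    if n_vox == 0:
        raise ValueError("noise region is empty")

    samples = series.frames[list(baseline_frames)][:, region]  # (F, V)
    if n_vox == 1:
        sigma = float(np.std(samples.ravel(), ddof=1))
    else:
        dev = samples - samples.mean(axis=1, keepdims=True)
        dof = samples.size - len(baseline_frames)
        sigma = float(np.sqrt((dev ** 2).sum() / dof))
    if sigma <= 0:
        raise ValueError("degenerate baseline: zero variance")
    return NoiseEstimate(sigma=sigma, source_frames=baseline_frames,
                         source_region=region)


def snr_curve(series: DynamicSeries, mask: np.ndarray,
              noise: NoiseEstimate) -> SnrCurve:
    """Voxel-wise SNR averaged over ``mask`` per frame, with trapezoidal
    AUC at unit frame spacing.  Requires a flip-angle corrected series."""
    if not series.flip_corrected:
        raise ValueError("snr_curve requires a flip-angle corrected series")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    values = series.frames[:, mask].mean(axis=1) / noise.sigma
    return SnrCurve(values=values, auc=float(np.trapezoid(values)))


def sum_pyruvate(series: DynamicSeries) -> np.ndarray:
    """Voxel-wise sum of all dynamic frames."""
    return series.frames.sum(axis=0)


def metabolic_outcome(lac: DynamicSeries, bic: DynamicSeries,
                      mid_myo: np.ndarray, noise: NoiseEstimate) -> float:
    """Combined AUC of the lactate and bicarbonate mean-SNR curves over the
    mid-myocardial mask."""
    if lac.n_frames != bic.n_frames:
        raise ValueError(f"lactate ({lac.n_frames}) and bicarbonate "
                         f"({bic.n_frames}) frame counts differ")
    mid_myo = np.asarray(mid_myo, dtype=bool)
    if not mid_myo.any():
        raise ValueError("mid-myocardial mask is empty")
    return snr_curve(lac, mid_myo, noise).auc + snr_curve(bic, mid_myo, noise).auc
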