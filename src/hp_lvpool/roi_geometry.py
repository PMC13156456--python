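"""Elliptical ROI mask construction on the analysis grid.

The left-ventricular region set is parameterized by a single epicardial
ellipse.  The endocardial contour is the same ellipse with both semi-axes
scaled down, the myocardium is the band between the two, and the
mid-myocardial band is the myocardium eroded from both boundaries.
Membership is decided per voxel center (no partial voxels), 0-based
(row, col) coordinates, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaskSet", "build_masks", "downsample_reference"]


@dataclass(frozen=True)
class MaskSet:
    """Boolean masks of the four cardiac regions on a square grid.

    Invariants: ``endo`` is a subset of ``epic``, ``myo = epic & ~endo``,
    ``mid_myo`` is a subset of ``myo``, and all four masks are non-empty.
    """

    epic: np.ndarray
    endo: np.ndarray
    myo: np.ndarray
    mid_myo: np.ndarray
    grid_size: int

    def __post_init__(self) -> None:
        for name in ("epic", "endo", "myo", "mid_myo"):
            m = getattr(self, name)
            if m.shape != (self.grid_size, self.grid_size):
                raise ValueError(f"mask {name!r} has shape {m.shape}, "
                                 f"expected ({self.grid_size}, {self.grid_size})")
            if m.dtype != bool:
                raise ValueError(f"mask {name!r} must be boolean")
            if not m.any():
                raise ValueError(f"mask {name!r} is empty")
        if (self.endo & ~self.epic).any():
            raise ValueError("endo mask extends outside epic mask")
        if (self.mid_myo & ~self.myo).any():
            raise ValueError("mid_myo mask extends outside myo mask")


def _ellipse_mask(center: tuple[float, float],
                  semi_axes: tuple[float, float],
                  angle_deg: float,
                  grid_size: int) -> np.ndarray:
    """Voxels whose centers lie inside (inclusive) the rotated ellipse."""
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise ValueError(f"semi-axes must be positive, got {semi_axes}")
    theta = np.deg2rad(angle_deg)
    rows, cols = np.mgrid[0:grid_size, 0:grid_size].astype(float)
    dr = rows - center[0]
    dc = cols - center[1]
    # rotate into the ellipse frame
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _check_inside_grid(center: tuple[float, float],
                       semi_axes: tuple[float, float],
                       angle_deg: float,
                       grid_size: int) -> None:
    a, b = semi_axes
    theta = np.deg2rad(angle_deg)
    # bounding-box half extents of the rotated ellipse
    half_r = np.hypot(a * np.cos(theta), b * np.sin(theta))
    half_c = np.hypot(a * np.sin(theta), b * np.cos(theta))
    if (center[0] - half_r < 0 or center[0] + half_r > grid_size - 1
            or center[1] - half_c < 0 or center[1] + half_c > grid_size - 1):
        raise ValueError(
            f"ellipse (center={center}, semi_axes={semi_axes}, "
            f"angle={angle_deg}) does not fit inside a {grid_size}x{grid_size} grid")


def build_masks(center: tuple[float, float],
                semi_axes: tuple[float, float],
                angle: float = 0.0,
                endo_scale: float = 0.80,
                mid_myo_shrink: float = 0.10,
                grid_size: int = 100) -> MaskSet:
    """Construct epicardial / endocardial / myocardial / mid-myocardial masks.

    Parameters
    ----------
    center
        (row, col) of the epicardial ellipse center, in voxel coordinates.
    semi_axes
        (row semi-axis, col semi-axis) of the epicardial ellipse, voxels.
    angle
        In-plane rotation of the ellipse, degrees.
    endo_scale
        Factor in (0, 1) applied to both semi-axes to obtain the
        endocardial ellipse.
    mid_myo_shrink
        Fraction in [0, 0.5) of the per-axis band half-width by which each
        myocardial boundary is moved toward the band mid-line to form the
        mid-myocardial mask.
    grid_size
        Side of the square analysis grid.

    Returns
    -------
    MaskSet
    """
    if not 0.0 < endo_scale < 1.0:
        raise ValueError(f"endo_scale must be in (0, 1), got {endo_scale}")
    if not 0.0 <= mid_myo_shrink < 0.5:
        raise ValueError(f"mid_myo_shrink must be in [0, 0.5), got {mid_myo_shrink}")
    _check_inside_grid(center, semi_axes, angle, grid_size)

    a, b = semi_axes
    epic = _ellipse_mask(center, (a, b), angle, grid_size)
    if not epic.any():
        raise ValueError("epicardial ellipse interior contains no voxel centers")

    a_e, b_e = a * endo_scale, b * endo_scale
    endo = _ellipse_mask(center, (a_e, b_e), angle, grid_size)
    if not endo.any():
        raise ValueError(
            f"endocardial mask is empty at endo_scale={endo_scale}")

    myo = epic & ~endo
    if not myo.any():
        raise ValueError(
            f"myocardial band is empty (endo_scale={endo_scale} too close to 1)")

    # erode both band boundaries toward the mid-line by mid_myo_shrink of
    # the per-axis half-width
    h_a = (a - a_e) / 2.0
    h_b = (b - b_e) / 2.0
    outer = _ellipse_mask(center, (a - mid_myo_shrink * h_a,
                                   b - mid_myo_shrink * h_b), angle, grid_size)
    inner = _ellipse_mask(center, (a_e + mid_myo_shrink * h_a,
                                   b_e + mid_myo_shrink * h_b), angle, grid_size)
    mid_myo = outer & ~inner
    if not mid_myo.any():
        raise ValueError("mid-myocardial band is empty after erosion")

    return MaskSet(epic=epic, endo=endo, myo=myo, mid_myo=mid_myo,
                   grid_size=grid_size)


def downsample_reference(image: np.ndarray, out_size: int = 100,
                         method: str = "area") -> np.ndarray:
    """Resample a square high-resolution reference image to the analysis grid.

    ``method="area"`` uses exact area-weighted rebinning (pixel-interval
    overlap), which conserves the mean intensity exactly for any input/output
    size ratio and reduces to block averaging when the ratio is an integer.
    ``method="zoom"`` uses spline interpolation as a configurable fallback.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square 2D image, got shape {image.shape}")
    side = image.shape[0]
    if side < out_size:
        raise ValueError(f"input side {side} is smaller than target {out_size}")

    if method == "zoom":
        from scipy.ndimage import zoom
        return zoom(image, out_size / side, order=1, grid_mode=True,
                    mode="nearest")
    if method != "area":
        raise ValueError(f"unknown method {method!r}")

    f = side / out_size  # input pixels per output cell
    # overlap of output cell i = [i*f, (i+1)*f) with input pixel j = [j, j+1)
    w = np.zeros((out_size, side))
    for i in range(out_size):
        lo, hi = i * f, (i + 1) * f
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, side)):
            w[i, j] = max(0.0, min(hi, j + 1) - max(lo, j))
    w /= f  # rows sum to 1 -> mean-preserving
    return w @ image @ w.T
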