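"""Intensity normalisation and background-removal operators.

One operator per technique used by the emulated software pipelines:
min-max rescaling and median filtering (CellProfiler), slice-wise
rolling-ball subtraction (Fiji, GA3), z-intensity equalisation (GA3,
Imaris), Laplacian-of-Gaussian enhancement (GA3), and
subtract-large-Gaussian background removal (Imaris).

All subtraction operators clip at zero and never exceed the input
pointwise. Every operator logs its resolved voxel-unit parameters at
DEBUG level.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu as _sk_otsu
from skimage.restoration import rolling_ball as _sk_rolling_ball
from skimage.transform import resize as _sk_resize

from .core import Length, VoxelGeometry, parse_length

__all__ = [
    "rescale_intensity",
    "median_filter",
    "rolling_ball_subtract",
    "equalize_z",
    "EqualizeResult",
    "gaussian_laplace",
    "gaussian_background_subtract",
]

log = logging.getLogger(__name__)


def rescale_intensity(grid: np.ndarray) -> np.ndarray:
    """Affinely map intensities to the full [0, 1] range.

    The minimum maps to 0 and the maximum to 1. A constant grid maps to
    all-zeros (the degenerate case has no dynamic range to stretch).
    """
    grid = np.asarray(grid, dtype=np.float64)
    if not np.all(np.isfinite(grid)):
        raise ValueError("rescale_intensity requires a finite grid")
    lo = grid.min()
    hi = grid.max()
    if hi == lo:
        return np.zeros_like(grid)
    return (grid - lo) / (hi - lo)


def median_filter(grid: np.ndarray, size: int) -> np.ndarray:
    """Median filter over a cubic ``size³`` neighbourhood, reflected edges.

    ``size`` must be odd so the neighbourhood is centred; size 1 is the
    identity.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError(f"median filter size must be odd and >= 1, got {size}")
    grid = np.asarray(grid)
    if size == 1:
        return grid.copy()
    return ndi.median_filter(grid, size=size, mode="reflect")


# -- rolling ball ------------------------------------------------------------

# Above this radius the exact non-flat opening becomes quadratic in the
# radius; larger radii use the shrink/restore strategy of ImageJ's
# "Subtract Background" (downscale, roll the ball on the small image,
# upscale the background). The crossover keeps the exact path for every
# radius a desk-scale oracle can check.
_EXACT_RADIUS_LIMIT = 16.0


def _slice_background(img: np.ndarray, radius_px: float) -> np.ndarray:
    if radius_px <= _EXACT_RADIUS_LIMIT:
        return _sk_rolling_ball(img, radius=radius_px)
    shrink = max(2, int(np.ceil(radius_px / 8.0)))
    small_shape = (max(1, img.shape[0] // shrink), max(1, img.shape[1] // shrink))
    # min-pool before shrinking so bright structures cannot leak into the
    # background estimate, then roll the ball at the reduced radius
    small = _sk_resize(
        ndi.minimum_filter(img, size=shrink, mode="reflect"),
        small_shape, order=1, anti_aliasing=False, preserve_range=True,
    )
    bg_small = _sk_rolling_ball(small, radius=radius_px / shrink)
    bg = _sk_resize(bg_small, img.shape, order=1, anti_aliasing=False,
                    preserve_range=True)
    return np.minimum(bg, img)


def rolling_ball_subtract(
    grid: np.ndarray,
    radius: Length | str | float,
    geometry: VoxelGeometry | None = None,
    mode: str = "slicewise",
) -> np.ndarray:
    """Slice-wise rolling-ball background subtraction.

    The background of each z-slice is the grayscale opening with a
    ball-shaped (non-flat) structuring element of the given radius; the
    output is the slice minus its background, clipped at zero. The radius
    carries a unit tag: pixels (Fiji convention) need no geometry,
    µm-denominated radii (GA3 convention) are converted through the
    supplied :class:`~pseudoislet3d.core.VoxelGeometry`.
    """
    if mode != "slicewise":
        raise ValueError(f"unsupported mode {mode!r}")
    radius = parse_length(radius)
    if radius.unit == "um" and geometry is None:
        raise ValueError("µm-denominated radius requires a geometry")
    radius_px = radius.to_pixels(geometry, "xy") if radius.unit == "um" else radius.value
    if radius_px < 1.0:
        raise ValueError(
            f"rolling-ball radius {radius} resolves to {radius_px:.3f} px (< 1 pixel)"
        )
    log.debug("rolling_ball_subtract: radius=%s -> %.2f px", radius, radius_px)
    grid = np.asarray(grid, dtype=np.float64)
    out = np.empty_like(grid)
    for k in range(grid.shape[0]):
        sl = grid[k]
        if sl.max() == sl.min():  # constant slice: background is the slice itself
            out[k] = 0.0
            continue
        out[k] = sl - _slice_background(sl, radius_px)
    return np.clip(out, 0.0, None)


# -- z equalisation ----------------------------------------------------------


class EqualizeResult(NamedTuple):
    grid: np.ndarray
    report: pd.DataFrame  # per-slice: robust_centre, scale, flagged


def _robust_centre(sl: np.ndarray) -> float | None:
    """Median of the voxels above the slice's Otsu threshold, or None."""
    if sl.max() == sl.min():
        return None
    thr = _sk_otsu(sl.ravel())
    fg = sl[sl > thr]
    if fg.size == 0:
        return None
    return float(np.median(fg))


def equalize_z(grid: np.ndarray) -> EqualizeResult:
    """Equalise foreground intensity across z-slices.

    Each slice is multiplicatively rescaled so its robust centre (median
    of voxels above the slice's Otsu threshold) matches the
    brightest-reference slice, compensating the depth-dependent signal
    loss of thick-sample imaging. Slices with empty foreground are left
    unscaled and flagged in the returned per-slice report.
    """
    grid = np.asarray(grid, dtype=np.float64)
    centres = [_robust_centre(grid[k]) for k in range(grid.shape[0])]
    valid = [c for c in centres if c is not None and c > 0]
    out = grid.copy()
    rows = []
    reference = max(valid) if valid else None
    for k, c in enumerate(centres):
        flagged = c is None or c <= 0 or reference is None
        scale = 1.0 if flagged else reference / c
        if not flagged:
            out[k] = grid[k] * scale
        rows.append({"slice": k, "robust_centre": np.nan if c is None else c,
                     "scale": scale, "flagged": flagged})
    report = pd.DataFrame(rows, columns=["slice", "robust_centre", "scale", "flagged"])
    log.debug("equalize_z: reference=%s, %d/%d slices flagged",
              reference, int(report["flagged"].sum()), len(report))
    return EqualizeResult(out, report)


# -- blob enhancement and Gaussian high-pass ---------------------------------


def gaussian_laplace(grid: np.ndarray, sigma: float) -> np.ndarray:
    """Negated slice-wise Laplacian-of-Gaussian response.

    Computed in 2D per z-slice with the given sigma in pixels and
    sign-flipped so bright blobs give positive peaks; the response of a
    blob is maximal when its scale matches sigma. Each slice's mean is
    subtracted first, which makes the response exactly offset-invariant
    (a derivative filter's truncated kernel otherwise leaks a small DC
    term) and a constant grid maps to exact zeros.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    grid = np.asarray(grid, dtype=np.float64)
    out = np.empty_like(grid)
    for k in range(grid.shape[0]):
        sl = grid[k]
        out[k] = -ndi.gaussian_laplace(sl - sl.mean(), sigma=sigma, mode="reflect")
    return out


def gaussian_background_subtract(
    grid: np.ndarray, length_um: float, geometry: VoxelGeometry
) -> np.ndarray:
    """High-pass filter: subtract a wide Gaussian blur of the grid.

    Structures wider than roughly ``length_um`` are treated as background
    (sigma = length/2 per axis, converted to anisotropic voxel units);
    the result is clipped at zero. A length resolving to under half a
    voxel in every axis degenerates to subtracting the grid from itself;
    that case warns and returns zeros.
    """
    if not length_um > 0:
        raise ValueError(f"length must be > 0, got {length_um}")
    grid = np.asarray(grid, dtype=np.float64)
    sigma_um = length_um / 2.0
    sigma_vox = (sigma_um / geometry.z_step,
                 sigma_um / geometry.pixel_size_xy,
                 sigma_um / geometry.pixel_size_xy)
    if max(sigma_vox) < 0.5:
        log.warning(
            "gaussian_background_subtract: length %.3g µm is below one voxel; "
            "background equals the image and the output is all zeros", length_um
        )
        return np.zeros_like(grid)
    log.debug("gaussian_background_subtract: length=%.3g µm -> sigma(z,y,x)=%s vox",
              length_um, tuple(round(s, 2) for s in sigma_vox))
    background = _wide_gaussian(grid, sigma_vox)
    return np.clip(grid - background, 0.0, None)


def _wide_gaussian(grid: np.ndarray, sigma_vox: tuple[float, ...]) -> np.ndarray:
    """Gaussian blur; very wide kernels run on a downscaled grid.

    A background estimate at sigma of tens of voxels carries no detail
    finer than sigma, so blurring a 1/s-scale copy with sigma/s and
    resampling back is equivalent to working at full resolution while
    cutting the cost by s^3.
    """
    s_min = min(sigma_vox)
    if s_min <= 8.0:
        return ndi.gaussian_filter(grid, sigma=sigma_vox, mode="reflect")
    shrink = int(min(s_min / 4.0, min(grid.shape) / 16.0))
    if shrink < 2:
        return ndi.gaussian_filter(grid, sigma=sigma_vox, mode="reflect")
    small_shape = tuple(max(4, d // shrink) for d in grid.shape)
    small = _sk_resize(grid, small_shape, order=1, anti_aliasing=True,
                       preserve_range=True)
    small = ndi.gaussian_filter(
        small, sigma=tuple(s / shrink for s in sigma_vox), mode="reflect"
    )
    return _sk_resize(small, grid.shape, order=1, anti_aliasing=False,
                      preserve_range=True)
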