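"""Image preparation: contours → masks, resampling, normalization, discretization.

The preprocessing chain applied to every native T1 map before texture
analysis is: rasterize the endo/epi contours to an annular myocardial mask,
resample image and mask to a common pixel spacing (1.17 mm, bilinear for the
image, nearest-neighbour for the mask), clip in-mask intensities to
``mu ± 3*sigma`` of the in-mask distribution, and discretize the in-mask
range into a fixed number of equal-width gray levels.  Each filtered variant
of the image is discretized independently with the same rule.

Coordinates: contours are in millimetres, with pixel (r, c) centred at
``(r * row_spacing, c * col_spacing)``; image indices are 0-based, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

DEFAULT_TARGET_SPACING = 1.17  # mm, common grid for all cases
DEFAULT_N_BINS = 32


class GeometryError(ValueError):
    """Raised for degenerate contour geometry (empty ring, endo outside epi)."""


@dataclass
class T1Map:
    """A 2D native T1 parametric map in milliseconds."""

    pixels: np.ndarray  # (rows, cols), float, ms
    spacing: tuple[float, float]  # (row_mm, col_mm)
    case_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("T1Map requires a non-empty 2D pixel grid")
        if min(self.spacing) <= 0:
            raise ValueError("pixel spacing must be positive")


@dataclass
class ContourSet:
    """Endocardial and epicardial polygons, vertices in mm (x=col, y=row)."""

    endo: np.ndarray  # (n, 2)
    epi: np.ndarray  # (m, 2)

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        for name, poly in (("endo", self.endo), ("epi", self.epi)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"{name} contour needs >= 3 (x, y) vertices")


@dataclass
class MyocardialMask:
    """Boolean annulus aligned to a T1Map grid."""

    mask: np.ndarray  # (rows, cols) bool
    spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class NormalizationParams:
    mu: float
    sigma: float
    degenerate: bool = False  # sigma == 0 (constant in-mask image)


@dataclass
class DiscretizedImage:
    """Integer gray levels 1..n_levels on in-mask pixels (0 outside)."""

    levels: np.ndarray  # int, 0 outside mask
    n_levels: int
    mask: np.ndarray = field(repr=False, default=None)


def _points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd rule by horizontal ray casting, vectorised over points.

    Edge convention: an edge contributes a crossing iff the ray from the
    point towards +x strictly crosses it (half-open in y, strict in x), so
    the result is deterministic for points on polygon edges.
    """
    px = points[:, 0][:, None]
    py = points[:, 1][:, None]
    x1, y1 = polygon[:, 0][None, :], polygon[:, 1][None, :]
    x2 = np.roll(polygon[:, 0], -1)[None, :]
    y2 = np.roll(polygon[:, 1], -1)[None, :]
    straddles = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
    crossings = straddles & (px < x_cross)
    return (crossings.sum(axis=1) % 2).astype(bool)


def rasterize_ring_mask(
    contours: ContourSet,
    grid_shape: tuple[int, int],
    spacing: tuple[float, float],
) -> MyocardialMask:
    """Rasterize endo/epi contours to the annular myocardial mask.

    A pixel belongs to the myocardium iff its centre lies inside the
    epicardial polygon and not inside the endocardial polygon (even-odd
    rule).  Raises :class:`GeometryError` for an empty ring or when the
    endocardial contour is not contained in the epicardial one.
    """
    rows, cols = grid_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    centers = np.column_stack([cc.ravel() * spacing[1], rr.ravel() * spacing[0]])
    in_epi = _points_in_polygon(centers, contours.epi)
    in_endo = _points_in_polygon(centers, contours.endo)
    if np.any(in_endo & ~in_epi):
        raise GeometryError("endocardial contour extends outside the epicardial one")
    ring = (in_epi & ~in_endo).reshape(rows, cols)
    if not ring.any():
        raise GeometryError("rasterized myocardial ring is empty")
    return MyocardialMask(mask=ring, spacing=tuple(spacing))


def resample(
    t1map: T1Map,
    mask: MyocardialMask,
    target_spacing: float = DEFAULT_TARGET_SPACING,
) -> tuple[T1Map, MyocardialMask]:
    """Resample image (bilinear) and mask (nearest) to an isotropic spacing."""
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    sr, sc = t1map.spacing
    if np.isclose(sr, target_spacing) and np.isclose(sc, target_spacing):
        return t1map, mask
    rows, cols = t1map.pixels.shape
    new_rows = max(2, int(np.floor((rows - 1) * sr / target_spacing)) + 1)
    new_cols = max(2, int(np.floor((cols - 1) * sc / target_spacing)) + 1)
    r_idx = np.arange(new_rows) * target_spacing / sr
    c_idx = np.arange(new_cols) * target_spacing / sc
    coords = np.meshgrid(r_idx, c_idx, indexing="ij")
    img = ndimage.map_coordinates(t1map.pixels, coords, order=1, mode="nearest")
    msk = ndimage.map_coordinates(
        mask.mask.astype(np.uint8), coords, order=0, mode="constant"
    ).astype(bool)
    out_map = T1Map(img, (target_spacing, target_spacing), t1map.case_id)
    return out_map, MyocardialMask(msk, (target_spacing, target_spacing))


def normalize_mu3sigma(
    t1map: T1Map, mask: MyocardialMask
) -> tuple[T1Map, NormalizationParams]:
    """Clip in-mask intensities to ``[mu - 3 sigma, mu + 3 sigma]``.

    mu and sigma are the mean and (population) standard deviation of the
    gray levels inside the myocardium.  A constant in-mask image is passed
    through unchanged with the degeneracy flagged.
    """
    vals = t1map.pixels[mask.mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    mu = float(vals.mean())
    sigma = float(vals.std())
    if sigma == 0.0:
        return t1map, NormalizationParams(mu=mu, sigma=0.0, degenerate=True)
    out = t1map.pixels.copy()
    out[mask.mask] = np.clip(vals, mu - 3 * sigma, mu + 3 * sigma)
    return (
        T1Map(out, t1map.spacing, t1map.case_id),
        NormalizationParams(mu=mu, sigma=sigma),
    )


def discretize(
    image: np.ndarray, mask: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> DiscretizedImage:
    """Equal-width binning of the in-mask intensity range into 1..n_bins.

    ``level(x) = min(floor((x - min) / width) + 1, n_bins)``.  A constant
    in-mask image maps to a single level (n_levels = 1).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(image, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        return DiscretizedImage(levels=levels, n_levels=1, mask=mask)
    width = (hi - lo) / n_bins
    lv = np.minimum(np.floor((vals - lo) / width).astype(np.int64) + 1, n_bins)
    levels[mask] = lv
    return DiscretizedImage(levels=levels, n_levels=n_bins, mask=mask)
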