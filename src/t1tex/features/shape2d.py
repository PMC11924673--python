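"""2D shape descriptors of the myocardial mask.

9 features computed from the mask geometry alone (in mm units).  The mesh
surface and perimeter come from marching-squares contours of the mask, so an
annular ROI counts both its outer and inner boundary in the perimeter and
subtracts the hole from the surface.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

SHAPE2D_NAMES = (
    "MeshSurface",
    "PixelSurface",
    "Perimeter",
    "PerimeterSurfaceRatio",
    "Sphericity",
    "MaximumDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
    "Elongation",
)


def _contours_mm(mask: np.ndarray, spacing: tuple[float, float]) -> list[np.ndarray]:
    padded = np.pad(mask.astype(float), 1)
    cs = measure.find_contours(padded, 0.5)
    return [(c - 1.0) * np.asarray(spacing) for c in cs]


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 1], poly[:, 0]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def shape2d_features(mask: np.ndarray, spacing: tuple[float, float]) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    area_px = float(spacing[0] * spacing[1])
    contours = _contours_mm(mask, spacing)
    # find_contours orientation: high side on the left -> holes get opposite sign
    mesh_surface = abs(sum(_signed_area(c) for c in contours))
    perimeter = float(
        sum(np.sqrt(((np.diff(c, axis=0)) ** 2).sum(axis=1)).sum() for c in contours)
    )
    rr, cc = np.nonzero(mask)
    pts = np.column_stack([rr * spacing[0], cc * spacing[1]])
    if len(pts) >= 3 and not np.allclose(pts.var(axis=0), 0):
        try:
            hull = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear masks
            hull = pts
    else:
        hull = pts
    d = hull[:, None, :] - hull[None, :, :]
    max_diam = float(np.sqrt((d**2).sum(axis=-1)).max())
    cov = np.cov(pts, rowvar=False) if len(pts) > 1 else np.zeros((2, 2))
    ev = np.sort(np.maximum(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0))
    minor, major = 4.0 * np.sqrt(ev[0]), 4.0 * np.sqrt(ev[1])
    return {
        "MeshSurface": mesh_surface,
        "PixelSurface": float(mask.sum() * area_px),
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / mesh_surface if mesh_surface > 0 else np.inf,
        "Sphericity": (
            2.0 * np.sqrt(np.pi * mesh_surface) / perimeter if perimeter > 0 else 0.0
        ),
        "MaximumDiameter": max_diam,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "Elongation": float(np.sqrt(ev[0] / ev[1])) if ev[1] > 0 else 1.0,
    }
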