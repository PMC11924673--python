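"""Construction of the five gray-level texture matrices.

All matrices operate on a :class:`~t1tex.image_prep.DiscretizedImage`-style
pair ``(levels, mask)`` where ``levels`` holds integer gray levels 1..Ng on
in-mask pixels.  Conventions (2D):

* GLCM — distance 1, the four unique 2D offsets ``(0,1), (1,1), (1,0),
  (1,-1)``, symmetric, normalized per angle; features are computed per angle
  and averaged.
* GLRLM — run counting along the same four directions, features averaged.
* GLSZM — zones are maximal 8-connected components of equal gray level.
* GLDM — dependence = number of Chebyshev-distance-1 in-mask neighbours
  whose level differs by at most ``alpha`` (default 0); the matrix is
  indexed by (gray level, dependence count + 1).
* NGTDM — 8-neighbour mean absolute differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

GLCM_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class GLCM:
    """Angle-wise symmetric normalized co-occurrence matrices."""

    matrices: list[np.ndarray]  # each (Ng, Ng), sums to 1
    n_levels: int


@dataclass
class GLRLM:
    matrices: list[np.ndarray]  # each (Ng, max_run), raw counts
    n_levels: int
    n_pixels: int


@dataclass
class GLSZM:
    z: np.ndarray  # (Ng, max_zone) zone counts
    n_levels: int
    n_pixels: int

    @property
    def n_zones(self) -> int:
        return int(self.z.sum())


@dataclass
class GLDM:
    d: np.ndarray  # (Ng, Nd) dependence counts
    n_levels: int
    n_pixels: int


@dataclass
class NGTDM:
    s: np.ndarray  # (Ng,) summed absolute differences per level
    n: np.ndarray  # (Ng,) pixel counts per level
    n_levels: int
    n_pixels: int


def _masked_levels(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    ng = int(levels[mask].max())
    return levels, mask, ng


def compute_glcm(levels: np.ndarray, mask: np.ndarray, distance: int = 1) -> GLCM:
    """Symmetric normalized GLCMs for the four 2D angles at ``distance``."""
    levels, mask, ng = _masked_levels(levels, mask)
    rows, cols = levels.shape
    mats: list[np.ndarray] = []
    for dr, dc in GLCM_OFFSETS:
        dr, dc = dr * distance, dc * distance
        r0s, r0e = max(0, -dr), rows - max(0, dr)
        c0s, c0e = max(0, -dc), cols - max(0, dc)
        a_mask = mask[r0s:r0e, c0s:c0e]
        b_mask = mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        valid = a_mask & b_mask
        if not valid.any():
            continue
        a = levels[r0s:r0e, c0s:c0e][valid] - 1
        b = levels[r0s + dr : r0e + dr, c0s + dc : c0e + dc][valid] - 1
        c = np.zeros((ng, ng), dtype=float)
        np.add.at(c, (a, b), 1.0)
        c = c + c.T
        mats.append(c / c.sum())
    if not mats:
        raise ValueError("no valid pixel pair at any GLCM offset")
    return GLCM(matrices=mats, n_levels=ng)


def _direction_lines(levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int]):
    """Yield 1D arrays of masked levels (0 = gap) along a scan direction."""
    lv = np.where(mask, levels, 0)
    dr, dc = direction
    if (dr, dc) == (0, 1):
        yield from lv
    elif (dr, dc) == (1, 0):
        yield from lv.T
    elif (dr, dc) == (1, 1):
        rows, cols = lv.shape
        for off in range(-(rows - 1), cols):
            yield np.diagonal(lv, offset=off)
    elif (dr, dc) == (1, -1):
        yield from _direction_lines(levels[:, ::-1], mask[:, ::-1], (1, 1))
    else:  # pragma: no cover - fixed direction set
        raise ValueError(f"unsupported direction {direction}")


def _runs_in_line(line: np.ndarray):
    """(level, run_length) for maximal constant nonzero runs."""
    n = len(line)
    i = 0
    while i < n:
        if line[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and line[j + 1] == line[i]:
            j += 1
        yield int(line[i]), j - i + 1
        i = j + 1


def compute_glrlm(levels: np.ndarray, mask: np.ndarray) -> GLRLM:
    """Run-length matrices for the four 2D directions."""
    levels, mask, ng = _masked_levels(levels, mask)
    max_run = max(levels.shape)
    mats = []
    for direction in GLCM_OFFSETS:
        m = np.zeros((ng, max_run), dtype=float)
        for line in _direction_lines(levels, mask, direction):
            for g, rl in _runs_in_line(np.asarray(line)):
                m[g - 1, rl - 1] += 1
        mats.append(m)
    return GLRLM(matrices=mats, n_levels=ng, n_pixels=int(mask.sum()))


_STRUCT8 = np.ones((3, 3), dtype=int)


def compute_glszm(levels: np.ndarray, mask: np.ndarray) -> GLSZM:
    """Size-zone matrix: maximal 8-connected equal-level zones."""
    levels, mask, ng = _masked_levels(levels, mask)
    np_pixels = int(mask.sum())
    zones: list[tuple[int, int]] = []
    for g in range(1, ng + 1):
        lab, nlab = ndimage.label((levels == g) & mask, structure=_STRUCT8)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((g, int(s)) for s in sizes)
    max_zone = max(s for _, s in zones)
    z = np.zeros((ng, max_zone), dtype=float)
    for g, s in zones:
        z[g - 1, s - 1] += 1
    return GLSZM(z=z, n_levels=ng, n_pixels=np_pixels)


_CHEB_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def compute_gldm(levels: np.ndarray, mask: np.ndarray, alpha: int = 0) -> GLDM:
    """Dependence matrix with Chebyshev distance 1 and threshold ``alpha``."""
    levels, mask, ng = _masked_levels(levels, mask)
    rows, cols = levels.shape
    dep = np.zeros(levels.shape, dtype=np.int32)
    for dr, dc in _CHEB_OFFSETS:
        r0s, r0e = max(0, -dr), rows - max(0, dr)
        c0s, c0e = max(0, -dc), cols - max(0, dc)
        nb_mask = np.zeros_like(mask)
        nb_close = np.zeros_like(mask)
        nb_mask[r0s:r0e, c0s:c0e] = mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        diff = np.abs(
            levels[r0s:r0e, c0s:c0e] - levels[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
        )
        nb_close[r0s:r0e, c0s:c0e] = diff <= alpha
        dep += (nb_mask & nb_close & mask).astype(np.int32)
    nd = int(dep[mask].max()) + 1  # dependence index j = count + 1
    d = np.zeros((ng, nd), dtype=float)
    np.add.at(d, (levels[mask] - 1, dep[mask]), 1.0)
    return GLDM(d=d, n_levels=ng, n_pixels=int(mask.sum()))


def compute_ngtdm(levels: np.ndarray, mask: np.ndarray) -> NGTDM:
    """Neighbouring gray-tone difference matrix (8-neighbour means)."""
    levels, mask, ng = _masked_levels(levels, mask)
    lv = np.where(mask, levels, 0).astype(float)
    ones = mask.astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    nb_sum = ndimage.correlate(lv, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(ones, kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    s = np.zeros(ng, dtype=float)
    n = np.zeros(ng, dtype=float)
    diffs = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    np.add.at(s, levels[valid] - 1, diffs)
    np.add.at(n, levels[valid] - 1, 1.0)
    return NGTDM(s=s, n=n, n_levels=ng, n_pixels=int(n.sum()))
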