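"""Filter bank producing the image variants used for texture extraction.

Nine variants per case: the original (normalized) image plus eight filtered
ones — gradient magnitude, square, LBP(8,1), LBP(8,2), and the four
sub-bands (LL, LH, HL, HH) of a single-level undecimated 2D discrete
wavelet transform with the Coiflet-1 kernel.  All filters preserve the grid
shape so the myocardial mask applies unchanged; every filtered image is
subsequently discretized with the same rule as the original.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import ndimage
from skimage.feature import local_binary_pattern

FILTER_NAMES = (
    "original",
    "gradient",
    "square",
    "lbp_8_1",
    "lbp_8_2",
    "wavelet_LL",
    "wavelet_LH",
    "wavelet_HL",
    "wavelet_HH",
)


def gradient_filter(image: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Spacing-aware gradient magnitude (central differences, one-sided at borders)."""
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2:
        raise ValueError("gradient filter needs at least a 2x2 image")
    gr, gc = np.gradient(image, spacing[0], spacing[1])
    return np.hypot(gr, gc)


def square_filter(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Pixel-wise square, rescaled so the (in-mask) max |output| equals the
    (in-mask) max |input|.  An all-zero image passes through unscaled."""
    image = np.asarray(image, dtype=float)
    sq = image**2
    sel = np.asarray(mask, dtype=bool) if mask is not None else np.ones_like(sq, bool)
    m = np.abs(image[sel]).max()
    if m == 0:
        return sq
    return sq * (m / sq[sel].max())


def lbp_filter(image: np.ndarray, points: int = 8, radius: int = 1) -> np.ndarray:
    """Rotation-invariant uniform LBP codes (values 0..points+1) per pixel."""
    image = np.asarray(image, dtype=float)
    if radius >= min(image.shape) / 2:
        raise ValueError("LBP radius too large for the image")
    with warnings.catch_warnings():
        # float input is intended here: codes on the normalized T1 image
        warnings.filterwarnings("ignore", message=".*local_binary_pattern.*")
        return local_binary_pattern(image, P=points, R=radius, method="uniform")


def _sep_filter(image: np.ndarray, row_taps: np.ndarray, col_taps: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(image, row_taps, axis=0, mode="reflect")
    return ndimage.correlate1d(out, col_taps, axis=1, mode="reflect")


def wavelet_subbands(image: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level undecimated 2D DWT sub-bands LL, LH, HL, HH (same shape).

    Separable application of the wavelet's decomposition filters without
    downsampling, symmetric boundary handling.  First letter = row (vertical)
    filter, second = column (horizontal): LH responds to horizontal edges
    changing along columns, HL along rows.
    """
    image = np.asarray(image, dtype=float)
    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo)[::-1]  # pywt stores taps for convolution
    hi = np.asarray(w.dec_hi)[::-1]
    if min(image.shape) < lo.size:
        raise ValueError("image smaller than the wavelet filter support")
    return {
        "LL": _sep_filter(image, lo, lo),
        "LH": _sep_filter(image, lo, hi),
        "HL": _sep_filter(image, hi, lo),
        "HH": _sep_filter(image, hi, hi),
    }


def apply_filter_bank(
    image: np.ndarray,
    spacing: tuple[float, float] = (1.0, 1.0),
    mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """All nine image variants, keyed by filter name."""
    bands = wavelet_subbands(image)
    return {
        "original": np.asarray(image, dtype=float),
        "gradient": gradient_filter(image, spacing),
        "square": square_filter(image, mask),
        "lbp_8_1": lbp_filter(image, 8, 1),
        "lbp_8_2": lbp_filter(image, 8, 2),
        "wavelet_LL": bands["LL"],
        "wavelet_LH": bands["LH"],
        "wavelet_HL": bands["HL"],
        "wavelet_HH": bands["HH"],
    }
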