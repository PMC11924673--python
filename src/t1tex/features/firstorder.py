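"""First-order (histogram) statistics of the in-mask intensity distribution.

18 features.  Intensity-domain statistics use the raw (normalized) in-mask
values; Entropy and Uniformity use the discretized gray-level histogram, so
they are bounded by the number of gray levels.  Variance, skewness and
kurtosis use population (biased) moments; kurtosis is not excess-corrected.
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    image: np.ndarray,
    mask: np.ndarray,
    levels: np.ndarray,
    pixel_area_mm2: float = 1.0,
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(image, dtype=float)[mask]
    if x.size == 0:
        raise ValueError("empty mask")
    lv = np.asarray(levels)[mask]
    counts = np.bincount(lv)[1:].astype(float)
    p = counts[counts > 0] / lv.size

    mean = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    p10, p90 = np.percentile(x, [10, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if robust.size == 0:  # tiny ROIs: the percentile band can be empty
        robust = x
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / sd**4)
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(pixel_area_mm2 * (x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
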