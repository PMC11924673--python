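"""The pinned feature catalog: 102 features x 9 image variants = 918.

Single source of truth for feature names.  Full feature names follow the
schema ``<filter>__<family>__<feature>``.
"""

from __future__ import annotations

from ..filters import FILTER_NAMES
from .firstorder import FIRSTORDER_NAMES
from .shape2d import SHAPE2D_NAMES

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

FAMILY_NAMES: dict[str, tuple[str, ...]] = {
    "shape2d": SHAPE2D_NAMES,  # 9
    "firstorder": FIRSTORDER_NAMES,  # 18
    "glcm": GLCM_NAMES,  # 24
    "gldm": GLDM_NAMES,  # 14
    "glrlm": GLRLM_NAMES,  # 16
    "glszm": GLSZM_NAMES,  # 16
    "ngtdm": NGTDM_NAMES,  # 5
}

FAMILY_SIZES = {fam: len(names) for fam, names in FAMILY_NAMES.items()}

FEATURES_PER_VARIANT = sum(FAMILY_SIZES.values())  # 102


def full_catalog() -> list[str]:
    """All 918 feature names in canonical order (filter-major)."""
    return [
        f"{filt}__{fam}__{name}"
        for filt in FILTER_NAMES
        for fam, names in FAMILY_NAMES.items()
        for name in names
    ]


N_FEATURES = len(FILTER_NAMES) * FEATURES_PER_VARIANT  # 918
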