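"""End-to-end feature extraction for a single case.

Pipeline order: rasterize contours -> resample to the common spacing ->
clip to mu +/- 3 sigma -> apply the filter bank -> discretize each variant
independently -> compute the seven feature families per variant.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from .. import image_prep as prep
from ..filters import apply_filter_bank
from . import families
from .catalog import FAMILY_NAMES, full_catalog
from .firstorder import firstorder_features
from .matrices import (
    compute_glcm,
    compute_gldm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
)
from .shape2d import shape2d_features

logger = logging.getLogger(__name__)


def extract_variant(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float],
    n_bins: int = prep.DEFAULT_N_BINS,
) -> dict[str, float]:
    """The 102 features of one image variant (keys ``<family>__<feature>``)."""
    disc = prep.discretize(image, mask, n_bins=n_bins)
    values: dict[str, float] = {}
    values.update(
        {f"shape2d__{k}": v for k, v in shape2d_features(mask, spacing).items()}
    )
    fo = firstorder_features(image, mask, disc.levels, spacing[0] * spacing[1])
    values.update({f"firstorder__{k}": v for k, v in fo.items()})
    lv, mk = disc.levels, disc.mask
    values.update(
        {f"glcm__{k}": v for k, v in families.glcm_features(compute_glcm(lv, mk)).items()}
    )
    values.update(
        {f"gldm__{k}": v for k, v in families.gldm_features(compute_gldm(lv, mk)).items()}
    )
    values.update(
        {
            f"glrlm__{k}": v
            for k, v in families.glrlm_features(compute_glrlm(lv, mk)).items()
        }
    )
    values.update(
        {
            f"glszm__{k}": v
            for k, v in families.glszm_features(compute_glszm(lv, mk)).items()
        }
    )
    values.update(
        {
            f"ngtdm__{k}": v
            for k, v in families.ngtdm_features(compute_ngtdm(lv, mk)).items()
        }
    )
    return values


def extract_all(
    t1map: prep.T1Map,
    contours: prep.ContourSet,
    target_spacing: float = prep.DEFAULT_TARGET_SPACING,
    n_bins: int = prep.DEFAULT_N_BINS,
) -> dict[str, float]:
    """The full 918-feature vector for one case.

    Degenerate ROIs (constant after normalization) still yield a complete
    vector via the per-feature limit conventions; an empty ROI raises.
    """
    t0 = time.perf_counter()
    mask = prep.rasterize_ring_mask(contours, t1map.pixels.shape, t1map.spacing)
    t1map, mask = prep.resample(t1map, mask, target_spacing)
    norm, params = prep.normalize_mu3sigma(t1map, mask)
    if params.degenerate:
        logger.warning("case %s: constant in-mask image", t1map.case_id)
    variants = apply_filter_bank(norm.pixels, norm.spacing, mask.mask)
    features: dict[str, float] = {}
    for filt, img in variants.items():
        vals = extract_variant(img, mask.mask, norm.spacing, n_bins=n_bins)
        features.update({f"{filt}__{k}": v for k, v in vals.items()})
    catalog = full_catalog()
    missing = set(catalog) - set(features)
    if missing:
        raise RuntimeError(f"incomplete feature vector: missing {sorted(missing)[:5]}")
    features = {name: features[name] for name in catalog}
    logger.info(
        "case %s: %d features in %.2f s",
        t1map.case_id,
        len(features),
        time.perf_counter() - t0,
    )
    return features


def extract_case(case, **kwargs) -> dict[str, float]:
    """Extract features from a :class:`~t1tex.synthetic.SyntheticCase`."""
    return extract_all(case.t1_map, case.contours, **kwargs)
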