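"""Feature formulas for the five matrix families.

Each ``*_features`` function maps a matrix object from
:mod:`t1tex.features.matrices` to an ordered ``{name: value}`` dict whose
keys are pinned by the catalog (24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM,
5 NGTDM).  Angle-dependent families (GLCM, GLRLM) compute every feature per
angle and average.  Degenerate single-level regions follow limit
conventions: entropy-like features are 0, homogeneity-like features
(Id*, correlation-like) are 1.
"""

from __future__ import annotations

import numpy as np

from .matrices import GLCM, GLDM, GLRLM, GLSZM, NGTDM

_EPS = np.spacing(1.0)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------- GLCM


def _glcm_single(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sigx = float(np.sqrt((((i - ux) ** 2) * px).sum()))
    sigy = float(np.sqrt((((i - uy) ** 2) * py).sum()))

    # distributions of i+j (2..2Ng) and |i-j| (0..Ng-1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    ks = np.arange(2, 2 * ng + 1)
    kd = np.arange(ng)

    corr_num = float((ii * jj * p).sum()) - ux * uy
    correlation = 1.0 if sigx * sigy == 0 else corr_num / (sigx * sigy)

    hx = _entropy(px)
    hy = _entropy(py)
    hxy = _entropy(p)
    pxpy = np.outer(px, py)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz] + _EPS)).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    imc1 = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: second-largest eigenvalue of Q on the support of px/py
    present = px > 0
    if present.sum() < 2:
        mcc = 1.0
    else:
        psub = p[np.ix_(present, present)]
        q = (psub / px[present][:, None]) @ (psub / py[present][None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, ev[-2])))

    da = float((kd * p_diff).sum())
    off = ii != jj
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float((((ii + jj - ux - uy) ** 4) * p).sum()),
        "ClusterShade": float((((ii + jj - ux - uy) ** 3) * p).sum()),
        "ClusterTendency": float((((ii + jj - ux - uy) ** 2) * p).sum()),
        "Contrast": float((((ii - jj) ** 2) * p).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float((((kd - da) ** 2) * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) ** 2) / ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p[off] / ((ii - jj)[off] ** 2)).sum()),
        "JointAverage": ux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((ks * p_sum).sum()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float((((i - ux) ** 2) * px).sum()),
    }


def glcm_features(glcm: GLCM) -> dict[str, float]:
    per_angle = [_glcm_single(p, glcm.n_levels) for p in glcm.matrices]
    return {k: float(np.mean([a[k] for a in per_angle])) for k in per_angle[0]}


def glcm_idmn(glcm: GLCM) -> float:
    """Inverse difference moment normalized, averaged over angles."""
    return glcm_features(glcm)["Idmn"]


def glcm_sum_entropy(glcm: GLCM) -> float:
    """Entropy of the distribution of co-occurring gray-level sums."""
    return glcm_features(glcm)["SumEntropy"]


# ------------------------------------------------- size/run/dependence


def _weighted_stats(m: np.ndarray) -> dict[str, float]:
    """Shared emphasis/nonuniformity stats for a (level x size)-type matrix."""
    n = m.sum()
    i = np.arange(1, m.shape[0] + 1, dtype=float)
    j = np.arange(1, m.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = m / n
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((i * pi).sum())
    mu_j = float((j * pj).sum())
    return {
        "small_j": float((p / jj**2).sum()),
        "large_j": float((p * jj**2).sum()),
        "low_i": float((p / ii**2).sum()),
        "high_i": float((p * ii**2).sum()),
        "small_j_low_i": float((p / (ii**2 * jj**2)).sum()),
        "small_j_high_i": float((p * ii**2 / jj**2).sum()),
        "large_j_low_i": float((p * jj**2 / ii**2).sum()),
        "large_j_high_i": float((p * (ii * jj) ** 2).sum()),
        "gln": float((m.sum(axis=1) ** 2).sum() / n),
        "glnn": float((p.sum(axis=1) ** 2).sum()),
        "jln": float((m.sum(axis=0) ** 2).sum() / n),
        "jlnn": float((p.sum(axis=0) ** 2).sum()),
        "var_i": float(((i - mu_i) ** 2 * pi).sum()),
        "var_j": float(((j - mu_j) ** 2 * pj).sum()),
        "entropy": _entropy(p.ravel()),
        "n": float(n),
    }


def glrlm_features(glrlm: GLRLM) -> dict[str, float]:
    per_angle = []
    for m in glrlm.matrices:
        s = _weighted_stats(m)
        per_angle.append(
            {
                "ShortRunEmphasis": s["small_j"],
                "LongRunEmphasis": s["large_j"],
                "GrayLevelNonUniformity": s["gln"],
                "GrayLevelNonUniformityNormalized": s["glnn"],
                "RunLengthNonUniformity": s["jln"],
                "RunLengthNonUniformityNormalized": s["jlnn"],
                "RunPercentage": s["n"] / glrlm.n_pixels,
                "GrayLevelVariance": s["var_i"],
                "RunVariance": s["var_j"],
                "RunEntropy": s["entropy"],
                "LowGrayLevelRunEmphasis": s["low_i"],
                "HighGrayLevelRunEmphasis": s["high_i"],
                "ShortRunLowGrayLevelEmphasis": s["small_j_low_i"],
                "ShortRunHighGrayLevelEmphasis": s["small_j_high_i"],
                "LongRunLowGrayLevelEmphasis": s["large_j_low_i"],
                "LongRunHighGrayLevelEmphasis": s["large_j_high_i"],
            }
        )
    return {k: float(np.mean([a[k] for a in per_angle])) for k in per_angle[0]}


def glszm_features(glszm: GLSZM) -> dict[str, float]:
    s = _weighted_stats(glszm.z)
    return {
        "SmallAreaEmphasis": s["small_j"],
        "LargeAreaEmphasis": s["large_j"],
        "GrayLevelNonUniformity": s["gln"],
        "GrayLevelNonUniformityNormalized": s["glnn"],
        "SizeZoneNonUniformity": s["jln"],
        "SizeZoneNonUniformityNormalized": s["jlnn"],
        "ZonePercentage": glszm.n_zones / glszm.n_pixels,
        "GrayLevelVariance": s["var_i"],
        "ZoneVariance": s["var_j"],
        "ZoneEntropy": s["entropy"],
        "LowGrayLevelZoneEmphasis": s["low_i"],
        "HighGrayLevelZoneEmphasis": s["high_i"],
        "SmallAreaLowGrayLevelEmphasis": s["small_j_low_i"],
        "SmallAreaHighGrayLevelEmphasis": s["small_j_high_i"],
        "LargeAreaLowGrayLevelEmphasis": s["large_j_low_i"],
        "LargeAreaHighGrayLevelEmphasis": s["large_j_high_i"],
    }


def glszm_zone_percentage(glszm: GLSZM) -> float:
    """Nz / Np — texture coarseness (1 iff every pixel is its own zone)."""
    return glszm.n_zones / glszm.n_pixels


def gldm_features(gldm: GLDM) -> dict[str, float]:
    s = _weighted_stats(gldm.d)
    return {
        "SmallDependenceEmphasis": s["small_j"],
        "LargeDependenceEmphasis": s["large_j"],
        "GrayLevelNonUniformity": s["gln"],
        "DependenceNonUniformity": s["jln"],
        "DependenceNonUniformityNormalized": s["jlnn"],
        "GrayLevelVariance": s["var_i"],
        "DependenceVariance": s["var_j"],
        "DependenceEntropy": s["entropy"],
        "LowGrayLevelEmphasis": s["low_i"],
        "HighGrayLevelEmphasis": s["high_i"],
        "SmallDependenceLowGrayLevelEmphasis": s["small_j_low_i"],
        "SmallDependenceHighGrayLevelEmphasis": s["small_j_high_i"],
        "LargeDependenceLowGrayLevelEmphasis": s["large_j_low_i"],
        "LargeDependenceHighGrayLevelEmphasis": s["large_j_high_i"],
    }


def ngtdm_features(ngtdm: NGTDM) -> dict[str, float]:
    nvp = float(ngtdm.n.sum())
    p = ngtdm.n / nvp
    s = ngtdm.s
    present = p > 0
    i = np.arange(1, ngtdm.n_levels + 1, dtype=float)
    ip, pp, sp = i[present], p[present], s[present]
    ngp = int(present.sum())

    coarse_den = float((p * s).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp <= 1:
        contrast = 0.0
    else:
        pair = float(np.sum(pp[:, None] * pp[None, :] * (ip[:, None] - ip[None, :]) ** 2))
        contrast = pair / (ngp * (ngp - 1)) * float(s.sum()) / nvp

    busy_den = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
    busyness = coarse_den / busy_den if busy_den > 0 else 0.0

    if ngp <= 1:
        complexity = 0.0
        strength = 0.0
    else:
        num = np.abs(ip[:, None] - ip[None, :]) * (
            (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
            / (pp[:, None] + pp[None, :])
        )
        complexity = float(num.sum()) / nvp
        s_num = float(
            np.sum((pp[:, None] + pp[None, :]) * (ip[:, None] - ip[None, :]) ** 2)
        )
        strength = s_num / float(s.sum()) if s.sum() > 0 else 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
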