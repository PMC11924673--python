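"""Independent brute-force oracles used by the test suite.

Everything here is written with naive loops / enumeration, deliberately
independent of the vectorised implementations in ``t1tex``: texture-matrix
builders, loop-based feature formulas, an ANOVA-decomposition ICC, an
exhaustive decision-stump search, and an adaptive Gauss-Hermite quadrature
likelihood for the random-intercept logistic model.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1)]


# ----------------------------------------------------------- matrices


def glcm_oracle(levels, mask, offset, ng):
    """Symmetric normalized co-occurrence matrix by pair enumeration."""
    rows, cols = levels.shape
    dr, dc = offset
    c = np.zeros((ng, ng))
    for r in range(rows):
        for col in range(cols):
            r2, c2 = r + dr, col + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, col] and mask[r2, c2]:
                i, j = levels[r, col] - 1, levels[r2, c2] - 1
                c[i, j] += 1
                c[j, i] += 1
    s = c.sum()
    return c / s if s > 0 else c


def glrlm_oracle(levels, mask, direction, ng, max_run):
    """Run-length matrix by explicit line walking."""
    rows, cols = levels.shape
    dr, dc = direction
    m = np.zeros((ng, max_run))
    # starting points: cells with no predecessor along (dr, dc)
    for r in range(rows):
        for c in range(cols):
            pr, pc = r - dr, c - dc
            if 0 <= pr < rows and 0 <= pc < cols:
                continue  # not a line start
            run_level, run_len = 0, 0
            rr, cc = r, c
            while 0 <= rr < rows and 0 <= cc < cols:
                lv = levels[rr, cc] if mask[rr, cc] else 0
                if lv == run_level:
                    run_len += 1
                else:
                    if run_level > 0:
                        m[run_level - 1, run_len - 1] += 1
                    run_level, run_len = lv, 1
                rr, cc = rr + dr, cc + dc
            if run_level > 0:
                m[run_level - 1, run_len - 1] += 1
    return m


def glszm_zones_oracle(levels, mask, ng):
    """(gray level, zone size) pairs by BFS flood fill, 8-connectivity."""
    rows, cols = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or seen[r, c]:
                continue
            g = levels[r, c]
            size = 0
            q = deque([(r, c)])
            seen[r, c] = True
            while q:
                cr, cc = q.popleft()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = cr + dr, cc + dc
                        if (
                            0 <= nr < rows
                            and 0 <= nc < cols
                            and mask[nr, nc]
                            and not seen[nr, nc]
                            and levels[nr, nc] == g
                        ):
                            seen[nr, nc] = True
                            q.append((nr, nc))
            zones.append((g, size))
    return zones


def gldm_oracle(levels, mask, ng, alpha=0):
    """Dependence matrix by per-pixel neighbour counting (j = count + 1)."""
    rows, cols = levels.shape
    pairs = []
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            dep = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if (
                        0 <= nr < rows
                        and 0 <= nc < cols
                        and mask[nr, nc]
                        and abs(int(levels[nr, nc]) - int(levels[r, c])) <= alpha
                    ):
                        dep += 1
            pairs.append((levels[r, c], dep + 1))
    nd = max(j for _, j in pairs)
    m = np.zeros((ng, nd))
    for g, j in pairs:
        m[g - 1, j - 1] += 1
    return m


def ngtdm_oracle(levels, mask, ng):
    """(s, n) arrays by per-pixel 8-neighbour mean differences."""
    rows, cols = levels.shape
    s = np.zeros(ng)
    n = np.zeros(ng)
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc]:
                        nb.append(levels[nr, nc])
            if not nb:
                continue
            g = levels[r, c]
            s[g - 1] += abs(g - sum(nb) / len(nb))
            n[g - 1] += 1
    return s, n


# ---------------------------------------------- loop-based feature formulas


def _log2(v):
    return math.log2(v) if v > 0 else 0.0


def glcm_features_oracle(p, ng):
    """All 24 co-occurrence features from one normalized matrix, pure loops."""
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    ux = sum((i + 1) * px[i] for i in range(ng))
    uy = sum((j + 1) * py[j] for j in range(ng))
    sx = math.sqrt(sum((i + 1 - ux) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j + 1 - uy) ** 2 * py[j] for j in range(ng)))
    psum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    pdiff = {k: 0.0 for k in range(0, ng)}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]
    f = {}
    f["Autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
    )
    for name, power in (
        ("ClusterProminence", 4),
        ("ClusterShade", 3),
        ("ClusterTendency", 2),
    ):
        f[name] = sum(
            (i + 1 + j + 1 - ux - uy) ** power * p[i][j]
            for i in range(ng)
            for j in range(ng)
        )
    f["Contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    f["Correlation"] = (
        1.0 if sx * sy == 0 else (f["Autocorrelation"] - ux * uy) / (sx * sy)
    )
    da = sum(k * v for k, v in pdiff.items())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(v * _log2(v) for v in pdiff.values() if v > 0)
    f["DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    f["Id"] = sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["Idm"] = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["Idmn"] = sum(
        p[i][j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    f["Idn"] = sum(
        p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    hx = -sum(v * _log2(v) for v in px if v > 0)
    hy = -sum(v * _log2(v) for v in py if v > 0)
    hxy = -sum(
        p[i][j] * _log2(p[i][j]) for i in range(ng) for j in range(ng) if p[i][j] > 0
    )
    eps = np.spacing(1.0)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j] + eps)
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    f["Imc1"] = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    f["Imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    f["InverseVariance"] = sum(
        p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["JointAverage"] = ux
    f["JointEnergy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    f["JointEntropy"] = hxy
    present = [i for i in range(ng) if px[i] > 0]
    if len(present) < 2:
        f["MCC"] = 1.0
    else:
        q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(
                    p[i][k] * p[j][k] / (px[i] * py[k]) for k in present if py[k] > 0
                )
        ev = sorted(np.real(np.linalg.eigvals(q)))
        f["MCC"] = math.sqrt(max(0.0, ev[-2]))
    f["MaximumProbability"] = max(p[i][j] for i in range(ng) for j in range(ng))
    f["SumAverage"] = sum(k * v for k, v in psum.items())
    f["SumEntropy"] = -sum(v * _log2(v) for v in psum.values() if v > 0)
    f["SumSquares"] = sum((i + 1 - ux) ** 2 * px[i] for i in range(ng))
    return f


def sizezone_features_oracle(m, n_pixels, kind):
    """GLRLM/GLSZM/GLDM features from a (level x size) count matrix, loops.

    ``kind`` in {"glrlm", "glszm", "gldm"} selects the name set.
    """
    ng, nj = m.shape
    n = m.sum()
    p = m / n
    pi = [sum(p[i][j] for j in range(nj)) for i in range(ng)]
    pj = [sum(p[i][j] for i in range(ng)) for j in range(nj)]
    mu_i = sum((i + 1) * pi[i] for i in range(ng))
    mu_j = sum((j + 1) * pj[j] for j in range(nj))
    stats = {
        "small_j": sum(p[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nj)),
        "large_j": sum(p[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nj)),
        "low_i": sum(p[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nj)),
        "high_i": sum(p[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nj)),
        "sj_li": sum(
            p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
            for i in range(ng)
            for j in range(nj)
        ),
        "sj_hi": sum(
            p[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nj)
        ),
        "lj_li": sum(
            p[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nj)
        ),
        "lj_hi": sum(
            p[i][j] * ((i + 1) * (j + 1)) ** 2 for i in range(ng) for j in range(nj)
        ),
        "gln": sum(sum(m[i]) ** 2 for i in range(ng)) / n,
        "glnn": sum(pi[i] ** 2 for i in range(ng)),
        "jln": sum(sum(m[i][j] for i in range(ng)) ** 2 for j in range(nj)) / n,
        "jlnn": sum(pj[j] ** 2 for j in range(nj)),
        "var_i": sum((i + 1 - mu_i) ** 2 * pi[i] for i in range(ng)),
        "var_j": sum((j + 1 - mu_j) ** 2 * pj[j] for j in range(nj)),
        "entropy": -sum(
            p[i][j] * _log2(p[i][j]) for i in range(ng) for j in range(nj) if p[i][j] > 0
        ),
    }
    if kind == "glrlm":
        return {
            "ShortRunEmphasis": stats["small_j"],
            "LongRunEmphasis": stats["large_j"],
            "GrayLevelNonUniformity": stats["gln"],
            "GrayLevelNonUniformityNormalized": stats["glnn"],
            "RunLengthNonUniformity": stats["jln"],
            "RunLengthNonUniformityNormalized": stats["jlnn"],
            "RunPercentage": n / n_pixels,
            "GrayLevelVariance": stats["var_i"],
            "RunVariance": stats["var_j"],
            "RunEntropy": stats["entropy"],
            "LowGrayLevelRunEmphasis": stats["low_i"],
            "HighGrayLevelRunEmphasis": stats["high_i"],
            "ShortRunLowGrayLevelEmphasis": stats["sj_li"],
            "ShortRunHighGrayLevelEmphasis": stats["sj_hi"],
            "LongRunLowGrayLevelEmphasis": stats["lj_li"],
            "LongRunHighGrayLevelEmphasis": stats["lj_hi"],
        }
    if kind == "glszm":
        return {
            "SmallAreaEmphasis": stats["small_j"],
            "LargeAreaEmphasis": stats["large_j"],
            "GrayLevelNonUniformity": stats["gln"],
            "GrayLevelNonUniformityNormalized": stats["glnn"],
            "SizeZoneNonUniformity": stats["jln"],
            "SizeZoneNonUniformityNormalized": stats["jlnn"],
            "ZonePercentage": n / n_pixels,
            "GrayLevelVariance": stats["var_i"],
            "ZoneVariance": stats["var_j"],
            "ZoneEntropy": stats["entropy"],
            "LowGrayLevelZoneEmphasis": stats["low_i"],
            "HighGrayLevelZoneEmphasis": stats["high_i"],
            "SmallAreaLowGrayLevelEmphasis": stats["sj_li"],
            "SmallAreaHighGrayLevelEmphasis": stats["sj_hi"],
            "LargeAreaLowGrayLevelEmphasis": stats["lj_li"],
            "LargeAreaHighGrayLevelEmphasis": stats["lj_hi"],
        }
    return {
        "SmallDependenceEmphasis": stats["small_j"],
        "LargeDependenceEmphasis": stats["large_j"],
        "GrayLevelNonUniformity": stats["gln"],
        "DependenceNonUniformity": stats["jln"],
        "DependenceNonUniformityNormalized": stats["jlnn"],
        "GrayLevelVariance": stats["var_i"],
        "DependenceVariance": stats["var_j"],
        "DependenceEntropy": stats["entropy"],
        "LowGrayLevelEmphasis": stats["low_i"],
        "HighGrayLevelEmphasis": stats["high_i"],
        "SmallDependenceLowGrayLevelEmphasis": stats["sj_li"],
        "SmallDependenceHighGrayLevelEmphasis": stats["sj_hi"],
        "LargeDependenceLowGrayLevelEmphasis": stats["lj_li"],
        "LargeDependenceHighGrayLevelEmphasis": stats["lj_hi"],
    }


def ngtdm_features_oracle(s, n, ng):
    nvp = n.sum()
    p = n / nvp
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    coarse_den = sum(p[i] * s[i] for i in range(ng))
    out = {"Coarseness": 1.0 / coarse_den if coarse_den > 0 else 1e6}
    if ngp <= 1:
        out.update({"Contrast": 0.0, "Complexity": 0.0, "Strength": 0.0})
    else:
        pair = sum(
            p[i] * p[j] * (i - j) ** 2 for i in present for j in present
        )
        out["Contrast"] = pair / (ngp * (ngp - 1)) * s.sum() / nvp
        out["Complexity"] = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / nvp
        )
        snum = sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
        out["Strength"] = snum / s.sum() if s.sum() > 0 else 0.0
    busy_den = sum(
        abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
    )
    out["Busyness"] = coarse_den / busy_den if busy_den > 0 else 0.0
    return out


# ----------------------------------------------------------- statistics


def icc_anova_oracle(ratings):
    """ICC(C,1) from first-principles sums of squares."""
    ratings = np.asarray(ratings, float)
    n, k = ratings.shape
    grand = ratings.mean()
    ssr = sum(k * (ratings[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (ratings[:, j].mean() - grand) ** 2 for j in range(k))
    sst = ((ratings - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


def stump_oracle(x, y):
    """Exhaustive search over all midpoints and both directions; best accuracy
    by Gini impurity, ties to the widest gap."""
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    ux = np.unique(x)
    best = None
    n = len(y)
    for a, b in zip(ux[:-1], ux[1:]):
        t = (a + b) / 2
        hi = x > t
        gini = 0.0
        for side in (hi, ~hi):
            m = side.sum()
            if m:
                q = y[side].mean()
                gini += (m / n) * 2 * q * (1 - q)
        key = (gini, -(b - a))
        if best is None or key < best[0]:
            best = (key, t)
    return best[1]


def glmm_loglik_agq(params, x, y, group_idx, n_groups, n_nodes=15):
    """Adaptive Gauss-Hermite marginal log-likelihood of the random-intercept
    logistic model; mode finding by scalar bisection-free Newton per group."""
    b0, b1, log_sigma = params
    sigma2 = math.exp(2 * log_sigma)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    total = 0.0
    for g in range(n_groups):
        sel = group_idx == g
        xg, yg = x[sel], y[sel]

        def f(b):
            eta = b0 + b1 * xg + b
            return float((yg * eta - np.logaddexp(0, eta)).sum() - b * b / (2 * sigma2))

        # Newton for the mode
        b = 0.0
        for _ in range(100):
            eta = b0 + b1 * xg + b
            p = 1 / (1 + np.exp(-eta))
            g1 = float((yg - p).sum() - b / sigma2)
            g2 = float(-(p * (1 - p)).sum() - 1 / sigma2)
            step = g1 / g2
            b -= step
            if abs(step) < 1e-12:
                break
        scale = 1.0 / math.sqrt(-g2)
        vals = [
            w * math.exp(f(b + scale * z) + z * z / 2.0)
            for z, w in zip(nodes, weights)
        ]
        total += math.log(scale * sum(vals)) - 0.5 * math.log(2 * math.pi * sigma2)
    return total
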