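"""Loop-based transcriptions of the texture-feature formulas.

Each function evaluates the defining formulas with explicit python
loops over matrix entries, independently of the vectorised package
code.  Keys of the run-length family use the generic small/large-size
vocabulary; tests map them onto the per-family labels.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_feats_bf(p: np.ndarray, ng: int) -> dict[str, float]:
    idx = range(1, ng + 1)
    px = [sum(p[i - 1, j - 1] for j in idx) for i in idx]
    py = [sum(p[i - 1, j - 1] for i in idx) for j in idx]
    mu_x = sum(i * px[i - 1] for i in idx)
    mu_y = sum(j * py[j - 1] for j in idx)
    var_x = sum((i - mu_x) ** 2 * px[i - 1] for i in idx)
    var_y = sum((j - mu_y) ** 2 * py[j - 1] for j in idx)
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in idx:
        for j in idx:
            p_sum[i + j] += p[i - 1, j - 1]
            p_diff[abs(i - j)] += p[i - 1, j - 1]
    ent = lambda vals: -sum(v * math.log2(v) for v in vals if v > 0)
    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i - 1, j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in idx
        for j in idx
        if p[i - 1, j - 1] > 0
    )
    hxy2 = -sum(
        px[i - 1] * py[j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in idx
        for j in idx
        if px[i - 1] * py[j - 1] > 0
    )
    da = sum(k * v for k, v in p_diff.items())
    s2 = lambda f: sum(f(i, j) * p[i - 1, j - 1] for i in idx for j in idx)
    out = {
        "Autocorrelation": s2(lambda i, j: i * j),
        "ClusterProminence": s2(lambda i, j: (i + j - mu_x - mu_y) ** 4),
        "ClusterShade": s2(lambda i, j: (i + j - mu_x - mu_y) ** 3),
        "ClusterTendency": s2(lambda i, j: (i + j - mu_x - mu_y) ** 2),
        "Contrast": s2(lambda i, j: (i - j) ** 2),
        "Correlation": (s2(lambda i, j: i * j) - mu_x * mu_y) / math.sqrt(var_x * var_y)
        if var_x > 0 and var_y > 0
        else float("nan"),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "Id": s2(lambda i, j: 1.0 / (1 + abs(i - j))),
        "Idm": s2(lambda i, j: 1.0 / (1 + (i - j) ** 2)),
        "Idmn": s2(lambda i, j: 1.0 / (1 + (i - j) ** 2 / ng**2)),
        "Idn": s2(lambda i, j: 1.0 / (1 + abs(i - j) / ng)),
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else float("nan"),
        "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
        "InverseVariance": sum(
            p[i - 1, j - 1] / (i - j) ** 2 for i in idx for j in idx if i != j
        ),
        "JointAverage": mu_x,
        "JointEnergy": sum(v**2 for v in p.ravel()),
        "JointEntropy": hxy,
        "MaximumProbability": max(p.ravel()),
        "SumEntropy": ent(p_sum.values()),
        "SumSquares": var_x,
    }
    return out


def size_family_bf(counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    ng, nmax = counts.shape
    total = counts.sum()
    gi = range(1, ng + 1)
    sj = range(1, nmax + 1)
    c = lambda i, j: counts[i - 1, j - 1]
    pg = [sum(c(i, j) for j in sj) for i in gi]
    ps = [sum(c(i, j) for i in gi) for j in sj]
    mu_i = sum(i * c(i, j) for i in gi for j in sj) / total
    mu_j = sum(j * c(i, j) for i in gi for j in sj) / total
    return {
        "SmallEmphasis": sum(c(i, j) / j**2 for i in gi for j in sj) / total,
        "LargeEmphasis": sum(c(i, j) * j**2 for i in gi for j in sj) / total,
        "GrayLevelNonUniformity": sum(v**2 for v in pg) / total,
        "GrayLevelNonUniformityNormalized": sum(v**2 for v in pg) / total**2,
        "SizeNonUniformity": sum(v**2 for v in ps) / total,
        "SizeNonUniformityNormalized": sum(v**2 for v in ps) / total**2,
        "Percentage": total / n_pixels,
        "GrayLevelVariance": sum((i - mu_i) ** 2 * c(i, j) for i in gi for j in sj) / total,
        "SizeVariance": sum((j - mu_j) ** 2 * c(i, j) for i in gi for j in sj) / total,
        "Entropy": -sum(
            c(i, j) / total * math.log2(c(i, j) / total)
            for i in gi
            for j in sj
            if c(i, j) > 0
        ),
        "LowGrayLevelEmphasis": sum(c(i, j) / i**2 for i in gi for j in sj) / total,
        "HighGrayLevelEmphasis": sum(c(i, j) * i**2 for i in gi for j in sj) / total,
        "SmallLowGrayLevelEmphasis": sum(c(i, j) / (i**2 * j**2) for i in gi for j in sj) / total,
        "SmallHighGrayLevelEmphasis": sum(c(i, j) * i**2 / j**2 for i in gi for j in sj) / total,
        "LargeLowGrayLevelEmphasis": sum(c(i, j) * j**2 / i**2 for i in gi for j in sj) / total,
        "LargeHighGrayLevelEmphasis": sum(c(i, j) * i**2 * j**2 for i in gi for j in sj) / total,
    }


def ngtdm_feats_bf(n_i: np.ndarray, s_i: np.ndarray, ng: int) -> dict[str, float]:
    nvp = n_i.sum()
    p = n_i / nvp
    act = [i for i in range(1, ng + 1) if p[i - 1] > 0]
    ngp = len(act)
    coarse_den = sum(p[i - 1] * s_i[i - 1] for i in act)
    if ngp <= 1:
        contrast = 0.0
    else:
        contrast = (
            sum(p[i - 1] * p[j - 1] * (i - j) ** 2 for i in act for j in act)
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
    busy_den = sum(abs(i * p[i - 1] - j * p[j - 1]) for i in act for j in act)
    complexity = (
        sum(
            abs(i - j)
            * (p[i - 1] * s_i[i - 1] + p[j - 1] * s_i[j - 1])
            / (p[i - 1] + p[j - 1])
            for i in act
            for j in act
        )
        / nvp
    )
    s_sum = s_i.sum()
    strength = (
        sum((p[i - 1] + p[j - 1]) * (i - j) ** 2 for i in act for j in act) / s_sum
        if s_sum > 0
        else float("nan")
    )
    return {
        "Busyness": coarse_den / busy_den if busy_den > 0 else float("nan"),
        "Coarseness": 1.0 / coarse_den if coarse_den > 0 else float("nan"),
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
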