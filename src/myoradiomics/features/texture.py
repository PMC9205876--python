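"""IBSI-style feature formulas evaluated on gray-level matrices.

Conventions shared by every formula below:

* gray levels and run/zone/dependence sizes are 1-based indices;
* logarithms are base 2;
* a formula whose denominator vanishes (or that would take log 0 as a
  whole) returns ``nan`` — the caller records it as missing, never as 0.
"""

from __future__ import annotations

import numpy as np

from .matrices import GrayLevelMatrix

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

_NAN = float("nan")


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(m: GrayLevelMatrix) -> dict[str, float]:
    """The 22 co-occurrence features from one directional probability matrix."""
    if m.degenerate:
        return {k: _NAN for k in _GLCM_KEYS}
    p = m.values
    ng = m.n_levels
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    diff_avg = float((k_diff * p_diff).sum())
    hxy = _entropy(p.ravel())
    hx, hy = _entropy(px), _entropy(py)
    pxy = np.outer(px, py)
    mask = p > 0
    hxy1 = float(-(p[mask] * np.log2(pxy[mask])).sum())
    mask2 = pxy > 0
    hxy2 = float(-(pxy[mask2] * np.log2(pxy[mask2])).sum())

    autocorr = float((p * ii * jj).sum())
    corr = _NAN
    if var_x > 0 and var_y > 0:
        corr = (autocorr - mu_x * mu_y) / np.sqrt(var_x * var_y)
    imc1 = _NAN if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off = ii != jj

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float((p * (ii + jj - mu_x - mu_y) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - mu_x - mu_y) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - mu_x - mu_y) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p[off] / (ii[off] - jj[off]) ** 2).sum()),
        "JointAverage": mu_x,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": var_x,
    }


_GLCM_KEYS = (
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
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)


def _size_family(counts: np.ndarray, n_pixels: int, names: dict[str, str]) -> dict[str, float]:
    """Shared algebra of the run-length / size-zone / dependence families.

    ``counts`` is an (N_g x max-size) count matrix; ``names`` maps the
    generic keys to the family's feature labels.
    """
    total = counts.sum()
    if total == 0:
        return {v: _NAN for v in names.values()}
    ng, nmax = counts.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nmax + 1, dtype=float)[None, :]
    p = counts / total
    pg = counts.sum(axis=1)
    ps = counts.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())

    out = {
        "SmallEmphasis": float((counts / j**2).sum() / total),
        "LargeEmphasis": float((counts * j**2).sum() / total),
        "GrayLevelNonUniformity": float((pg**2).sum() / total),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / total**2),
        "SizeNonUniformity": float((ps**2).sum() / total),
        "SizeNonUniformityNormalized": float((ps**2).sum() / total**2),
        "Percentage": float(total / n_pixels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "SizeVariance": float((p * (j - mu_j) ** 2).sum()),
        "Entropy": _entropy(p.ravel()),
        "LowGrayLevelEmphasis": float((counts / i**2).sum() / total),
        "HighGrayLevelEmphasis": float((counts * i**2).sum() / total),
        "SmallLowGrayLevelEmphasis": float((counts / (i**2 * j**2)).sum() / total),
        "SmallHighGrayLevelEmphasis": float((counts * i**2 / j**2).sum() / total),
        "LargeLowGrayLevelEmphasis": float((counts * j**2 / i**2).sum() / total),
        "LargeHighGrayLevelEmphasis": float((counts * i**2 * j**2).sum() / total),
    }
    return {label: out[key] for key, label in names.items()}


_GLRLM_NAMES = {
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
    "LargeEmphasis": "LongRunEmphasis",
    "LargeHighGrayLevelEmphasis": "LongRunHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
    "Entropy": "RunEntropy",
    "SizeNonUniformity": "RunLengthNonUniformity",
    "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
    "Percentage": "RunPercentage",
    "SizeVariance": "RunVariance",
    "SmallEmphasis": "ShortRunEmphasis",
    "SmallHighGrayLevelEmphasis": "ShortRunHighGrayLevelEmphasis",
    "SmallLowGrayLevelEmphasis": "ShortRunLowGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance",
    "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
    "LargeEmphasis": "LargeAreaEmphasis",
    "LargeHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
    "SizeNonUniformity": "SizeZoneNonUniformity",
    "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "SmallEmphasis": "SmallAreaEmphasis",
    "SmallHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
    "SmallLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
    "Entropy": "ZoneEntropy",
    "Percentage": "ZonePercentage",
    "SizeVariance": "ZoneVariance",
}

_GLDM_NAMES = {
    "Entropy": "DependenceEntropy",
    "SizeNonUniformity": "DependenceNonUniformity",
    "SizeNonUniformityNormalized": "DependenceNonUniformityNormalized",
    "SizeVariance": "DependenceVariance",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelVariance": "GrayLevelVariance",
    "HighGrayLevelEmphasis": "HighGrayLevelEmphasis",
    "LargeEmphasis": "LargeDependenceEmphasis",
    "LargeHighGrayLevelEmphasis": "LargeDependenceHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis": "LowGrayLevelEmphasis",
    "SmallEmphasis": "SmallDependenceEmphasis",
    "SmallHighGrayLevelEmphasis": "SmallDependenceHighGrayLevelEmphasis",
    "SmallLowGrayLevelEmphasis": "SmallDependenceLowGrayLevelEmphasis",
}


def glrlm_features(m: GrayLevelMatrix, n_pixels: int) -> dict[str, float]:
    return _size_family(m.values, n_pixels, _GLRLM_NAMES)


def glszm_features(m: GrayLevelMatrix, n_pixels: int) -> dict[str, float]:
    return _size_family(m.values, n_pixels, _GLSZM_NAMES)


def gldm_features(m: GrayLevelMatrix) -> dict[str, float]:
    # every valid pixel contributes one dependence, so Percentage == 1
    # and is not part of the GLDM feature set
    n = int(m.values.sum())
    return _size_family(m.values, max(n, 1), _GLDM_NAMES)


def ngtdm_features(m: GrayLevelMatrix) -> dict[str, float]:
    """Busyness, Coarseness, Complexity, Contrast, Strength."""
    if m.degenerate:
        return {k: _NAN for k in ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")}
    n_i = m.values[:, 0]
    s_i = m.values[:, 1]
    nvp = n_i.sum()
    p = n_i / nvp
    i = np.arange(1, m.n_levels + 1, dtype=float)
    act = p > 0
    ngp = int(act.sum())

    coarse_den = float((p * s_i).sum())
    coarseness = _NAN if coarse_den == 0 else 1.0 / coarse_den

    if ngp <= 1:
        contrast = 0.0
    else:
        pi, pj = np.meshgrid(p[act], p[act], indexing="ij")
        di = np.subtract.outer(i[act], i[act])
        contrast = float((pi * pj * di**2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / nvp))

    ipi = i[act] * p[act]
    busy_den = float(np.abs(np.subtract.outer(ipi, ipi)).sum())
    busyness = _NAN if busy_den == 0 else float((p * s_i).sum()) / busy_den

    pi, pj = np.meshgrid(p[act], p[act], indexing="ij")
    si, sj = np.meshgrid(s_i[act], s_i[act], indexing="ij")
    di = np.abs(np.subtract.outer(i[act], i[act]))
    complexity = float((di * (pi * si + pj * sj) / (pi + pj)).sum() / nvp)

    s_sum = float(s_i.sum())
    strength = _NAN if s_sum == 0 else float(((pi + pj) * di**2).sum()) / s_sum

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
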