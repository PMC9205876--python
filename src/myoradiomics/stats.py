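"""Robustness statistics: ICC, CV, repeated-measures correlation.

The intraclass correlation follows the two-way mixed-effects model with
a single rater and absolute agreement,

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)),

where MS_R, MS_C, MS_E are the row (subject), column (rater) and error
mean squares of the crossed ANOVA decomposition, n subjects, k raters.
Here a "rater" is one level of the varied preprocessing element (a
voxel size, a bin width, or a spatial filter).

The coefficient of variation is 100 * SD / |mean| (sample SD, n-1) of
one subject's feature values across the varied conditions.

The repeated-measures correlation (rmcorr) is the common within-subject
correlation from an ANCOVA with a subject factor and a shared slope:
r_rm = sign(b) * sqrt(SS_slope / (SS_slope + SS_error)) with
df = N(k-1) - 1 residual degrees of freedom in the balanced case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "IccAnovaComponents",
    "IccEstimate",
    "RmcorrEstimate",
    "anova_components",
    "icc",
    "stratify",
    "cv",
    "cv_summary",
    "rmcorr",
    "bonferroni",
]


@dataclass(frozen=True)
class IccAnovaComponents:
    ms_r: float  # between-subject (rows)
    ms_c: float  # between-rater (columns)
    ms_e: float  # residual
    n: int
    k: int


@dataclass(frozen=True)
class IccEstimate:
    value: float
    band: str
    degenerate: bool = False


@dataclass(frozen=True)
class RmcorrEstimate:
    r_rm: float
    df: int
    p_value: float
    slope: float


def anova_components(data: np.ndarray) -> IccAnovaComponents:
    """Two-way crossed ANOVA mean squares of an n x k matrix (no
    replication): rows = subjects, columns = raters."""
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"data must be 2D, got ndim={x.ndim}")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 raters, got {n}x{k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("data must be complete (apply listwise deletion upstream)")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_r = k * ((row_means - grand) ** 2).sum()
    ss_c = n * ((col_means - grand) ** 2).sum()
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_e = (resid**2).sum()
    return IccAnovaComponents(
        ms_r=ss_r / (n - 1),
        ms_c=ss_c / (k - 1),
        ms_e=ss_e / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc(data: np.ndarray) -> IccEstimate:
    """Two-way mixed, single-rater, absolute-agreement ICC of an n x k
    matrix.  An all-identical matrix (0/0) is defined as ICC = 1 with a
    degeneracy flag — the structurally forced case for features that do
    not depend on the varied element."""
    comp = anova_components(data)
    num = comp.ms_r - comp.ms_e
    den = comp.ms_r + (comp.k - 1) * comp.ms_e + comp.k / comp.n * (comp.ms_c - comp.ms_e)
    if den == 0:
        # all cells identical: no variance anywhere
        return IccEstimate(1.0, stratify(1.0), degenerate=True)
    value = num / den
    return IccEstimate(float(value), stratify(value))


def stratify(icc_value: float) -> str:
    """Variability band: high (<=0.5), considerable (<=0.75), moderate
    (<=0.9), low (<=1); boundary values fall in the lower band."""
    if icc_value > 1.0 + 1e-12:
        raise ValueError(f"ICC must be <= 1, got {icc_value}")
    if icc_value <= 0.5:
        return "high"
    if icc_value <= 0.75:
        return "considerable"
    if icc_value <= 0.9:
        return "moderate"
    return "low"


def cv(values) -> float:
    """100 * sample SD / |mean|; nan when the mean is zero (undefined)."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError(f"cv needs >= 2 values, got {x.size}")
    if np.ptp(x) == 0:  # all equal: exactly 0 (the mean of n copies of v
        return 0.0      # need not be bit-equal to v, so SD can pick up 1 ulp)
    mean = x.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / abs(mean))


def cv_summary(cv_percents) -> float:
    """Median CV over subject x fixed-condition records, dropping
    undefined entries; nan when all are undefined."""
    x = np.asarray(list(cv_percents), dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return float("nan")
    return float(np.median(x))


def rmcorr(subjects, x, y) -> RmcorrEstimate:
    """Repeated-measures correlation via within-subject centring.

    Equivalent to an ANCOVA with a subject factor and common slope for
    ``x``; the subject effect is removed exactly by centring both
    variables within subject.
    """
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not (len(subjects) == len(x) == len(y)):
        raise ValueError("subjects, x, y must have equal length")
    uniq, inverse, counts = np.unique(subjects, return_inverse=True, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("rmcorr needs >= 2 subjects (cannot separate the subject effect)")
    if counts.min() < 2:
        raise ValueError("every subject needs >= 2 observations")

    xc = x - np.bincount(inverse, weights=x)[inverse] / counts[inverse]
    yc = y - np.bincount(inverse, weights=y)[inverse] / counts[inverse]
    sxx = float((xc**2).sum())
    if sxx == 0:
        raise ValueError("zero within-subject variance in x")
    slope = float((xc * yc).sum() / sxx)
    ss_slope = slope**2 * sxx
    ss_error = float(((yc - slope * xc) ** 2).sum())
    df = len(x) - len(uniq) - 1  # = N(k-1) - 1 when balanced
    if df < 1:
        raise ValueError(f"not enough residual degrees of freedom (df={df})")
    denom = ss_slope + ss_error
    r = 0.0 if denom == 0 else math.copysign(math.sqrt(ss_slope / denom), slope)
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RmcorrEstimate(r_rm=r, df=df, p_value=p, slope=slope)


def bonferroni(p_values, alpha: float = 0.05) -> list[bool]:
    """Family-wise significance flags: p <= alpha / m over the family of
    m tests (one family = the features tested for one modality x effect)."""
    p = np.asarray(list(p_values), dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return []
    return list(p <= alpha / m)
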