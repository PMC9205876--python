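"""First-order features of the ROI intensity distribution.

The 14 statistical features operate on the continuous (pre-
discretization) ROI values — which is why they are structurally
invariant to the bin width.  Entropy and Uniformity operate on the
discretized intensity histogram.  Kurtosis is reported in Pearson
(non-excess) form, i.e. excess kurtosis + 3.
"""

from __future__ import annotations

import numpy as np

from ..cohort import QuantitativeMap, RoiMask
from ..preprocess import DiscretizedRoi

__all__ = ["firstorder_features"]


def firstorder_features(
    qmap: QuantitativeMap, mask: RoiMask, d: DiscretizedRoi
) -> dict[str, float]:
    mask.check_congruent(qmap)
    x = qmap.values[mask.mask].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])  # linear interpolation
    robust = x[(x >= p10) & (x <= p90)]

    skew = m3 / m2**1.5 if m2 > 0 else float("nan")
    kurt = m4 / m2**2 if m2 > 0 else float("nan")  # Pearson form

    # histogram features on the discretized levels
    counts = np.bincount(d.roi_levels, minlength=d.n_levels + 1)[1:].astype(float)
    p = counts[counts > 0] / counts.sum()

    return {
        "Mean": mean,
        "Variance": m2,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "InterquartileRange": float(p75 - p25),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "Energy": float((x**2).sum()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Uniformity": float((p**2).sum()),
    }
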