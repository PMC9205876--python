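"""Closed registry of the 98 2D radiomic features.

9 shape, 16 first-order, and 73 texture features (22 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM, 5 NGTDM), named with the conventional labels used by
IBSI-aligned extraction software.  Shape features are omitted for
filtered maps (89 features), since the ROI geometry does not depend on
the intensity filter.
"""

from __future__ import annotations

SHAPE2D = (
    "Elongation",
    "MajorAxisLength",
    "MaximumDiameter",
    "MeshSurface",
    "MinorAxisLength",
    "Perimeter",
    "PerimeterSurfaceRatio",
    "PixelSurface",
    "Sphericity",
)

# 14 intensity-based statistics (computed before discretization) plus
# the two intensity-histogram features Entropy and Uniformity.
FIRSTORDER_STATISTICAL = (
    "Mean",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Median",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "InterquartileRange",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "Energy",
    "RootMeanSquared",
)
FIRSTORDER_HISTOGRAM = ("Entropy", "Uniformity")
FIRSTORDER = FIRSTORDER_STATISTICAL + FIRSTORDER_HISTOGRAM

GLCM = (
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

GLRLM = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

GLDM = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

_CLASSES = {
    "shape": SHAPE2D,
    "firstorder": FIRSTORDER,
    "glcm": GLCM,
    "glrlm": GLRLM,
    "glszm": GLSZM,
    "gldm": GLDM,
    "ngtdm": NGTDM,
}

FEATURE_CLASSES = tuple(_CLASSES)


def feature_registry(include_shape: bool = True) -> list[tuple[str, str]]:
    """Stable ordered list of (feature_class, feature_name) pairs:
    98 entries, or 89 without the shape class."""
    out: list[tuple[str, str]] = []
    for cls, names in _CLASSES.items():
        if cls == "shape" and not include_shape:
            continue
        out.extend((cls, n) for n in names)
    return out
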