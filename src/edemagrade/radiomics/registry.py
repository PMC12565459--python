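"""Versioned registry of the radiomic feature bank.

Pins the exact, ordered feature-name lists per family and the image-type
ordering, so a full extraction always yields the same 851 names:
14 shape + 93 per image type x (original + 8 wavelet sub-bands).
Names follow the IBSI-consistent conventions of the de-facto standard
radiomics feature sets, with schema ``{imageType}_{class}_{Feature}``.
"""

from __future__ import annotations

REGISTRY_VERSION = "1.0"

SHAPE_FEATURES: tuple[str, ...] = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)

FIRSTORDER_FEATURES: tuple[str, ...] = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
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

GLCM_FEATURES: tuple[str, ...] = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
)

GLRLM_FEATURES: tuple[str, ...] = (
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

GLSZM_FEATURES: tuple[str, ...] = (
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

GLDM_FEATURES: tuple[str, ...] = (
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

NGTDM_FEATURES: tuple[str, ...] = (
    "Coarseness",
    "Contrast",
    "Busyness",
    "Complexity",
    "Strength",
)

#: Per-image-type texture/first-order families, in extraction order.
INTENSITY_FAMILIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("firstorder", FIRSTORDER_FEATURES),
    ("glcm", GLCM_FEATURES),
    ("gldm", GLDM_FEATURES),
    ("glrlm", GLRLM_FEATURES),
    ("glszm", GLSZM_FEATURES),
    ("ngtdm", NGTDM_FEATURES),
)

#: Wavelet sub-band ordering (L = low-pass, H = high-pass, per axis).
WAVELET_BANDS: tuple[str, ...] = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

N_SHAPE = len(SHAPE_FEATURES)
N_PER_IMAGE_TYPE = sum(len(names) for _, names in INTENSITY_FAMILIES)
N_WAVELET = len(WAVELET_BANDS) * N_PER_IMAGE_TYPE
N_TOTAL = N_SHAPE + N_PER_IMAGE_TYPE + N_WAVELET

assert N_PER_IMAGE_TYPE == 93 and N_WAVELET == 744 and N_TOTAL == 851


def full_feature_names() -> list[str]:
    """The 851 feature names of a full extraction, in stable order."""
    names = [f"original_shape_{f}" for f in SHAPE_FEATURES]
    for image_type in ("original", *(f"wavelet-{b}" for b in WAVELET_BANDS)):
        for family, feats in INTENSITY_FAMILIES:
            names.extend(f"{image_type}_{family}_{f}" for f in feats)
    return names
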