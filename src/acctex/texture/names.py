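"""Frozen feature-name schema: 92 features across six families.

The names are namespaced as ``family_FeatureName`` and follow the naming
used by IBSI-aligned extractors, so downstream tables and reports are
directly comparable across toolchains. Any rename is a schema break.
"""

FIRSTORDER_NAMES = [
    "firstorder_10Percentile",
    "firstorder_90Percentile",
    "firstorder_Energy",
    "firstorder_Entropy",
    "firstorder_InterquartileRange",
    "firstorder_Kurtosis",
    "firstorder_Maximum",
    "firstorder_Mean",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_Median",
    "firstorder_Minimum",
    "firstorder_Range",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_Skewness",
    "firstorder_TotalEnergy",
    "firstorder_Uniformity",
    "firstorder_Variance",
]

GLCM_NAMES = [
    "glcm_Autocorrelation",
    "glcm_ClusterProminence",
    "glcm_ClusterShade",
    "glcm_ClusterTendency",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_DifferenceAverage",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_Id",
    "glcm_Idm",
    "glcm_Idmn",
    "glcm_Idn",
    "glcm_Imc1",
    "glcm_Imc2",
    "glcm_InverseVariance",
    "glcm_JointAverage",
    "glcm_JointEnergy",
    "glcm_JointEntropy",
    "glcm_MCC",
    "glcm_MaximumProbability",
    "glcm_SumEntropy",
    "glcm_SumSquares",
]

GLRLM_NAMES = [
    "glrlm_GrayLevelNonUniformity",
    "glrlm_GrayLevelNonUniformityNormalized",
    "glrlm_GrayLevelVariance",
    "glrlm_HighGrayLevelRunEmphasis",
    "glrlm_LongRunEmphasis",
    "glrlm_LongRunHighGrayLevelEmphasis",
    "glrlm_LongRunLowGrayLevelEmphasis",
    "glrlm_LowGrayLevelRunEmphasis",
    "glrlm_RunEntropy",
    "glrlm_RunLengthNonUniformity",
    "glrlm_RunLengthNonUniformityNormalized",
    "glrlm_RunPercentage",
    "glrlm_RunVariance",
    "glrlm_ShortRunEmphasis",
    "glrlm_ShortRunHighGrayLevelEmphasis",
    "glrlm_ShortRunLowGrayLevelEmphasis",
]

GLSZM_NAMES = [
    "glszm_GrayLevelNonUniformity",
    "glszm_GrayLevelNonUniformityNormalized",
    "glszm_GrayLevelVariance",
    "glszm_HighGrayLevelZoneEmphasis",
    "glszm_LargeAreaEmphasis",
    "glszm_LargeAreaHighGrayLevelEmphasis",
    "glszm_LargeAreaLowGrayLevelEmphasis",
    "glszm_LowGrayLevelZoneEmphasis",
    "glszm_SizeZoneNonUniformity",
    "glszm_SizeZoneNonUniformityNormalized",
    "glszm_SmallAreaEmphasis",
    "glszm_SmallAreaHighGrayLevelEmphasis",
    "glszm_SmallAreaLowGrayLevelEmphasis",
    "glszm_ZoneEntropy",
    "glszm_ZonePercentage",
    "glszm_ZoneVariance",
]

GLDM_NAMES = [
    "gldm_DependenceEntropy",
    "gldm_DependenceNonUniformity",
    "gldm_DependenceNonUniformityNormalized",
    "gldm_DependenceVariance",
    "gldm_GrayLevelNonUniformity",
    "gldm_GrayLevelVariance",
    "gldm_HighGrayLevelEmphasis",
    "gldm_LargeDependenceEmphasis",
    "gldm_LargeDependenceHighGrayLevelEmphasis",
    "gldm_LargeDependenceLowGrayLevelEmphasis",
    "gldm_LowGrayLevelEmphasis",
    "gldm_SmallDependenceEmphasis",
    "gldm_SmallDependenceHighGrayLevelEmphasis",
    "gldm_SmallDependenceLowGrayLevelEmphasis",
]

NGTDM_NAMES = [
    "ngtdm_Busyness",
    "ngtdm_Coarseness",
    "ngtdm_Complexity",
    "ngtdm_Contrast",
    "ngtdm_Strength",
]

FAMILY_NAMES = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

FEATURE_NAMES = (
    FIRSTORDER_NAMES + GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + GLDM_NAMES + NGTDM_NAMES
)

assert len(FEATURE_NAMES) == 92 and len(set(FEATURE_NAMES)) == 92
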