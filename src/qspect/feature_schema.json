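[
 {
  "index": 0,
  "column": "ct_firstorder_Entropy",
  "modality": "CT (Hounsfield units)",
  "description": "Shannon entropy (base 2) of the discretized-level histogram"
 },
 {
  "index": 1,
  "column": "ct_firstorder_TotalEnergy",
  "modality": "CT (Hounsfield units)",
  "description": "voxel_volume * sum of squared raw window values"
 },
 {
  "index": 2,
  "column": "ct_firstorder_Uniformity",
  "modality": "CT (Hounsfield units)",
  "description": "sum of squared level-histogram frequencies"
 },
 {
  "index": 3,
  "column": "ct_glcm_Id",
  "modality": "CT (Hounsfield units)",
  "description": "inverse difference: sum p(i,j)/(1+|i-j|)"
 },
 {
  "index": 4,
  "column": "ct_glcm_Idm",
  "modality": "CT (Hounsfield units)",
  "description": "inverse difference moment: sum p(i,j)/(1+(i-j)^2)"
 },
 {
  "index": 5,
  "column": "ct_glcm_JointEnergy",
  "modality": "CT (Hounsfield units)",
  "description": "sum of squared co-occurrence probabilities"
 },
 {
  "index": 6,
  "column": "ct_glcm_MaximumProbability",
  "modality": "CT (Hounsfield units)",
  "description": "largest co-occurrence probability"
 },
 {
  "index": 7,
  "column": "ct_gldm_DependenceNonUniformityNormalized",
  "modality": "CT (Hounsfield units)",
  "description": "sum_j (sum_i P(i,j))^2 / Nz^2"
 },
 {
  "index": 8,
  "column": "ct_gldm_DependenceVariance",
  "modality": "CT (Hounsfield units)",
  "description": "variance of dependence size weighted by P/Nz"
 },
 {
  "index": 9,
  "column": "ct_gldm_LargeDependenceEmphasis",
  "modality": "CT (Hounsfield units)",
  "description": "sum j^2 P(i,j) / Nz"
 },
 {
  "index": 10,
  "column": "ct_glrlm_GrayLevelNonUniformityNormalized",
  "modality": "CT (Hounsfield units)",
  "description": "sum_i (sum_j P(i,j))^2 / Nr^2, direction-averaged"
 },
 {
  "index": 11,
  "column": "ct_glrlm_RunLengthNonUniformityNormalized",
  "modality": "CT (Hounsfield units)",
  "description": "sum_j (sum_i P(i,j))^2 / Nr^2, direction-averaged"
 },
 {
  "index": 12,
  "column": "ct_glrlm_RunPercentage",
  "modality": "CT (Hounsfield units)",
  "description": "Nr / Np, direction-averaged"
 },
 {
  "index": 13,
  "column": "ct_glrlm_ShortRunEmphasis",
  "modality": "CT (Hounsfield units)",
  "description": "sum P(i,j)/j^2 / Nr, direction-averaged"
 },
 {
  "index": 14,
  "column": "spect_firstorder_Entropy",
  "modality": "normalized SPECT",
  "description": "Shannon entropy (base 2) of the discretized-level histogram"
 },
 {
  "index": 15,
  "column": "spect_firstorder_TotalEnergy",
  "modality": "normalized SPECT",
  "description": "voxel_volume * sum of squared raw window values"
 },
 {
  "index": 16,
  "column": "spect_firstorder_Uniformity",
  "modality": "normalized SPECT",
  "description": "sum of squared level-histogram frequencies"
 },
 {
  "index": 17,
  "column": "spect_glcm_Id",
  "modality": "normalized SPECT",
  "description": "inverse difference: sum p(i,j)/(1+|i-j|)"
 },
 {
  "index": 18,
  "column": "spect_glcm_Idm",
  "modality": "normalized SPECT",
  "description": "inverse difference moment: sum p(i,j)/(1+(i-j)^2)"
 },
 {
  "index": 19,
  "column": "spect_glcm_JointEnergy",
  "modality": "normalized SPECT",
  "description": "sum of squared co-occurrence probabilities"
 },
 {
  "index": 20,
  "column": "spect_glcm_MaximumProbability",
  "modality": "normalized SPECT",
  "description": "largest co-occurrence probability"
 },
 {
  "index": 21,
  "column": "spect_gldm_DependenceNonUniformityNormalized",
  "modality": "normalized SPECT",
  "description": "sum_j (sum_i P(i,j))^2 / Nz^2"
 },
 {
  "index": 22,
  "column": "spect_gldm_DependenceVariance",
  "modality": "normalized SPECT",
  "description": "variance of dependence size weighted by P/Nz"
 },
 {
  "index": 23,
  "column": "spect_gldm_LargeDependenceEmphasis",
  "modality": "normalized SPECT",
  "description": "sum j^2 P(i,j) / Nz"
 },
 {
  "index": 24,
  "column": "spect_glrlm_GrayLevelNonUniformityNormalized",
  "modality": "normalized SPECT",
  "description": "sum_i (sum_j P(i,j))^2 / Nr^2, direction-averaged"
 },
 {
  "index": 25,
  "column": "spect_glrlm_RunLengthNonUniformityNormalized",
  "modality": "normalized SPECT",
  "description": "sum_j (sum_i P(i,j))^2 / Nr^2, direction-averaged"
 },
 {
  "index": 26,
  "column": "spect_glrlm_RunPercentage",
  "modality": "normalized SPECT",
  "description": "Nr / Np, direction-averaged"
 },
 {
  "index": 27,
  "column": "spect_glrlm_ShortRunEmphasis",
  "modality": "normalized SPECT",
  "description": "sum P(i,j)/j^2 / Nr, direction-averaged"
 }
]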