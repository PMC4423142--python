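{
  "model_id": "eq2_gapls",
  "method": "GA-PLS selected subset, reported as the collapsed linear equation",
  "descriptors": ["IC1", "Mor24m", "Mor15e", "Mor32e"],
  "coefficients": [6.363, 2.119, -0.665, -0.784],
  "coef_se": [0.394, 0.485, 0.189, 0.37],
  "intercept": -12.589,
  "intercept_se": 1.208,
  "stats": {"N": 24, "R2_c": 0.932, "SE": 0.328, "Q2_LOO": 0.9, "RMS_CV": 0.391}
}
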