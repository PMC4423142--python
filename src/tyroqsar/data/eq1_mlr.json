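{
  "model_id": "eq1_mlr",
  "method": "stepwise MLR on the pooled CDFS descriptor set",
  "descriptors": ["IC1", "Mor24m", "RDF115m", "SP20", "Mor15e"],
  "coefficients": [5.965, 1.464, -0.187, 0.307, 1.284],
  "coef_se": [0.488, 0.618, 0.044, 0.067, 0.514],
  "intercept": -13.428,
  "intercept_se": 1.72,
  "stats": {"N": 24, "R2_c": 0.958, "SE": 0.285, "Q2_LOO": 0.921, "RMS_CV": 0.346}
}
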