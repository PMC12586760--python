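{
  "description": "Published vital rates of the three little-penguin growth phenotypes (fast/slow/light). Proportion-type rates carry 95% CIs from GLM/GLMM fits; survival rates carry Hessian-based CIs from the capture-mark-recapture model.",
  "hatching_success": {"estimate": 0.796, "n_events": 3768, "n_individuals": 648},
  "sex_ratio": 0.5,
  "adult_breeding_probability": 1.0,
  "clusters": {
    "fast": {
      "f":  {"estimate": 0.96, "ci": [0.94, 0.97], "n": 1104},
      "S0": {"estimate": 0.20, "ci": [0.11, 0.33], "n": 901},
      "S1": {"estimate": 0.70, "ci": [0.55, 0.82]},
      "S2": {"estimate": 0.83, "ci": [0.69, 0.92]},
      "S3": {"estimate": 0.78, "ci": [0.64, 0.83]},
      "Sa": {"estimate": 0.90, "ci": [0.77, 0.96]},
      "P2": {"estimate": 0.47, "ci": [0.34, 0.61], "n": 49},
      "P3": {"estimate": 0.50, "ci": [0.32, 0.68], "n": 26},
      "P4": {"estimate": 1.0, "n": 13},
      "Pa": {"estimate": 1.0},
      "C":  {"estimate": 0.32, "ci": [0.27, 0.39], "n": 284, "n_individuals": 49}
    },
    "slow": {
      "f":  {"estimate": 0.98, "ci": [0.97, 0.99], "n": 758},
      "S0": {"estimate": 0.17, "ci": [0.09, 0.28], "n": 610},
      "S1": {"estimate": 0.66, "ci": [0.50, 0.79]},
      "S2": {"estimate": 0.80, "ci": [0.65, 0.91]},
      "S3": {"estimate": 0.91, "ci": [0.73, 0.98]},
      "Sa": {"estimate": 0.88, "ci": [0.75, 0.95]},
      "P2": {"estimate": 0.29, "ci": [0.15, 0.50], "n": 24},
      "P3": {"estimate": 0.53, "ci": [0.30, 0.74], "n": 17},
      "P4": {"estimate": 1.0, "n": 8},
      "Pa": {"estimate": 1.0},
      "C":  {"estimate": 0.30, "ci": [0.22, 0.40], "n": 127, "n_individuals": 24}
    },
    "light": {
      "f":  {"estimate": 0.39, "ci": [0.34, 0.45], "n": 436},
      "S0": {"estimate": 0.08, "ci": [0.04, 0.18], "n": 111},
      "S1": {"estimate": 0.47, "ci": [0.28, 0.67]},
      "S2": {"estimate": 0.65, "ci": [0.42, 0.83]},
      "S3": {"estimate": 0.82, "ci": [0.54, 0.95]},
      "Sa": {"estimate": 0.77, "ci": [0.55, 0.91]},
      "P2": {"estimate": 0.67, "ci": [0.15, 0.96], "n": 3},
      "P3": {"estimate": 0.0, "ci": [0.0, 1.0], "n": 1},
      "P4": {"estimate": 1.0, "n": 1},
      "Pa": {"estimate": 1.0},
      "C":  {"estimate": 0.12, "ci": [0.02, 0.54], "n": 8, "n_individuals": 3}
    }
  }
}
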