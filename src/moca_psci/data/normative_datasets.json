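{
  "conti": {
    "full_name": "Conti et al. normative dataset (Italian MoCA norms)",
    "es0_cutoff": 17.36,
    "age_range": [60, 80],
    "coefficients": {
      "age_slope": 0.175,
      "age_center": 70.08,
      "edu_slope": 24.3,
      "edu_center": 0.126
    }
  },
  "santangelo": {
    "full_name": "Santangelo et al. normative dataset (Italian MoCA norms)",
    "es0_cutoff": 15.5,
    "age_range": [21, 95],
    "coefficients": {
      "age_slope": 4.228,
      "age_center": 1.58,
      "edu_slope": 3.201,
      "edu_center": 3.25
    }
  },
  "aiello": {
    "full_name": "Aiello et al. normative dataset (Italian MoCA norms)",
    "es0_cutoff": 18.58,
    "age_range": [21, 96],
    "coefficients": {
      "age_slope": 8e-06,
      "age_center": 297697.184801,
      "edu_slope": 3.331407,
      "edu_center": 2.325648
    }
  }
}
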