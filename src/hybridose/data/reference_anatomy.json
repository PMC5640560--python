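{
  "comment": "Reference organ masses (g) by age model, after ICRP-style reference anatomy, used for the default-mass organ-level dosimetry arm and for pediatric plausibility ranges. Whole-body masses in kg.",
  "age_models": {
    "1":     {"kidneys": 70,  "liver": 330,  "spleen": 29,  "body_kg": 10},
    "5":     {"kidneys": 110, "liver": 570,  "spleen": 50,  "body_kg": 19},
    "10":    {"kidneys": 180, "liver": 830,  "spleen": 80,  "body_kg": 32},
    "15":    {"kidneys": 250, "liver": 1300, "spleen": 130, "body_kg": 56},
    "adult": {"kidneys": 310, "liver": 1800, "spleen": 150, "body_kg": 73}
  },
  "pediatric_mass_ranges_g": {
    "left_kidney": [35, 160],
    "right_kidney": [35, 160],
    "kidneys": [70, 320],
    "liver": [300, 1500],
    "spleen": [25, 200]
  }
}
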