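{
 "prevalence_tol_pp": 0.05,
 "anchor_rel_tol": 0.01,
 "settings": {
  "rural": {
   "baseline": {"low": 0.0483, "moderate": 0.0007, "high": 0.0009},
   "gdp_per_capita": 10167,
   "age18_prevalence_pct": {"school_screening": 89.16, "traditional": 87.63, "digital": 85.37},
   "high_myopia_reduction_pp": 1.81,
   "cost_per_person": {"school_screening": 171, "traditional": 218, "digital": 324},
   "qaly_per_person": {"school_screening": 9.57764, "traditional": 9.58509, "digital": 9.59448},
   "daly_per_person": {"school_screening": 0.06562, "traditional": 0.06189, "digital": 0.05905},
   "subgroup_cost_per_person": {
    "perfect_outdoor_activity": 321,
    "perfect_vision_test_coverage": 343,
    "perfect_spectacles": 484,
    "perfect_hospital_examination": 683
   },
   "subgroup_daly_per_person": {
    "perfect_outdoor_activity": 0.05766,
    "perfect_vision_test_coverage": 0.05878,
    "perfect_spectacles": 0.05342,
    "perfect_hospital_examination": 0.05324
   }
  },
  "urban": {
   "baseline": {"low": 0.1256, "moderate": 0.0019, "high": 0.0025},
   "gdp_per_capita": 13856,
   "age18_prevalence_pct": {"school_screening": 90.04, "traditional": 88.64, "digital": 86.56},
   "high_myopia_reduction_pp": 1.35,
   "cost_per_person": {"school_screening": 607, "traditional": 729, "digital": 819},
   "qaly_per_person": {"school_screening": 9.56321, "traditional": 9.57119, "digital": 9.57964},
   "daly_per_person": {"school_screening": 0.06552, "traditional": 0.05886, "digital": 0.0567},
   "subgroup_cost_per_person": {
    "perfect_outdoor_activity": 808,
    "perfect_vision_test_coverage": 882,
    "perfect_spectacles": 1003,
    "perfect_hospital_examination": 1071
   },
   "subgroup_daly_per_person": {
    "perfect_outdoor_activity": 0.05564,
    "perfect_vision_test_coverage": 0.05534,
    "perfect_spectacles": 0.04949,
    "perfect_hospital_examination": 0.05107
   }
  }
 }
}
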