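{
 "meta": {
  "label": "calibrated surrogate parameter set (frozen fixture)",
  "provenance": "calibrated surrogate, not original appendix values",
  "currency": "USD",
  "cost_year": 2021,
  "seed": 0
 },
 "economics": {
  "exchange_rate": 6.45,
  "cost_adjustment_rate": 0.05,
  "discount_rate": 0.05,
  "national_gdp_per_capita": 12551,
  "urbanization_rate": 0.65,
  "urban_rural_income_ratio": 2.5,
  "cohort_size": 100000
 },
 "screening_test": {
  "sensitivity": 0.85,
  "specificity": 0.9
 },
 "effects": {
  "outdoor": {
   "onset_rate_multiplier": 0.5
  },
  "spectacles": {
   "progression_rate_multiplier": {
    "rural": 0.265689707734316,
    "urban": 0.051889906823803886
   }
  }
 },
 "payoffs": {
  "utility": {
   "non": 1.0,
   "low": {
    "rural": 0.9489472041877954,
    "urban": 0.9511275806298466
   },
   "moderate": {
    "rural": 0.9489472041877954,
    "urban": 0.9511275806298466
   },
   "high": {
    "rural": 0.9489472041877954,
    "urban": 0.9041073120288349
   }
  },
  "disability_weight": {
   "non": 0.0,
   "low": {
    "rural": 0.00045218177181965274,
    "urban": 1.3913012765493978e-07
   },
   "moderate": {
    "rural": 0.006157704779915433,
    "urban": 0.03729175538043917
   },
   "high": {
    "rural": 0.11545299909287493,
    "urban": 0.03729175538043917
   }
  }
 },
 "strategies": {
  "school_screening": {
   "education_channel": "none",
   "education_exposure": 0.0,
   "compliance_overrides": {
    "referral": {
     "rural": 0.26545546592353825,
     "urban": 0.5932358177407067
    }
   }
  },
  "traditional": {
   "education_channel": "traditional",
   "education_exposure": {
    "rural": 0.13248281235002476,
    "urban": 0.13219647152574576
   }
  },
  "digital": {
   "education_channel": "digital",
   "education_exposure": {
    "rural": 0.3031096743958917,
    "urban": 0.30345635459867
   }
  }
 },
 "settings": {
  "rural": {
   "baseline": {
    "low": 0.0483,
    "moderate": 0.0007,
    "high": 0.0009
   },
   "gdp_per_capita": 10167,
   "compliance": {
    "coverage": 0.918,
    "referral": 0.353,
    "spectacles": 0.36,
    "outdoor": 0.838
   },
   "transitions": {
    "onset": {
     "6": 0.10781442443041772,
     "7": 0.13476803053802217,
     "8": 0.1617216366456266,
     "9": 0.18867524275323103,
     "10": 0.21562884886083544,
     "11": 0.20664431349163398,
     "12": 0.19765977812243252,
     "13": 0.18867524275323103,
     "14": 0.17969070738402956,
     "15": 0.1557319463994923,
     "16": 0.13177318541495503,
     "17": 0.10781442443041772
    },
    "low_to_moderate": {
     "6": 0.18371177675878458,
     "7": 0.18371177675878458,
     "8": 0.18371177675878458,
     "9": 0.18371177675878458,
     "10": 0.18371177675878458,
     "11": 0.18371177675878458,
     "12": 0.18371177675878458,
     "13": 0.18371177675878458,
     "14": 0.18371177675878458,
     "15": 0.18371177675878458,
     "16": 0.18371177675878458,
     "17": 0.18371177675878458
    },
    "moderate_to_high": {
     "6": 0.07555543573148499,
     "7": 0.07555543573148499,
     "8": 0.07555543573148499,
     "9": 0.07555543573148499,
     "10": 0.07555543573148499,
     "11": 0.07555543573148499,
     "12": 0.07555543573148499,
     "13": 0.07555543573148499,
     "14": 0.07555543573148499,
     "15": 0.07555543573148499,
     "16": 0.07555543573148499,
     "17": 0.07555543573148499
    }
   },
   "costs": {
    "screening_per_test": 1.55,
    "education_traditional": 0.0,
    "education_digital": 11.405890689770922,
    "hospital_examination": 121.53726308469984,
    "treatment_annual": 23.766983639306563,
    "outdoor_program": 0.0
   }
  },
  "urban": {
   "baseline": {
    "low": 0.1256,
    "moderate": 0.0019,
    "high": 0.0025
   },
   "gdp_per_capita": 13856,
   "compliance": {
    "coverage": 0.918,
    "referral": 0.733,
    "spectacles": 0.683,
    "outdoor": 0.838
   },
   "transitions": {
    "onset": {
     "6": 0.10766081893707816,
     "7": 0.13457602367134772,
     "8": 0.16149122840561725,
     "9": 0.18840643313988675,
     "10": 0.2153216378741563,
     "11": 0.20634990296273317,
     "12": 0.19737816805131,
     "13": 0.18840643313988678,
     "14": 0.17943469822846364,
     "15": 0.15551007179800178,
     "16": 0.13158544536754,
     "17": 0.10766081893707816
    },
    "low_to_moderate": {
     "6": 0.13372091609281428,
     "7": 0.13372091609281428,
     "8": 0.13372091609281428,
     "9": 0.13372091609281428,
     "10": 0.13372091609281428,
     "11": 0.13372091609281428,
     "12": 0.13372091609281428,
     "13": 0.13372091609281428,
     "14": 0.13372091609281428,
     "15": 0.13372091609281428,
     "16": 0.13372091609281428,
     "17": 0.13372091609281428
    },
    "moderate_to_high": {
     "6": 0.04418047556147101,
     "7": 0.04418047556147101,
     "8": 0.04418047556147101,
     "9": 0.04418047556147101,
     "10": 0.04418047556147101,
     "11": 0.04418047556147101,
     "12": 0.04418047556147101,
     "13": 0.04418047556147101,
     "14": 0.04418047556147101,
     "15": 0.04418047556147101,
     "16": 0.04418047556147101,
     "17": 0.04418047556147101
    }
   },
   "costs": {
    "screening_per_test": 1.55,
    "education_traditional": 0.0,
    "education_digital": 11.57526129401446,
    "hospital_examination": 0.28356910631262444,
    "treatment_annual": 328.0355769205733,
    "outdoor_program": 0.0
   }
  }
 }
}
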