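{
  "input_scaling": "minmax_unit",
  "scaling_note": "Covariates are assumed min-max normalized to [0,1] per variable before entering the linear predictor (anthropometric ordinals mapped over their 8 z-score bins); the source report does not state the normalization, so this declaration is an assumption surfaced in the model card.",
  "models": {
    "CDelay": {
      "description": "BSID-III cognitive composite < 85 at 24 months corrected age; predictors up to 12 months",
      "intercept": 4.39,
      "terms": [
        ["bsid_mot_12m", -2.22, "Motor BSID-III score at 12 months"],
        ["bsid_cog_12m", -3.71, "Cognitive BSID-III score at 12 months"],
        ["abdominal_surgery", 1.36, "Abdominal surgery"],
        ["ippv_days", -2.56, "IPPV days"],
        ["ph_first_blood_gas", -1.14, "pH in first-time blood gas"],
        ["oxygen_supply_ge40", 0.28, "Oxygenation supply >= 40%"],
        ["hc_6m", -1.48, "Head circumference at 6 months CA (8 z-score bins)"],
        ["maternal_edu_le12y", 0.34, "Maternal education <= 12 years"],
        ["body_length_6m", 0.8, "Body length at 6 months CA (8 z-score bins)"],
        ["hs_pda", -0.15, "Hemodynamically significant PDA"]
      ]
    },
    "MDelay": {
      "description": "BSID-III motor composite < 85 at 24 months corrected age; predictors up to 12 months",
      "intercept": 4.98,
      "terms": [
        ["bsid_mot_12m", -8.09, "Motor BSID-III score at 12 months"],
        ["bsid_cog_12m", -3.31, "Cognitive BSID-III score at 12 months"],
        ["nicu_days", 2.89, "NICU days"],
        ["pma_discharge", -1.66, "Post-menstrual age at discharge"]
      ]
    },
    "CRegres": {
      "description": "BSID-III cognitive composite declines >= 15 points between 6 and 24 months; predictors up to 6 months",
      "intercept": -4.42,
      "terms": [
        ["bsid_cog_6m", 8.47, "Cognitive BSID-III score at 6 months"],
        ["bsid_mot_6m", -1.04, "Motor BSID-III score at 6 months"],
        ["maternal_mgso4", -0.65, "Maternal MgSO4 use"],
        ["parental_edu_le12y", 0.23, "Parental education <= 12 years"]
      ]
    },
    "MRegres": {
      "description": "BSID-III motor composite declines >= 15 points between 6 and 24 months; predictors up to 6 months",
      "intercept": -5.84,
      "terms": [
        ["bsid_mot_6m", 9.91, "Motor BSID-III score at 6 months"],
        ["antenatal_steroid", 0.52, "Antenatal steroid use"],
        ["hc_admission", 0.08, "Head circumference at admission (8 z-score bins)"],
        ["prom", 0.007, "Prolonged rupture of membranes"]
      ]
    }
  }
}
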