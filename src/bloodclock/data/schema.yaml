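# Default CHARLS-like variable schema: 24 clock predictors (16 blood panel
# variables, sex, fasting flag, 6 biometric variables), 10 disease-history
# flags, raw psychosocial/demographic covariates, and meta variables.
# Ranges are broad physiological plausibility windows used by the exclusion
# stage; units are conventional clinical units.
#
# Note: the blood panel names both uric_acid and bun (blood urea nitrogen).
# Some summaries conflate "urea acid" with either; they are kept as two
# distinct analytes here.
variables:
  - {name: id, role: id, kind: key}
  - {name: chronological_age, role: meta, kind: continuous, units: years, range: [45, 120]}

  # --- clock predictors: blood panel -------------------------------------
  - {name: total_cholesterol, role: predictor, kind: continuous, units: mg/dL, range: [80, 400], group: blood}
  - {name: ldl_cholesterol, role: predictor, kind: continuous, units: mg/dL, range: [20, 300], group: blood}
  - {name: hdl_cholesterol, role: predictor, kind: continuous, units: mg/dL, range: [10, 150], group: blood}
  - {name: c_reactive_protein, role: predictor, kind: continuous, units: mg/L, range: [0, 50], group: blood}
  - {name: glucose, role: predictor, kind: continuous, units: mg/dL, range: [40, 500], group: blood}
  - {name: triglycerides, role: predictor, kind: continuous, units: mg/dL, range: [20, 1000], group: blood}
  - {name: uric_acid, role: predictor, kind: continuous, units: mg/dL, range: [1, 15], group: blood}
  - {name: cystatin_c, role: predictor, kind: continuous, units: mg/L, range: [0.2, 5], group: blood}
  - {name: mcv, role: predictor, kind: continuous, units: fL, range: [60, 120], group: blood}
  - {name: creatinine, role: predictor, kind: continuous, units: mg/dL, range: [0.2, 5], group: blood}
  - {name: hba1c, role: predictor, kind: continuous, units: percent, range: [3, 15], group: blood}
  - {name: hemoglobin, role: predictor, kind: continuous, units: g/dL, range: [5, 22], group: blood}
  - {name: hematocrit, role: predictor, kind: continuous, units: percent, range: [20, 65], group: blood}
  - {name: bun, role: predictor, kind: continuous, units: mg/dL, range: [2, 60], group: blood}
  - {name: platelet_count, role: predictor, kind: continuous, units: 1e9/L, range: [50, 600], group: blood}
  - {name: wbc_count, role: predictor, kind: continuous, units: 1e9/L, range: [1, 30], group: blood}

  # --- clock predictors: categorical -------------------------------------
  - {name: sex, role: predictor, kind: categorical, levels: [female, male], group: demographic}
  - {name: fasting, role: predictor, kind: binary, group: demographic}

  # --- clock predictors: biometric ---------------------------------------
  - {name: systolic_bp, role: predictor, kind: continuous, units: mmHg, range: [70, 250], group: biometric}
  - {name: diastolic_bp, role: predictor, kind: continuous, units: mmHg, range: [40, 150], group: biometric}
  - {name: bmi, role: predictor, kind: continuous, units: kg/m2, range: [10, 60], group: biometric}
  - {name: waist_circumference, role: predictor, kind: continuous, units: cm, range: [40, 200], group: biometric}
  - {name: heart_rate, role: predictor, kind: continuous, units: bpm, range: [30, 200], group: biometric}
  - {name: spirometry, role: predictor, kind: continuous, units: L/min, range: [50, 900], group: biometric}

  # --- disease-history flags ----------------------------------------------
  # "mild" conditions may appear in the test set; "serious" conditions route
  # a participant to the discovery set.
  - {name: hypertension, role: disease_flag, kind: binary, group: mild}
  - {name: arthritis, role: disease_flag, kind: binary, group: mild}
  - {name: dyslipidemia, role: disease_flag, kind: binary, group: mild}
  - {name: kidney_disease, role: disease_flag, kind: binary, group: mild}
  - {name: diabetes, role: disease_flag, kind: binary, group: mild}
  - {name: cancer, role: disease_flag, kind: binary, group: serious}
  - {name: heart_disease, role: disease_flag, kind: binary, group: serious}
  - {name: stroke, role: disease_flag, kind: binary, group: serious}
  - {name: lung_disease, role: disease_flag, kind: binary, group: serious}
  - {name: liver_disease, role: disease_flag, kind: binary, group: serious}

  # --- raw covariates (binarized for the attribution stage) ---------------
  - {name: area, role: covariate, kind: categorical, levels: [urban, rural], group: demographic}
  - {name: marital_status, role: covariate, kind: categorical, levels: [never_married, married, widowed], group: social}
  - {name: smoking, role: covariate, kind: binary, group: lifestyle}

  # CES-D-style frequency-of-feeling items over the past week, coded
  # 0 = rarely or none of the time (< 1 day) ... 3 = most or all of the time.
  # Each maps to a "rarely ..." indicator that is 1 iff the response is 0.
  - {name: freq_bothered, role: covariate, kind: ordinal, levels: [0, 1, 2, 3], group: psych, indicator: rarely_bothered}
  - {name: freq_lacks_focus, role: covariate, kind: ordinal, levels: [0, 1, 2, 3], group: psych, indicator: rarely_lacks_focus}
  - {name: freq_depressed, role: covariate, kind: ordinal, levels: [0, 1, 2, 3], group: psych, indicator: rarely_depressed}
  - {name: freq_hopeful, role: covariate, kind: ordinal, levels: [0, 1, 2, 3], group: psych, indicator: rarely_hopeful}
  - {name: freq_fearful, role: covariate, kind: ordinal, levels: [0, 1, 2, 3], group: psych, indicator: rarely_fearful}
  - {name: freq_restless_sleep, role: covariate, kind: ordinal, levels: [0, 1, 2, 3], group: psych, indicator: restless_sleep_is_rare}
  - {name: freq_happy, role: covariate, kind: ordinal, levels: [0, 1, 2, 3], group: psych, indicator: rarely_happy}
  - {name: freq_lonely, role: covariate, kind: ordinal, levels: [0, 1, 2, 3], group: psych, indicator: rarely_lonely}
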