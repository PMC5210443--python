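# Default clinical-management rule set for hypertension and diabetes mellitus
# in primary care.  Band boundaries follow contemporaneous standard guideline
# cuts (screen-positive hypertension at >=140/90, immediate drug initiation
# above 160/100, urgency/emergency referral at >=180/120, diabetes at fasting
# glucose >=126 mg/dL, prediabetes 100-125).  All thresholds live here, never
# in code, so a revised guideline table drops in without a code change.
#
# Bands are half-open [lo, hi) on an integer measurement grid (mm Hg, mg/dL).
version: "2.1.5"
formulary: [amlodipine, enalapril, atenolol, metformin, glimepiride]
# Drug precedence used when merging comorbid hypertension + diabetes plans.
precedence: [amlodipine, enalapril, atenolol, metformin, glimepiride]
counseling_items:
  [diet, tobacco_cessation, physical_activity, alcohol_moderation, drug_compliance]

hypertension:
  # Classification = the more severe of the SBP band and the DBP band.
  domain: {sbp: [60, 260], dbp: [40, 160]}
  severity_order: [normal, prehypertension, stage1, stage2, urgency]
  bands:
    sbp:
      - {name: normal, lo: 60, hi: 120}
      - {name: prehypertension, lo: 120, hi: 140}
      - {name: stage1, lo: 140, hi: 161}   # 140-160 inclusive: confirmatory revisit
      - {name: stage2, lo: 161, hi: 180}   # >160: immediate management
      - {name: urgency, lo: 180, hi: 260}  # >=180: refer to higher centre
    dbp:
      - {name: normal, lo: 40, hi: 80}
      - {name: prehypertension, lo: 80, hi: 90}
      - {name: stage1, lo: 90, hi: 101}    # 90-100 inclusive
      - {name: stage2, lo: 101, hi: 120}   # >100
      - {name: urgency, lo: 120, hi: 160}  # >=120
  # Treatment target for titration: below stage1 on both arms.
  target: {sbp_below: 140, dbp_below: 90}
  plans:
    normal: {drugs: initiate_none, counseling: [], referral: false}
    prehypertension:
      drugs: initiate_none
      counseling: [diet, tobacco_cessation, physical_activity, alcohol_moderation]
      referral: false
    stage1:
      drugs: initiate_first
      counseling:
        [diet, tobacco_cessation, physical_activity, alcohol_moderation, drug_compliance]
      referral: false
    stage2:
      drugs: initiate_first
      counseling:
        [diet, tobacco_cessation, physical_activity, alcohol_moderation, drug_compliance]
      referral: false
    urgency:
      drugs: initiate_none
      counseling: [drug_compliance]
      referral: true
      referral_reason: hypertensive urgency/emergency
  ladder:
    - {drug: amlodipine, doses_mg: [2.5, 5, 10], frequency: od}
    - {drug: enalapril, doses_mg: [2.5, 5, 10, 20], frequency: od}
    - {drug: atenolol, doses_mg: [25, 50, 100], frequency: od}

diabetes:
  domain: {fpg: [50, 500], random_glucose: [50, 500]}
  severity_order: [normal, prediabetes, diabetes]
  bands:
    fpg:
      - {name: normal, lo: 50, hi: 100}
      - {name: prediabetes, lo: 100, hi: 126}
      - {name: diabetes, lo: 126, hi: 500}
    # Non-fasting (random) glucose only triages: screen-positive values are
    # recalled in fasting state for confirmatory laboratory diagnosis.
    random_glucose:
      - {name: normal, lo: 50, hi: 140}
      - {name: screen_positive, lo: 140, hi: 500}
  target: {fpg_below: 126}
  plans:
    normal: {drugs: initiate_none, counseling: [], referral: false}
    prediabetes:
      drugs: initiate_none
      counseling: [diet, tobacco_cessation, physical_activity, alcohol_moderation]
      referral: false
    diabetes:
      drugs: initiate_first
      counseling:
        [diet, tobacco_cessation, physical_activity, alcohol_moderation, drug_compliance]
      referral: false
  ladder:
    - {drug: metformin, doses_mg: [500, 1000, 1500, 2000], frequency: bd}
    - {drug: glimepiride, doses_mg: [1, 2, 4], frequency: od}
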