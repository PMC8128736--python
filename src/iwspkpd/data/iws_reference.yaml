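# Reference withdrawal-model parameter estimates (pediatric ICU cohort).
typical_baseline: 0.564
iiv_baseline_cv_percent: 114.0
delta: 0.428
pi_same_prev0: 0.401
pi_same_prevx: 0.216
pi_pm: 0.0698
drug_effects:
  fentanyl:
    k_dep: 0.242       # 1/h
    slope: 5.93        # ml/ng
    concentration_unit: ng/mL
  morphine:
    k_dep: 0.00848
    slope: 0.0687
    concentration_unit: ng/mL
  ketamine:
    k_dep: 0.0180
    slope: 1.59        # ml/mcg
    concentration_unit: mcg/mL
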