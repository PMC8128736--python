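# Illustrative pediatric PK parameter sets (editable defaults).
# Values are stand-ins in the range of published pediatric population models;
# reference weight 70 kg, allometric scaling CL ~ (WT/70)^0.75, V ~ (WT/70)^1.0.
# Analyses should state the PK parameters they use explicitly.
morphine:
  n_compartments: 2
  CL: 60.0        # L/h at 70 kg
  V_c: 150.0      # L
  Q2: 30.0
  V2: 100.0
  ka: 1.0         # 1/h, extravascular absorption
  F: 0.3          # oral bioavailability
  dose_unit: mg
  concentration_unit: ng/mL
fentanyl:
  n_compartments: 2
  CL: 50.0
  V_c: 100.0
  Q2: 200.0
  V2: 250.0
  dose_unit: mcg
  concentration_unit: ng/mL
ketamine:
  n_compartments: 1
  CL: 80.0
  V_c: 150.0
  dose_unit: mg
  concentration_unit: mcg/mL
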