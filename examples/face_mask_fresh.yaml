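# 8-h wear of an AgCur-coated face mask on fresh (healthy) skin.
# Family-average areal load and abrasion release constant; permeation rate
# constant from the fresh-skin Franz-cell measurement.
label: face-mask AgCur fresh
product:
  load_ng_cm2: 1530.0
  area_cm2: 555.0
  fa: 1.0
rates:
  kp_per_min: 0.086
  ksc_per_h: 1.8e-6
schedule:
  horizon_h: 8.0
  wear_h: 8.0
subject:
  bw_kg: 60.0
  dnel_mg_kg_day: 0.01
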