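# Representative healthy adult subject (defaults; all overridable).
body_weight: 60.0          # kg
liver_mass: 1650.0         # g
mppgl: 40.0                # mg microsomal protein per g liver
hepatic_blood_flow: 90.0   # L/h
cyp_abundance:
  CYP3A4: 1.0
  CYP3A5: 0.5              # *1/*3 expresser; set 0 for *3/*3 non-expresser
  other: 1.0
kdeg:
  CYP3A4: 0.0193           # 1/h (36-h turnover half-life)
  CYP3A5: 0.0193
portal_volume: 1.0         # L
portal_flow_fraction: 0.75
liver_kp: 4.0              # liver:blood partition
gut_transit: 20.0          # gut wall -> portal blood, 1/h
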