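# SYNTHETIC tacrolimus victim config.
#
# The source publications for the tacrolimus PBPK model are not reproduced
# here; this file is a synthetic stand-in with literature-plausible
# physicochemistry (extensive erythrocyte partitioning, low plasma unbound
# fraction).  The clearance magnitude and its CYP3A4/CYP3A5 split are NOT
# meaningful as shipped: calibrate_baseline() replaces clint_hlm and
# enzyme_fractions so the simulated 2-mg oral whole-blood AUC(0-120 h)
# matches the genotype-specific control exposures.
name: tacrolimus
mw: 804.02
logp: 3.3
fu_plasma: 0.013
bp_ratio: 35.0     # whole-blood:plasma; blood concentrations are reported
fa: 0.95
ka: 4.5            # 1/h
vss: 45.5          # L/kg plasma-referenced (≈1.3 L/kg in whole blood)
kp_scalar: 1.0
clint_hlm: 1000.0  # placeholder, replaced by calibration
enzyme_fractions:
  CYP3A4: 0.85
  CYP3A5: 0.10
  other: 0.05
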