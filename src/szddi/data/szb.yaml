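# Schizandrol B — PBPK inputs and CYP3A inhibition constants
# (genotyped-microsome values: reversible + time-dependent inhibition on both
# CYP3A4 and CYP3A5).
name: SZB
mw: 416.47
logp: 3.380
fu_plasma: 0.084
bp_ratio: 0.785
fa: 0.734
ka: 0.437          # 1/h
peff: 1.000        # 1e-4 cm/s, informational
vss: 2.225         # L/kg
kp_scalar: 1.0
clint_hlm: 4.5     # µL/min/mg microsomal protein
enzyme_fractions:
  CYP3A4: 0.0
  CYP3A5: 0.0
  other: 1.0
interaction:
  mode: RI_and_TDI
  enzymes:
    CYP3A4:
      ki: 2.03       # µM
      KI: 0.69       # µM
      kinact: 0.37   # 1/min
    CYP3A5:
      ki: 2.18       # µM
      KI: 0.5        # µM
      kinact: 0.009  # 1/min
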