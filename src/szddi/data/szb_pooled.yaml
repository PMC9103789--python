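# Schizandrol B with pooled-HLM (lumped CYP3A) inhibition constants, as an
# alternative to the genotyped-microsome spec in szb.yaml: the pooled Ki/KI/
# kinact are applied to both CYP3A4 and CYP3A5.
name: SZB
mw: 416.47
logp: 3.380
fu_plasma: 0.084
bp_ratio: 0.785
fa: 0.734
ka: 0.437
peff: 1.000
vss: 2.225
kp_scalar: 1.0
clint_hlm: 4.5
enzyme_fractions:
  CYP3A4: 0.0
  CYP3A5: 0.0
  other: 1.0
interaction:
  mode: RI_and_TDI
  enzymes:
    CYP3A4:
      ki: 5.82
      KI: 0.43
      kinact: 0.044
    CYP3A5:
      ki: 5.82
      KI: 0.43
      kinact: 0.044
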