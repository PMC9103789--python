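# Schizandrol A — PBPK inputs and CYP3A inhibition constants
# (genotyped-microsome values: weak time-dependent inactivation of CYP3A4
# only; no measurable reversible inhibition, so no ki entries).
name: SZA
mw: 432.52
logp: 3.390
fu_plasma: 0.083
bp_ratio: 1.254
fa: 0.500
ka: 0.218          # 1/h
peff: 0.500        # 1e-4 cm/s, informational
vss: 2.516         # L/kg
kp_scalar: 0.5
clint_hlm: 50.0    # µL/min/mg microsomal protein
# Perpetrator elimination routed through the non-CYP3A lump: its own CYP3A
# share is unknown, and this avoids conflating auto-inhibition with the
# victim interaction.
enzyme_fractions:
  CYP3A4: 0.0
  CYP3A5: 0.0
  other: 1.0
interaction:
  mode: TDI_only
  enzymes:
    CYP3A4:
      KI: 15.38      # µM
      kinact: 0.024  # 1/min
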