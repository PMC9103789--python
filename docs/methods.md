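# Methods

This note documents the models implemented in `szddi`, the assumptions they
make, the defaults they ship with, and what the synthetic-data tests do and
do not demonstrate.

## In vitro inhibition kinetics

### IC50 and IC50 shift

Normalized activity (fraction of the uninhibited control) is fit to a
logistic curve on log10 inhibitor concentration,

    A([I]) = bottom + (top − bottom) / (1 + 10^(h·(log10[I] − log10 IC50))),

with `top = 1` and `bottom = 0` fixed by default because the data are
control-normalized and the reference assays report percentages of control
activity; a free-bottom variant is available behind `free_bottom=True`.
The IC50 shift is IC50(no NADPH preincubation)/IC50(with 30-min NADPH
preincubation); values above 1.5 flag time-dependent inhibition (TDI).
Zero-concentration wells anchor the normalization but are excluded from the
log-concentration regression.  Datasets whose per-level mean activity spans
less than `flat_tolerance` (default 0.05) raise a "no inhibition detected"
error rather than returning an unbounded IC50.

### Dixon Ki

For a competitive inhibitor, 1/v is linear in [I] at every substrate level
and the lines intersect at [I] = −Ki.  Replicate wells are averaged per
(substrate, inhibitor) design point — the conventional Dixon plot of
triplicate means — before ordinary least squares of 1/v on [I] per substrate
level.  All pairwise line intersections are computed; their abscissae are
combined by a mean weighted by the product of the two slopes'
|t|-statistics (capped at 10⁶ so noiseless, zero-SE fits keep finite
weights), and Ki = −(weighted mean).  A common intersection — and hence the
"competitive" label — is accepted when the weighted SD of the abscissae is
below 25% of |mean| and the mean lies left of zero; otherwise the result is
`none_detected` with no Ki.  Lines count as showing inhibition only when the
slope |t| ≥ 2 and the relative rise of 1/v across the inhibitor range
exceeds 1% (small enough that a weak but noiseless signal, Ki far above the
design range, is still detected exactly).

On noiseless competitive data this estimator is exact (every pair intersects
at −Ki).  At 5% assay CV with the default 4×4 triplicate design it is
deliberately conservative: roughly a third of simulated datasets fail the
25%-spread rule and return `none_detected` instead of a forced Ki; among
accepted fits the median relative error is under 10%.  We regard refusing an
ill-determined intersection as correct behaviour for a screening assay, not
a defect to be tuned away.

### Time-dependent inactivation

Remaining activity after preincubation time t decays as exp(−kobs·t); kobs
at each preincubation concentration is the negated least-squares slope of
ln(activity) vs t.  By default the slope of the zero-inhibitor control
series is subtracted first, removing NADPH-independent activity loss (the
reference analysis does not state whether its kobs were control-corrected,
so the correction is switchable via `control_correct=False`); the result is
clipped at zero.  kobs saturates in concentration as

    kobs = kinact·[I] / (KI + [I]),

fit by nonlinear least squares with the Kitz–Wilson double-reciprocal line
(1/kobs vs 1/[I]) retained as a diagnostic cross-check, never as the
estimate.  The inactivation efficiency kinact/KI is reported in mL/min/µmol
(min⁻¹/µM × 1000).  Fits use the *preincubation-stage* inhibitor
concentration: the two-step protocol transfers a 20 µL aliquot into 180 µL
for the activity read, so the carryover concentration during the read is
10-fold lower (`applied_inhibitor_conc` implements both stages) and only the
preincubation concentration drives inactivation.

All three fits are exposed as scikit-learn style estimators
(`IC50Regressor`, `DixonKiEstimator`, `InactivationKineticsEstimator`,
`TDIActivityEstimator`) so they compose with sklearn tooling; the module
functions `fit_ic50` / `fit_dixon` / `fit_kobs` / `fit_tdi` /
`fit_inactivation` are thin dataset-level wrappers.

## PBPK model

A deliberately minimal, single-subject model: oral depot →(ka)→ gut wall
→(fast transit, 20 h⁻¹)→ portal blood → liver → central plasma compartment,
with an optional peripheral compartment (off by default).  Absorption is
first-order with fraction absorbed `fa`; the unabsorbed fraction never
enters the system.  The central volume is `Vss · Kp scalar · body weight`
with the published Vss values taken as inputs (no tissue-composition
prediction).  Hepatic elimination removes drug at `fu_b · CLint' · C_out`,
where `C_out` is the liver outflow blood concentration and
`fu_b = fu_plasma/(B:P)`, so the steady-state clearance is exactly the
well-stirred model CLh = Qh·fu_b·CLint/(Qh+fu_b·CLint).  A useful corollary
used throughout testing and calibration: oral AUC = fa·D/(fu_b·CLint),
independent of hepatic blood flow.

Microsomal intrinsic clearance scales to the whole organ as
CLint,liver(e) = CLint,HLM · fraction(e) · MPPGL · liver mass ·
abundance(e) · 60/10⁶ (µL/min → L/h), per enzyme e ∈ {CYP3A4, CYP3A5,
other}.

Subject defaults (all overridable): body weight 60 kg, liver 1650 g, MPPGL
40 mg/g, hepatic blood flow 90 L/h, portal fraction 0.75, portal volume 1 L,
liver:blood partition 4, CYP turnover kdeg 0.0193 h⁻¹ (36-h half-life) for
both CYP3A4 and CYP3A5, CYP3A5 abundance scalar 0.5 for *1/*3 expressers and
0 for *3/*3 non-expressers.  These are this package's own representative
values for a healthy adult; they do not claim to equal any proprietary
population library.

Integration uses LSODA with rtol 1e-8 / atol 1e-10 and a 0.05-h output grid;
doses are instantaneous depot additions with the integrator restarted at
every dose event (the post-dose state is kept at boundary points so mass
balance holds on the output grid).  The mass-balance residual
|absorbed − (in system + eliminated)| is checked at every output time and is
typically below 1e-10 of the dose.  PK metrics: Cmax/Tmax from the grid
maximum, AUC by trapezoid with no extrapolation.  Fold error is
max(predicted, observed)/min(predicted, observed).

The perpetrator configs (`data/sza.yaml`, `data/szb.yaml`) carry the
published physicochemical/absorption/distribution inputs; their own
elimination is routed through the non-CYP3A lump so perpetrator
auto-inhibition does not confound the victim interaction (their CYP3A share
is not published).  Peff is stored but unused by the first-order absorption
model.

## DDI model

The perpetrator's unbound liver concentration Iu = fu_b·C_out (µM) drives
two mechanisms per enzyme:

* reversible: CLint(e) is scaled by 1/(1 + Iu/Ki);
* mechanism-based: the active enzyme fraction f(e) obeys
  df/dt = kdeg·(1 − f) − kobs(Iu)·f with kobs = 60·kinact·Iu/(KI + Iu) h⁻¹,
  so the steady-state fraction is kdeg/(kdeg + kobs).

The driving concentration is a documented choice (the liver is the modeled
interaction site); it is the unbound *outflow* concentration under the
well-stirred assumption.  Shipped interaction constants follow the
genotyped-microsome results: SZA is a weak CYP3A4-only inactivator
(KI 15.38 µM, kinact 0.024 min⁻¹, no reversible component); SZB inhibits
both enzymes reversibly (Ki 2.03 µM CYP3A4 / 2.18 µM CYP3A5 — the source
tables disagree on which value belongs to which enzyme, and we follow the
summary assignment; only the value set is load-bearing) and irreversibly
(CYP3A4: KI 0.69 µM, kinact 0.37 min⁻¹; CYP3A5: KI 0.5 µM, kinact
0.009 min⁻¹).  The pooled-microsome constants ship as an alternative spec
(`szb_pooled.yaml`).

### Victim baseline calibration

Tacrolimus model inputs are not published alongside the inhibition data, so
the package ships a synthetic config (plausible fu, B:P, Vss; see
`tacrolimus_synthetic.yaml`) and pins the two quantities that matter for the
DDI — clearance magnitude and its CYP3A5 share — to the genotype-specific
control exposures: simulated 2-mg oral whole-blood AUC(0–120 h) of
118.07 ng/mL·h in non-expressers and 62.50 ng/mL·h in expressers.  Because
oral AUC is exactly inversely proportional to CLint here, each target is one
Brent root-finding on the same CLint→AUC map; total CLint T and CYP3A5
fraction φ then follow algebraically (non-expresser effective CLint =
T·(1−φ), expresser = T·(1−φ) + s·T·φ with abundance scalar s), with the
non-CYP3A share fixed at 5%.  The resulting fm splits (≈0.86/0/0.14
non-expresser, ≈0.46/0.47/0.07 expresser) are written back into the genotype
scenarios.  Calibration fails loudly when the genotype scalars make the two
targets unreachable (e.g. both zero) or a target is outside the achievable
AUC range.

### Scenario designs and outputs

Single-dose: perpetrator (33.6 mg SZA or 10.8 mg SZB) and 2 mg tacrolimus at
t = 0.  Multiple-dose: perpetrator b.i.d. (16.8 / 5.4 mg, 12-h spacing, 27
doses over 13.5 days), tacrolimus 2 mg at t = 324 h.  The victim AUC window
is the 120 h after the victim dose (the reference does not state its
window); AUCR = AUC(with)/AUC(without) on identical grids, and mechanism
cases restrict the interaction spec to RI only, TDI only, or both.  A static
mechanistic oracle,

    AUCR = 1 / ( Σ_e fm_e · ri_e · kdeg/(kdeg + kobs_e) + fm_other ),

is exact for the dynamic model under constant unbound exposure with enzymes
at steady state and serves as an independent cross-check (agreement within
2% in the tests, using a window long enough that truncation is negligible).

### What the minimal model does and does not reproduce

With the published compound inputs, single-dose perpetrator Cmax lands
within 2-fold of the reference predictions (72.7 vs 126.88 ng/mL for SZA,
50.9 vs 66.70 for SZB) — acceptable screening accuracy by the <2-fold
convention.  Predicted Tmax is later than reference (first-order absorption
vs a mechanistic dissolution/absorption model), and SZB's simulated
disposition (CLh ≈ 3 L/h, effective half-life ≈ 30 h from the published
CLint/Vss) accumulates far more on b.i.d. dosing than the reference
engine's, so simulated multiple-dose SZB AUCRs (≈6.2 non-expresser, ≈4.3
expresser) exceed the published 1.57/1.23.  The qualitative structure is
preserved and tested: AUCR(non-expresser) > AUCR(expresser) > 1 for SZB,
combined mechanism ≥ either alone, multiple-dose TDI ≥ single-dose, AUCR
monotone in perpetrator dose, and SZA (weak, CYP3A4-only; simulated
multiple-dose AUCR ≈ 1.03) ≪ SZB.  Quantitative reproduction of the
published inhibited AUCs would require the proprietary absorption and
population models that generated them.

## Synthetic data

Generators are pure functions of (spec, seed) and produce datasets that pass
assay validation.  Noise is multiplicative lognormal parameterized by CV
(responses are positive); an additive-Gaussian variant exists behind a flag.
Default designs copy the reference incubation layouts (concentration series,
preincubation times {0, 5, 10, 20, 30} min, triplicates).  At CV = 0 every
generate→fit closure recovers its truth to ≤1e-6 relative; at CV = 5% the
TDI pipeline's median worst-parameter error over 200 seeds is ≈12–14%.
The generators emulate design geometry and multiplicative assay noise only —
no inter-day drift, no matrix effects, no heteroscedastic quantification
error — so passing recovery tests demonstrates estimator correctness and
statistical behaviour under idealized noise, not robustness to every
real-laboratory artifact.

## Numerical and degenerate-input choices

* Nonlinear fits: `scipy.optimize.curve_fit` with bounds and tolerances
  1e-13; non-convergence raises a fitting error carrying residuals or the
  Kitz–Wilson fallback.
* Logs of non-positive activities raise a domain error rather than being
  masked.
* All-zero kobs maps raise "no inactivation"; flat IC50 curves raise "no
  inhibition detected".
* Display rounding (tables, fold errors, AUCRs) is half-up on the formatted
  string only; JSON outputs keep full precision.
* One source table prints an IC50 of "11.98 M"; context (the concentration
  series runs to 20 µM) makes this µM, and the package treats it as µM.
  A preincubation temperature printed as "3 °C" is treated as typographic
  for 37 °C; temperature is metadata only.
* Published single-dose AUCR values for SZA differ between the text (1.10)
  and the scenario table (1.00); the package pins the table and notes the
  discrepancy here rather than resolving it.

## Problem sizes

Test and acceptance runs use the study's own designs (tens of wells per
assay), 200-seed recovery ensembles, and simulations of 120–600 h at a
0.05-h output grid — the full scenario grid, not a reduced one.
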