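# Methods

## Scope and model structure

`gestpbpk` predicts maternal and fetal escitalopram exposure across
pregnancy. The disposition model is a whole-body, perfusion-limited PBPK
system: a lumped blood pool exchanging with eleven explicit tissues
(adipose, bone, brain, gut, heart, kidney, liver, lung, muscle, skin,
spleen) plus a rest-of-body compartment. Gut and spleen drain through the
portal vein into the liver; all other tissues exchange directly with blood.
Oral absorption is first-order from a depot into the liver, with the
bioavailable fraction `fa * Fg` applied at absorption (`Fg` from the hybrid
gut-flow model `Fg = Qgut / (Qgut + fu_gut * CLu_int,gut)`). Elimination is
well-stirred hepatic clearance (`CLh = Qh fu_B CLu_int / (Qh + fu_B CLu_int)`,
blood basis) and renal clearance from blood scaled by the GFR ratio to
baseline. Lungs are treated as one of the parallel systemic tissues rather
than in series with the heart; at this level of lumping the distinction has
no visible effect on plasma kinetics and it keeps the flow bookkeeping
(tissue flows summing to cardiac output) exact.

Amounts are carried in µg with volumes in L, so concentrations are ng/mL
throughout; intrinsic clearances enter in µL/min/pmol and are converted in
one place.

## Numerical method

Between dose events the system is linear and time-invariant, `dx/dt = Mx`.
The default propagator is the matrix exponential of `M * dt` applied
stepwise on the output grid (default 0.1 h), which is exact for the linear
system at any step size; repeated doses are depot-replenishment events at
which propagation restarts, so no discontinuity crosses a step. An adaptive
LSODA integration (default rtol 1e-8, atol 1e-10) is available as an
independent cross-check and agrees with the propagator to better than 0.5%
pointwise in the test suite. Mass balance (administered dose = body content
+ cumulative eliminated + first-pass loss) is checked after every
simulation; the matrix is conservative by construction (columns sum to
zero). PK metrics are computed on the final dosing interval by trapezoid on
the dense output.

One consequence of the exact propagator: an intravenous-bolus input
produces a distribution spike faster than the output grid, so the analytic
AUC oracle in the tests is evaluated through the cumulative-elimination
states (`AUC = A_renal(inf) / CL_R`) rather than a trapezoid over the
spike.

## Physiology and gestational scaling

The nonpregnant reference female (gestational week 0) is a bundled fixture:
60 kg, cardiac output 300 L/h, GFR 121 mL/min, liver 1500 g, MPPGL
40 mg/g, hematocrit 0.40, plasma volume 2.4 L, and hepatic CYP abundances
CYP2C19/CYP2D6/CYP3A4 = 14/8/137 pmol/mg microsomal protein. Tissue
volumes and flows are in `data/baseline_physiology.csv`.

Every pregnancy-adapted parameter follows the polynomial scaling law

    value(GW) = value(0) * (1 + b1 GW + b2 GW^2 + b3 GW^3 + b4 GW^4).

CYP2D6 activity uses b1 = 0.0163, b2 = 0.0009 and CYP3A4 uses b1 = 0.0129,
b2 = 0.0005; CYP2C19 activity is held constant (all coefficients zero).
The remaining trajectories (GFR, cardiac output, plasma volume, binding
protein, hematocrit) are quartics fitted once to reference curves from the
pregnancy-physiology literature — GFR rising ~40% by week 9 with a
mid-gestation plateau near +55%, cardiac output and plasma volume rising
~45% by term, alpha-1 acid glycoprotein falling to 80% of baseline, and
hematocrit diluted to 88% of baseline — and shipped as data
(`data/pregnancy_coefficients.csv`), overridable in config. Tissue blood
flows scale proportionally with cardiac output so they always sum to it.

Escitalopram is treated as bound predominantly to alpha-1 acid
glycoprotein (a documented package decision — the compound table does not
name the binding protein). Fraction unbound is rescaled for the protein
level assuming linear binding: `fu = 1 / (1 + ((1-fu0)/fu0) * ratio)`.

Fetal weight follows `3.7 kg * (GW/40)^3` and amniotic volume
`750 mL * (GW/40)^1.5`, smooth monotone curves anchored to the term means
(3.7 kg; 750 mL/day swallowed at term).

## Partitioning and distribution

Tissue-to-plasma partition coefficients use the mechanistic equations for
moderate-to-strong monoprotic bases, in which ionic association with
tissue acidic phospholipids dominates; the association constant is
back-calculated from erythrocyte partitioning (via B/P = 2.0, hematocrit
and fu). The published tissue-composition constants are bundled as a
fixture (`data/tissue_composition.csv`; the rest-of-body row reuses muscle
composition). Each Kp is multiplied by the compound's Kp scalar (0.92).
With the reference physiology this predicts Vss ≈ 10.4 L/kg, within 25% of
the 13.5 L/kg reference value; the difference reflects the fixture
composition and volumes, not the drug parameters. Because the acidic-
phospholipid term is derived from erythrocyte binding, predicted Kp values
are nearly invariant to fu — the gestational fall in binding protein
affects clearance much more than distribution.

## Gut first pass

The lumped unbound gut intrinsic clearance (0.3414 L/h) was chosen so that
overall oral bioavailability `fa * Fg * Fh` equals 0.80 at week 0,
anchoring the model to the drug's reported ~80% bioavailability given the
compound table's fa = 1.0. This yields Fg = 0.943 with the fitted
Qgut = 5.69 L/h. A corollary explored in estimation: with only ~6% gut
extraction, Qgut is very weakly identified from plasma data (see
Limitations).

## Fetoplacental unit

From gestational week 15 the maternal system is extended with a
permeability-limited placenta: maternal plasma <-> placental node (CL_PDM)
and placental node <-> fetal plasma (CL_PDF), both 0.80902 L/h (the single
shared reference value) and both driven by unbound concentrations — the
unbound basis is a documented package choice. The placental node is small
(0.5 L) so the barriers dominate kinetics. Fetal plasma volume is
0.045 L/kg fetal weight; fetal fraction unbound uses a fetal
binding-protein level of 0.37 of the maternal week-0 value. Fetal renal
clearance (Eq.-form: adult CL_R x fetal/adult GFR per kg, 0.044 L/h/kg)
moves drug from fetal plasma to amniotic fluid; swallowing clearance
(0.00844 L/h/kg) returns it, fully reabsorbed. The only true exit from the
fetoplacental unit is back-transfer to the mother.

Because the fetal loop is conservative, at the periodic steady state the
net placental flux over a dosing interval is exactly zero, which forces
`fu_m <C_maternal> = fu_f <C_fetal>`: the interval-averaged
total-concentration cord-to-maternal ratio equals `fu_m / fu_f`. With the
maternal protein ratio 0.80 at term and the fetal ratio 0.37 this gives
0.496/0.680 ≈ 0.73, the model's mechanistic explanation for the sub-unity
clinical cord ratio — and why the ratio is exactly dose-independent in a
linear model. The cord ratio is reported as the ratio of interval-averaged
concentrations over the final dosing interval (the trough-based ratio is
available from the profile arrays); the sampling time of the underlying
delivery measurements is not standardized, so the time-averaged definition
is the package convention.

## Populations and phenotypes

Virtual subjects perturb the per-isoform intrinsic clearances (CV 35%),
ka (25%), Kp scalar (20%) and fu (15%) with median-preserving log-normal
factors (`X = default * exp(sigma Z)`, `sigma = sqrt(ln(1+CV^2))`); the
CVs are package defaults (no reference variability settings exist) and are
configurable. CYP2C19 phenotype is assigned by frequency (Caucasian
fixture {PM 0.02, IM 0.26, NM 0.60, UM 0.12}; only the PM ~2% anchor is
literature-fixed) and multiplies the CYP2C19 intrinsic clearance with
defaults {UM 1.5, NM 1.0, IM 0.45, PM 0.05}. Trial design follows the
repeated-trial convention (10x10 default; 20x20 for dose scans), reported
as the mean profile with 5th/95th percentile bands.

A structural cap worth knowing: the reference intrinsic clearances and
abundances put ~64% of hepatic intrinsic clearance on CYP2C19, so even a
PM multiplier of zero can raise exposure only ~2.2-fold over NM
(`scripts/calibrate_phenotypes.py` reproduces this scan); the ~3.3-fold
clinical PM/NM ratio is unattainable in this structure, and PM exposure at
early gestation correspondingly sits slightly higher relative to the
therapeutic floor than the reference analysis reports (the PM trough at
week 7 on 10 mg lands ≈ 16–17 ng/mL, just above the 15 ng/mL floor).

## Sensitivity screening

Global sensitivity uses the Morris elementary-effects method (hand
implementation: r one-at-a-time trajectories on a 4-level grid, effects on
the unit scale, µ* = mean |EE| for ranking, σ for interaction). The nine
screened drug parameters are fa, ka, fu_gut, Qgut, logP, Kp scalar and the
three intrinsic clearances, each over ±50% of its default, evaluated on
the single-dose 20 mg nonpregnant simulation (the verification design),
outputs Cmax and full-horizon AUC. The binding ratios fu_p and B/P are
deliberately excluded: each rescales the reported plasma concentration or
clearance in a directly monotone, almost unit-like way that would dominate
the ranking without adding disposition insight. With this set the top-3
ranking is {Kp scalar, fa, ka} for Cmax and {fa, CLint CYP2C19, CLint
CYP2D6} for AUC, stable across seeds at r = 20.

## Parameter estimation

ka, Qgut and Kp scalar are estimated by weighted least squares
(`w = 1/obs^2` default, matching the proportional residual model; uniform
and 1/obs available) minimized by Nelder–Mead in log-parameter space, with
restarts drawn log-uniformly within bounds (default: a factor of four
either side of the reference values; 100 restarts by default, fewer
suffice in practice). The synthetic-data module generates the fitting
datasets: per-subject simulation, sparse steady-state sampling (default
{1, 2, 4, 6, 12, 24} h after the last dose; a 12-point rich grid for
estimation studies), multiplied by median-preserving log-normal residual
error. The reference estimation study uses 25 subjects on the rich grid
with 15% proportional noise and no between-subject variability.

## Therapeutic-window assessment

Regimens are classified per (dose, week, phenotype) cell against the
15–80 ng/mL steady-state trough range with a 160 ng/mL alert level and a
17 ng/mL average-concentration threshold. Classification uses the
population mean profile (20x20 trials), with the 5th-percentile subject's
trough reported alongside; troughs within 20% below the floor are flagged
"near" and never silently merged into "within". Weeks 7, 21 and 35
represent the trimesters. Classification is monotone in dose and exposure
falls with gestation for every phenotype (both properties are tested).

## What the synthetic data do and do not show

Synthetic observations share the model's own structure (same disposition
model, log-normal residuals, known truth), so closure tests — coverage of
self-generated data by the 5th–95th band ≈ 0.90, recovery of generating
parameters — validate the pipeline's statistical machinery, not the
biology. Real concentration data carry model misspecification,
assay-timing error and covariate structure that these tests cannot
surface.

## Known limitations

* Qgut is near-nonidentifiable from plasma data at ~6% gut extraction:
  noise-free recovery is exact, but under 15% proportional noise its
  median recovery error is ~35–45% (ka ~8%, Kp scalar ~9%), because
  percent-level drift in the fitted profile level is amplified ~17x
  through `d lnFg / d lnQgut ≈ 0.057`.
* Absolute exposures depend on the bundled reference physiology; they sit
  ~15–20% below the reference analysis's absolute predictions, while
  relative quantities (gestational percent reductions, cord ratio, dose
  linearity) are robust to the fixture choice.
* No metabolite kinetics, no saturable elimination, no transporters, no
  enterohepatic recirculation, no fetal metabolic clearance or fetal
  phenotypes, and no gestational change in CYP2C19 activity (held
  constant by design).
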