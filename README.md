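# gestpbpk

Physiologically based pharmacokinetic (PBPK) modeling of **escitalopram in
pregnancy**: maternal whole-body disposition scaled continuously with
gestational age, a permeability-limited fetoplacental unit, CYP2C19
phenotype stratification, model-qualification statistics, Morris
sensitivity screening, weighted-least-squares parameter estimation, and
therapeutic-window dose assessment.

It is written for pharmacometricians and DMPK scientists who want an open,
testable implementation of a pregnancy PBPK analysis: every fixture
(reference physiology, gestational trajectories, tissue composition,
compound table) ships as data in the package and is overridable.

## Model sketch

Maternal disposition is a perfusion-limited 13-compartment system with
first-order oral absorption, well-stirred hepatic elimination and
GFR-scaled renal clearance:

    CLh = Qh · fu_B · CLu_int / (Qh + fu_B · CLu_int),
    CLu_int = Σ_isoform CLint,i · abundance_i · MPPGL · liver weight · activity_i(GW)

Pregnancy enters through the gestational polynomial

    P(GW) = P(0) · (1 + B1·GW + B2·GW² + B3·GW³ + B4·GW⁴)

applied to enzyme activities (CYP2D6: B1=0.0163, B2=0.0009; CYP3A4:
B1=0.0129, B2=0.0005; CYP2C19 constant), GFR, cardiac output, plasma
volume, binding protein and hematocrit. From week 15 a placental node
links maternal and fetal plasma through two diffusion barriers
(CL_PDM = CL_PDF = 0.80902 L/h) driven by unbound concentrations, with
fetal renal clearance into amniotic fluid (0.044 L/h/kg) and swallowing
back to the fetus (0.00844 L/h/kg). Between doses the system is linear, so
profiles are propagated with a matrix exponential (exact) and
cross-checked against LSODA. See `docs/methods.md` for the full account.

## Worked example

```python
import gestpbpk as g

compound, fetal = g.load_compound()          # escitalopram reference table
regimen = g.DoseRegimen(dose=10, interval=24, n_doses=10)

for gw in (0, 20, 35):
    prof = g.simulate_individual(compound, g.build_physiology(gw), regimen)
    m = g.compute_pk_metrics(prof, 24.0)
    print(f"gw {gw:2d}: Cmax {m.c_max:5.2f} ng/mL  AUCtau {m.auc:6.1f} ng·h/mL")

term = g.simulate_pregnant_with_fetus(
    compound, g.build_physiology(40), regimen, fetal_params=fetal)
print("cord:maternal ratio", round(g.cord_to_maternal_ratio(term), 3))
```

prints

```
gw  0: Cmax 15.57 ng/mL  AUCtau  298.1 ng·h/mL
gw 20: Cmax 12.09 ng/mL  AUCtau  224.6 ng·h/mL
gw 35: Cmax  9.92 ng/mL  AUCtau  178.3 ng·h/mL
cord:maternal ratio 0.728
```

i.e. steady-state exposure falls by ~25% at week 20 and ~40% at week 35
(rising CYP2D6/CYP3A4 activity, falling protein binding, rising GFR), and
the fetus at term sees ~73% of maternal plasma levels — the ratio of
maternal to fetal unbound fractions, since the placental loop conserves
mass (see the methods note).

A CLI wraps the pipeline stages:

```bash
gestpbpk simulate --stage pregnant
gestpbpk optimize-dose
gestpbpk make-synthetic && gestpbpk fit --observed gestpbpk_out/synthetic_observed.csv
gestpbpk sensitivity
```

Each stage writes profile CSVs, summary tables and a run manifest (config
hash, seed, package version) so identical config + seed reproduces
identical outputs.

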