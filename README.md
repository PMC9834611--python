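# vinpbpk

A cross-species physiologically based pharmacokinetic (PBPK) model of
vinblastine, for pharmacologists and modelers who need mechanistic,
tissue-level simulations of vinca-alkaloid disposition in mouse (wild-type
and Mdr1a/b(−/−) knockout), dog, and human.

Vinblastine has a narrow therapeutic index, and its kinetics are dominated
by three tissue-level mechanisms this package represents explicitly:

- **Saturable intracellular tubulin binding.** Each tissue's venous (free)
  concentration satisfies `C_T = C_V (PC + BC/(K_D + C_V))`, with
  tissue-specific binding capacities `BC` (nmol/kg), partition coefficients
  `PC`, and `K_D = 196.08` nM. The unique non-negative root is solved in
  closed form.
- **ABCB1 (P-glycoprotein) efflux.** Michaelis–Menten transport
  `sf_T · V_T · V_max · C/(K_m + C)` scaled by relative tissue expression
  (brain 1.0, kidney 0.78, liver 0.28, gut 0.14), with a
  permeability-limited blood–brain barrier (PSA = 0.379 ml/h) whose efflux
  returns drug to the brain vasculature. The knockout scenario zeroes the
  transporter, reproducing the ~10-fold brain exposure increase seen in
  Mdr1a/b(−/−) mice.
- **Saturable elimination**: CYP-mediated hepatic metabolism
  (`V_LIV · V_max,M · C/(K_m,M + C)`, microsome-derived with IVIVE scaling),
  biliary transport, and glomerular filtration (`GFR·Q_kid·C_A`), tracked as
  cumulative metabolized/feces/urine sinks so mass balance closes exactly.

Around the nine-compartment stiff ODE core the package provides
noncompartmental analysis (linear-log trapezoidal AUC, terminal half-life
by log-linear regression), prediction-error metrics (PE, MAPE%, MPE%,
RMSPE%), bounded nonlinear least-squares calibration with AIC/BIC
comparison, seeded Monte Carlo virtual populations (lognormal parameter
sampling with Iman–Conover rank correlation), and a synthetic-data module
that emulates destructive mouse sampling and sparse clinical schedules.

## Worked example

Simulate 2 mg/kg IV bolus vinblastine in wild-type and knockout mice and
compute the NCA quantities on the study's 0.083–6 h sampling schedule:

```python
from vinpbpk import simulate_iv_bolus, studies
from vinpbpk.studies import study_nca

wt = studies.mouse_wild_type()
ko = studies.mouse_knockout()
sim_wt = simulate_iv_bolus(wt.physiology, wt.drug, wt.dose, t_end=6.0)
sim_ko = simulate_iv_bolus(ko.physiology, ko.drug, ko.dose, t_end=6.0)

for label, sim in [("wild-type", sim_wt), ("Mdr1a/b(-/-)", sim_ko)]:
    serum = study_nca(sim, "blood", wt.schedule)
    brain = study_nca(sim, "brain_tissue", wt.schedule)
    print(f"{label:13s} serum AUC(0.083-6h) = {serum.auc:6.1f} nM*h   "
          f"brain AUC = {brain.auc:6.1f} nM*h   "
          f"serum t1/2 = {serum.t_half:.2f} h")
```

prints

```
wild-type     serum AUC(0.083-6h) =  186.0 nM*h   brain AUC =  128.1 nM*h   serum t1/2 = 0.77 h
Mdr1a/b(-/-)  serum AUC(0.083-6h) =  194.5 nM*h   brain AUC = 1599.0 nM*h   serum t1/2 = 0.85 h
```

Serum exposure is nearly genotype-independent (efflux is a minor fraction
of total clearance), while brain exposure rises 12.5-fold when ABCB1 is
absent: the transporter, not the barrier permeability, keeps vinblastine
out of the wild-type brain. Note the AUC runs from the first scheduled
sample — the seconds-scale central distribution spike after a bolus is not
part of a measured profile (see `docs/methods.md`).

A CLI mirrors the library:

```bash
vinpbpk simulate --species mouse --scenario mdr1a1b_knockout \
    --dose-mg-per-kg 2 --t-end 6 --out ko.csv
vinpbpk mc --species dog --dose-mg-per-kg 0.086 --t-end 24 \
    --n 100 --seed 42 --out popdir/
vinpbpk nca --in obs.csv --t1 24 --out nca.csv
```

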