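# mgpk — population PK and dose optimization of IV magnesium sulfate in preeclampsia

Magnesium sulfate is the first-line anticonvulsant for preventing eclamptic
seizures, but it has a narrow therapeutic margin (2–3.5 mmol/L serum
magnesium) and published dosing schemes often leave patients below target.
`mgpk` is a Python package for pharmacometricians and clinical-pharmacology
researchers that implements the full analysis chain behind a
population-pharmacokinetic (PPK) dose-optimization study of IV MgSO4 in
women with preeclampsia:

* **pk_core** — analytic one-compartment model with zero-order infusion
  input and superposition over arbitrary multi-day schedules,
  `C(t) = baseline + Σ (R0/CL)(1 − e^(−k·Δt))·e^(−k·Δt')`, `k = CL/V`;
* **covariate_model** — individual parameters
  `CL_i = tvCL·(CCR/ref)^θ₁·(BMI/ref)^θ₂·(1 + θ₃·FURO)·e^ηCL`,
  `V_i = tvV·(1 + θ₄·FURO)·e^ηV`, η log-normal with diagonal Ω;
* **estimation** — FOCE nonlinear mixed-effects fitting (vectorized inner
  Gauss-Newton for the conditional modes, linearized marginal −2LL) with
  OFV/AIC/BIC, empirical-Bayes etas, shrinkage and standard errors;
* **scm** — stepwise covariate modeling: forward inclusion at ΔOFV ≥ 6.63
  (χ²₁, α = 0.01), backward elimination at ΔOFV ≥ 10.83 (α = 0.001);
* **diagnostics** — goodness-of-fit (PRED/IPRED/CWRES), nonparametric
  bootstrap over subjects, visual predictive check;
* **dosing_sim** — Monte Carlo probability of target attainment (PTA) for
  four candidate regimens over a renal-function × body-size × furosemide grid,
  with the >90%-in-window-after-hour-4 appropriateness rule;
* **synthetic_data** — a generator emulating the 51-subject study design
  (day-1 load + maintenance, day-2 maintenance, sparse 0/4/5/12 h sampling,
  published covariate distributions), so every stage runs with no external
  data;
* **io / pipeline / cli** — NONMEM-style CSV event datasets with strict
  validation, a declarative YAML config, and a `mgpk` command line
  (`simulate-data`, `fit`, `scm`, `bootstrap`, `vpc`, `pta`, `run-all`).

See `docs/methods.md` for the model, estimation details, units
(internally mg/L elemental Mg; 1 mmol/L = 24.305 mg/L) and design choices.

## Worked example

```python
import numpy as np
from mgpk import (generate_study, foce_fit, reference_model_spec,
                  mg_to_mmol, conc_profile, individual_params,
                  ThetaVector, Covariates)

# 1. simulate a study emulating the clinical design (51 subjects)
dataset, truth = generate_study(seed=1)
print(dataset.n_subjects, dataset.n_obs)        # 51 192

# 2. fit the final covariate model by FOCE
fit = foce_fit(dataset, reference_model_spec())
print(round(fit.ofv, 1), round(fit.params["tvCL"], 2),
      round(fit.params["tvV"], 2))              # 1102.7 4.04 27.01

# 3. predict a typical furosemide user's day-2 profile
theta = ThetaVector()                            # published estimates
cov = Covariates(CCR=175, BMI=29, furosemide=1)
p = individual_params(theta, cov, baseline=0.76 * 24.305)
from mgpk import Regimen
reg = Regimen.from_grams([(0.0, 5.0, 1/3), (1/3, 10.0, 6.7)])
prof = conc_profile(reg, p, np.arange(0, 8.5, 0.5))
print(round(float(mg_to_mmol(prof.total.max())), 2))   # 1.85
```

The single-study estimates (tvCL 4.04 L/h, tvV 27.01 L here) scatter around
the generating values 2.98 and 25.07 — one sparse 51-subject study carries
limited information; the medians across 50 replicate studies land within a
few percent (see below). The typical furosemide user peaks at 1.85 mmol/L
under a 5 g + 10 g regimen, just below the 2.0 mmol/L window edge, which is
why the Monte Carlo stage weighs loading dose and covariates.

Full pipeline from the shell:

```bash
mgpk run-all --outdir results/run1          # defaults; or --config my.yaml
mgpk pta --n 1000 --out results/pta.csv     # dose-optimization grid only
```

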