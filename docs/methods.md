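# Methods

## Scope and model

`mgpk` implements a population-pharmacokinetic (PPK) analysis of intravenous
magnesium sulfate (MgSO4) for seizure prophylaxis in preeclampsia, together
with the Monte Carlo dose-optimization that such an analysis feeds. The
structural model is a one-compartment disposition model with first-order
elimination and zero-order (infusion) input. During an infusion at rate `R0`
begun at `t0` the above-baseline concentration is
`(R0/CL)·(1 − e^(−k·(t−t0)))` with `k = CL/V`; after the infusion end the
end-of-infusion value decays mono-exponentially. The model is linear, so
multi-day schedules are handled by superposition of per-infusion
contributions. Total serum magnesium is the drug contribution plus an
endogenous baseline.

Individual parameters come from a log-normal covariate model:

    CL_i = tvCL · (CCR_i/ref_CCR)^dCLdCCR · (BMI_i/ref_BMI)^dCLdBMI
                · (1 + dCLdfurosemide·FURO_i) · exp(ηCL_i)
    V_i  = tvV  · (1 + dVdfurosemide·FURO_i) · exp(ηV_i)

with `η ~ N(0, diag(ω²CL, ω²V))` and a residual error that may be additive
(`stdev0`), proportional (`cv0`) or combined. Proportional coefficients are
stored signed and applied as `(1 + coef·x)`, so a factor printed as
`(1 − 0.16·furosemide)` corresponds to `coef = −0.16`.

## Units

Internally every concentration is mg/L of elemental magnesium. Clinical
quantities convert at 1 mmol/L = 24.305 mg/L; labeled dose grams convert at
98.61 mg elemental Mg per gram of MgSO4·7H2O (MW 246.47), the salt form of
clinical injection solutions; both constants are configurable. The additive
residual SD of the default parameter set (3.65) is plausible only on the
mg/L scale (0.15 mmol/L), which fixes the internal unit choice. The
therapeutic window 2–3.5 mmol/L maps to 48.6–85.1 mg/L.

The power-term normalization constants default to `ref_CCR = ref_BMI = 51`,
matching the printed form of the source equations, but 51 is almost surely a
transcription artifact (it equals the study's sample size; conventional
practice normalizes by the covariate median, CCR ≈ 182 ml/min and BMI ≈ 29
kg/m²). Both references are plain constructor arguments, and every recovery
experiment in this package is reference-invariant because simulation and
fitting share the same reference.

## Estimation

Estimation is first-order conditional (FOCE/Laplace family). For each
candidate `(θ, Ω, Σ)`:

1. **Inner problem.** Each subject's conditional mode `η*` of the joint
   density is found by a damped Gauss-Newton iteration using the analytic
   gradient of the infusion model with respect to `(ηCL, ηV)`
   (`∂f/∂ηCL = −C + kS`, `∂f/∂ηV = −kS`, where `C` is the above-baseline
   prediction and `S` the summed event sensitivities `∂c/∂k`). The
   Gauss-Newton Hessian is symmetric positive definite, each 2×2 system is
   solved in closed form, and the iteration is vectorized across subjects
   (padded, masked observation grids) with per-subject backtracking; the
   stopping rule is a maximum eta step below 1e−8.
2. **Outer objective.** The marginal −2 log-likelihood is approximated by
   linearizing `f` around `η*`: `y_i ~ N(f(η*) − G η*, G Ω Gᵀ + Σ)`. The
   objective (OFV) includes all 2π constants. With an additive residual the
   interaction term is immaterial and Σ is constant; for proportional or
   combined residuals Σ is evaluated at the conditional mode (FOCE with
   interaction).
3. **Outer optimization.** Variances and typical values are
   log-transformed, proportional coefficients atanh-transformed (keeping
   every factor positive without constrained solvers), power exponents left
   free. A quasi-Newton pass (L-BFGS-B, finite-difference gradients) is
   followed by a Nelder-Mead polish; the result is never allowed to be
   worse than the supplied inits. During optimization power-covariate
   references are internally re-centered at the sample median — an exact
   reparameterization, undone on reporting — because a reference far
   outside the covariate range makes `tvCL` and the exponents nearly
   collinear and the raw surface badly conditioned.

`AIC = OFV + 2p` and `BIC = OFV + p·ln(n_obs)` with `p` the number of free
parameters. Empirical-Bayes etas are the conditional modes at the optimum;
shrinkage is `100·(1 − SD(EBE)/ω)`, clipped to [0, 100] with a warning.
Standard errors come from the central-difference Hessian of OFV/2 on the
natural parameter scale; a non-invertible Hessian yields missing SEs, not
an exception. Non-convergence is flagged on the result, never raised.

The FOCE approximation is exact when the model is linear in eta; the test
suite verifies agreement with dense 2-d Gauss-Hermite quadrature to better
than 1% in the small-omega regime and ~2% at the default omega. Exact
quadrature is deliberately not a production path.

## Covariate selection

Stepwise covariate modeling tests one candidate effect at a time with
likelihood-ratio thresholds on ΔOFV: forward inclusion at α = 0.01
(χ²₁ = 6.63, inclusive) accepting the largest qualifying drop per step, then
backward elimination at α = 0.001 (χ²₁ = 10.83), removing the least
supported effect first. Ties break lexicographically on the coefficient
name; candidate fits that fail to converge are skipped and logged. Each
effect costs one degree of freedom. Continuous candidates enter as power
functions centered on the dataset median; categorical candidates as
proportional shifts. The full decision trace (both OFVs, ΔOFV, threshold,
decision) is recorded so every selection can be replayed from the log.

## Diagnostics

* **GOF**: PRED (all etas zero), IPRED (at the EBE), and CWRES — the
  residual vector `y − f(η*) + Gη*` whitened by the Cholesky factor of
  `G Ω Gᵀ + Σ` at the EBE. Under a correct model CWRES is approximately
  standard normal; the suite checks mean within ±0.15, SD in [0.8, 1.2] and
  ≥90% of values within ±2 on self-simulated data.
* **Bootstrap**: nonparametric, resampling subjects (all their rows) with
  replacement at the original subject count; non-convergent replicates are
  excluded and counted. One master seed spawns per-replicate substreams, so
  summaries are independent of execution order. The default replicate count
  in the pipeline configuration is 200 (1000 is the conventional
  publication-scale choice; it changes runtime, not code paths).
* **VPC**: replicate studies are simulated at the observed design (each
  subject's own covariates, doses and sampling times). Observations are
  binned by nominal sampling time — appropriate for this sparse,
  nominal-time design — and observed 5/50/95th percentiles are compared
  with the 2.5/50/97.5 envelope of the same percentiles across simulations.
  Both the per-percentile envelopes and the pooled 2.5–97.5 predictive band
  (with the fraction of observations inside it) are reported, since the two
  conventions differ between the Methods text and figure captions of
  published VPCs.

## Dose simulation

Four fixed regimens (2.5 or 5 g loading over 20 min, then 10 g over 6.7 h
or 15 g over 7.7 h, maintenance starting at loading end) are simulated for
1000 virtual individuals per covariate cell (CCR 140/175/213 ml/min × BMI
27/29/33 kg/m² × furosemide 0/1). Attainment is judged on the noise-free
(model-predicted) total concentration — residual error is assay noise, not
biology — with a configuration switch to include it. A constant endogenous
baseline of 0.76 mmol/L is added; without it the window is unreachable at
these doses. The appropriateness rule is strict: more than 90% of
individuals inside the closed window [2.0, 3.5] mmol/L at every hourly
check from hour 4 through hour 8. The pipeline's recommendation rule picks,
per furosemide group, the regimen appropriate in the most cells, breaking
ties toward the lower total dose — guaranteeing exactly one first-line
recommendation per group.

A measured caveat: under the default (literally printed) `/51`
normalization, covariate-adjusted typical clearances at the grid cells are
5–8 L/h and no regimen pushes typical patients above ~2.2 mmol/L, so the
upper-bound overshoot expected of the 15 g regimens (the toxicity rationale
for preferring 10 g maintenance) does not appear; under the
median-normalization reading overshoot
appears in a minority of cells only. The corresponding acceptance test is
kept faithful to the claim and fails, documenting the discrepancy rather
than masking it.

## Synthetic data generator

The generator emulates the study design: 51 subjects; day 1 a 5 g load with
duration drawn uniformly from 0.5–2 h followed immediately by 10 g over
6–8 h; day 2 (offset fixed at 24 h, the source being silent) a 10 g
maintenance infusion; serum magnesium sampled at 0/4/5/12 h after the day-2
dose start. The pre-dose sample is always kept and each later sample is
dropped independently with probability 0.05, reconciling the stated "two to
four samples per subject" with the stated total of 199 samples from 51
women (mean 3.9). Covariates: CCR normal 182.18 ± 67.15 ml/min truncated
at 30; BMI log-normal matched to quartiles 27.16/29.13/33.30; furosemide
Bernoulli(0.3137); baseline magnesium log-normal matched to 0.71/0.76/0.86
mmol/L; age, albumin, calcium, labetalol, nifedipine and ADR matched to the
published population summaries and carrying no effect under the generating
truth. Observations add residual noise per the generating residual model
and are floored at zero.

What the generator does **not** emulate: time-varying covariates,
assay-specific error structure, clinician-driven dose adjustments,
dropout correlated with concentration, or day-3+ dosing. Passing recovery
tests therefore demonstrate estimator correctness under the stated design,
not robustness to real-world protocol deviations.

## Numerical choices and degenerate inputs

* Variance floor 1e−10 on omega when inverting (omega = 0 forces eta to 0
  exactly and reduces the fit to least squares).
* Residual-variance floor 1e−12 in the inner objective; a non-PD linearized
  covariance returns an infinite OFV, which the optimizer guards map to a
  large finite penalty.
* ΔOFV threshold comparisons carry a 1e−9 absolute slack so a drop exactly
  at the critical value qualifies despite round-off.
* Empty regimens predict baseline everywhere; events with zero amount are
  legal and contribute nothing (this is also how padded event arrays work).
* Default inits (tvCL 4 L/h, tvV 20 L, coefficients 0, ω² 0.1, stdev0 3
  mg/L) are generic mid-range values for this drug class.

## Problem sizes used in the shipped experiments

The recovery experiment (acceptance script and suite) uses 50 replicates of
the 51-subject design — the scale at which the median estimates stabilize
well inside the tolerance bands. The selection operating-characteristic
checks use 20 replicates (null and power arms); the power arm uses 200
subjects with 8 samples each, a rich design where the true CCR effect's
ΔOFV is far above threshold. VPC stability checks use 400–800 simulated
replicates; the pipeline defaults (bootstrap 200, VPC 500, PTA 1000) are
the package's own working defaults, with publication-scale counts a single
config change away.

## Known limitations

* Diagonal Ω only; no CL–V correlation (none is reported for this model).
* No SAEM/MCMC path; FOCE equivalence with other software is claimed at the
  level of parameter recovery, not OFV-value identity (different software
  differs in constants and ELS variants).
* ω²V (0.023) is weakly identified by the sparse 2–4-sample design: its
  median recovery bias is about −40%, and it is reported but not held to a
  tolerance anywhere.
* The baseline-handling question (total vs baseline-subtracted magnesium)
  is configurable (`baseline = data | constant | zero`) because the source
  analysis does not state its choice; the default uses each subject's known
  baseline, which is available in synthetic data but would be a pre-dose
  measurement in practice.
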