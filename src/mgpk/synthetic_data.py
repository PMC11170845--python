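"""Synthetic study generator emulating the IV-MgSO4 preeclampsia design.

The emulated study: 51 pregnant women with preeclampsia; on day 1 a 5 g
loading infusion (30-120 min, clinician-chosen rate) followed by a 10 g
maintenance infusion over 6-8 h; on day 2 a 10 g maintenance infusion with
serum magnesium sampled at 0, 4, 5 and 12 h after the day-2 dose start.
Each subject contributes 2-4 samples; the study as a whole yielded ~199
observations (mean 3.9 per subject), so the default design always keeps the
pre-dose sample and drops each later sample independently with 5%
probability.

Covariate distributions are matched to the study's population summaries:
creatinine clearance normal 182.18 +/- 67.15 ml/min (truncated at 30), BMI
log-normal matched to quartiles 27.16/29.13/33.30 kg/m2, furosemide
Bernoulli(0.3137), endogenous baseline magnesium log-normal matched to
0.71/0.76/0.86 mmol/L, plus nuisance covariates (age, albumin, calcium,
labetalol, nifedipine, ADR) that carry no effect under the generating truth
and exist so covariate selection has something to reject.

Concentration truth comes from pk_core + covariate_model under a
configurable generating parameter set whose default is the published final
model (reference_truth); residual noise is added per the residual model.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .covariate_model import ThetaVector, OmegaMatrix
from .estimation import ModelSpec, ResidualModel, _residual_variance
from .io import EventDataset
from .pk_core import infusion_superposition
from .units import DEFAULT_SALT_FACTOR, MG_PER_MMOL


def _lognormal_sigma_from_quartiles(q25: float, q50: float, q75: float) -> float:
    """Log-scale SD matching the average quartile spread (z_0.75 = 0.6745)."""
    z75 = 0.6744897501960817
    return 0.5 * (np.log(q75 / q50) + np.log(q50 / q25)) / z75


@dataclass(frozen=True)
class StudyDesign:
    n_subjects: int = 51
    loading_grams: float = 5.0
    loading_duration_range: tuple[float, float] = (0.5, 2.0)
    maintenance_grams: float = 10.0
    maintenance_duration_range: tuple[float, float] = (6.0, 8.0)
    day2_offset: float = 24.0
    sampling_offsets: tuple[float, ...] = (0.0, 4.0, 5.0, 12.0)
    #: probability each non-predose sample is missing (expected ~3.9 obs/subject)
    sample_dropout: float = 0.05
    salt_factor: float = DEFAULT_SALT_FACTOR

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if list(self.sampling_offsets) != sorted(self.sampling_offsets):
            raise ValueError("sampling_offsets must be sorted")
        for lo, hi in (self.loading_duration_range, self.maintenance_duration_range):
            if not 0 < lo <= hi:
                raise ValueError("duration ranges must be positive and ordered")


@dataclass(frozen=True)
class CovariateDistributions:
    ccr_mean: float = 182.18
    ccr_sd: float = 67.15
    ccr_min: float = 30.0
    bmi_median: float = 29.13
    bmi_log_sd: float = _lognormal_sigma_from_quartiles(27.16, 29.13, 33.30)
    furosemide_p: float = 0.3137
    baseline_median_mmol: float = 0.76
    baseline_log_sd: float = _lognormal_sigma_from_quartiles(0.71, 0.76, 0.86)
    age_mean: float = 31.86
    age_sd: float = 5.22
    age_range: tuple[float, float] = (18.0, 45.0)
    albumin_mean: float = 30.45
    albumin_sd: float = 4.66
    calcium_mean: float = 2.17
    calcium_sd: float = 0.15
    labetalol_p: float = 0.9803
    nifedipine_p: float = 0.4314
    adr_p: float = 0.4118


def reference_truth() -> tuple[ThetaVector, OmegaMatrix, ResidualModel]:
    """Default generating parameters: the final covariate model estimates
    for this population (additive residual, mg/L scale)."""
    return ThetaVector(), OmegaMatrix(), ResidualModel("additive", stdev0=3.65)


def reference_model_spec() -> ModelSpec:
    """ModelSpec matching the reference truth's covariate structure."""
    from .covariate_model import final_model_effects

    return ModelSpec(effects=final_model_effects(), residual="additive", baseline="data")


def theta_to_params(theta: ThetaVector, omega: OmegaMatrix,
                    sigma: ResidualModel) -> dict[str, float]:
    """Flatten the structured truth into the estimation parameter dict."""
    params = {
        "tvCL": theta.tvCL,
        "tvV": theta.tvV,
        "dCLdCCR": theta.dCLdCCR,
        "dCLdBMI": theta.dCLdBMI,
        "dCLdfurosemide": theta.dCLdfurosemide,
        "dVdfurosemide": theta.dVdfurosemide,
        "omega2_CL": omega.omega2CL,
        "omega2_V": omega.omega2V,
    }
    if sigma.stdev0 is not None:
        params["stdev0"] = sigma.stdev0
    if sigma.cv0 is not None:
        params["cv0"] = sigma.cv0
    return params


def _truncated_normal(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_covariates(
    n: int,
    distributions: CovariateDistributions = CovariateDistributions(),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a per-subject covariate table (one row per subject).

    Reproducible for a given seed; BASE is returned in mg/L.
    """
    d = distributions
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ccr = _truncated_normal(rng, d.ccr_mean, d.ccr_sd, lo=d.ccr_min, size=n)
    bmi = d.bmi_median * np.exp(rng.normal(0.0, d.bmi_log_sd, size=n))
    furo = (rng.random(n) < d.furosemide_p).astype(int)
    base_mmol = d.baseline_median_mmol * np.exp(rng.normal(0.0, d.baseline_log_sd, size=n))
    age = _truncated_normal(rng, d.age_mean, d.age_sd, *d.age_range, size=n)
    albumin = _truncated_normal(rng, d.albumin_mean, d.albumin_sd, lo=5.0, size=n)
    calcium = _truncated_normal(rng, d.calcium_mean, d.calcium_sd, lo=0.5, size=n)
    return pd.DataFrame(
        {
            "ID": np.arange(n),
            "CCR": ccr,
            "BMI": bmi,
            "furosemide": furo,
            "age": age,
            "albumin": albumin,
            "calcium": calcium,
            "labetalol": (rng.random(n) < d.labetalol_p).astype(int),
            "nifedipine": (rng.random(n) < d.nifedipine_p).astype(int),
            "ADR": (rng.random(n) < d.adr_p).astype(int),
            "BASE": base_mmol * MG_PER_MMOL,
        }
    )


def generate_study(
    seed: int = 0,
    design: StudyDesign = StudyDesign(),
    distributions: CovariateDistributions = CovariateDistributions(),
    theta: ThetaVector | None = None,
    omega: OmegaMatrix | None = None,
    sigma: ResidualModel | None = None,
) -> tuple[EventDataset, dict]:
    """Simulate one complete study; returns (dataset, truth).

    ``truth`` records the generating parameters and the per-subject etas so
    recovery experiments can score estimates against them.
    """
    if theta is None or omega is None or sigma is None:
        t0, o0, s0 = reference_truth()
        theta = theta or t0
        omega = omega or o0
        sigma = sigma or s0

    rng = np.random.default_rng(seed)
    covs = sample_covariates(design.n_subjects, distributions, rng)

    lo_lo, lo_hi = design.loading_duration_range
    ma_lo, ma_hi = design.maintenance_duration_range
    n = design.n_subjects
    load_dur = rng.uniform(lo_lo, lo_hi, size=n)
    d1_maint_dur = rng.uniform(ma_lo, ma_hi, size=n)
    d2_maint_dur = rng.uniform(ma_lo, ma_hi, size=n)
    eta = rng.multivariate_normal(
        [0.0, 0.0], np.diag([omega.omega2CL, omega.omega2V]), size=n
    )

    offsets = np.asarray(design.sampling_offsets)
    keep = np.ones((n, len(offsets)), dtype=bool)
    if len(offsets) > 1:
        keep[:, 1:] = rng.random((n, len(offsets) - 1)) >= design.sample_dropout

    rows = []
    residual_kind = sigma.kind
    res_params = {"stdev0": sigma.stdev0, "cv0": sigma.cv0}
    for i in range(n):
        cov_row = covs.iloc[i]
        cl_typ = (
            theta.tvCL
            * (cov_row.CCR / theta.ref_CCR) ** theta.dCLdCCR
            * (cov_row.BMI / theta.ref_BMI) ** theta.dCLdBMI
            * (1.0 + theta.dCLdfurosemide * cov_row.furosemide)
        )
        v_typ = theta.tvV * (1.0 + theta.dVdfurosemide * cov_row.furosemide)
        cl_i = cl_typ * np.exp(eta[i, 0])
        v_i = v_typ * np.exp(eta[i, 1])

        starts = np.array([0.0, load_dur[i], design.day2_offset])
        durs = np.array([load_dur[i], d1_maint_dur[i], d2_maint_dur[i]])
        grams = np.array([design.loading_grams, design.maintenance_grams,
                          design.maintenance_grams])
        rates = grams * design.salt_factor / durs

        t_obs = design.day2_offset + offsets[keep[i]]
        above = infusion_superposition(t_obs, starts, durs, rates, cl_i, v_i)
        f = cov_row.BASE + above
        s2 = _residual_variance(residual_kind, res_params, f)
        dv = np.clip(f + rng.normal(0.0, 1.0, size=f.shape) * np.sqrt(s2), 0.0, None)

        common = {c: cov_row[c] for c in covs.columns if c != "ID"}
        for s, g, d in zip(starts, grams, durs):
            rows.append({"ID": i, "TIME": s, "EVID": 1, "AMT": g, "DUR": d,
                         "DV": np.nan, "MDV": 1, **common})
        for t, v in zip(t_obs, dv):
            rows.append({"ID": i, "TIME": t, "EVID": 0, "AMT": np.nan,
                         "DUR": np.nan, "DV": v, "MDV": 0, **common})

    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                        ascending=[True, True, False])
    df = df.reset_index(drop=True)
    dataset = EventDataset(df, salt_factor=design.salt_factor)
    truth = {
        "params": theta_to_params(theta, omega, sigma),
        "theta": theta,
        "omega": omega,
        "sigma": sigma,
        "etas": eta,
        "seed": seed,
    }
    return dataset, truth


def make_null_covariate(
    dataset: EventDataset, name: str, seed: int = 0, new_name: str | None = None
) -> EventDataset:
    """Add a no-effect copy of covariate ``name`` by permuting its
    per-subject values across subjects (marginal distribution preserved
    exactly).  The permuted column is ``<name>_null`` unless overridden."""
    if name not in dataset.df.columns:
        raise KeyError(f"unknown covariate column {name!r}")
    new_name = new_name or f"{name}_null"
    rng = np.random.default_rng(seed)
    ids = list(dataset.subject_ids)
    per_subject = dataset.df.groupby("ID", sort=False)[name].first().reindex(ids)
    permuted = per_subject.to_numpy()[rng.permutation(len(ids))]
    mapping = dict(zip(ids, permuted))
    df = dataset.df.copy()
    df[new_name] = df["ID"].map(mapping)
    return EventDataset(df, salt_factor=dataset.salt_factor)
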