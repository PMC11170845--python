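"""FOCE nonlinear mixed-effects estimation for the magnesium infusion model.

The population model for subject i, observation j is

    y_ij = f(t_ij; CL_i, V_i) + eps_ij
    CL_i = CLtyp_i * exp(etaCL_i),   V_i = Vtyp_i * exp(etaV_i)
    eta_i ~ N(0, diag(omega2_CL, omega2_V)),    eps_ij ~ N(0, sigma2_ij)

with ``f`` the analytic one-compartment infusion model (pk_core) plus the
subject's endogenous baseline, CLtyp/Vtyp given by the covariate model, and
sigma2 additive, proportional or combined.

Estimation follows the first-order conditional (FOCE/Laplace family)
scheme: for each candidate (theta, omega, sigma) an inner damped
Gauss-Newton solve finds every subject's conditional mode eta_i* of the
joint density; the marginal -2 log-likelihood is then approximated by
linearizing f around eta_i*,

    y_i ~ N( f(eta_i*) - G_i eta_i*,  G_i Omega G_i' + Sigma_i )

where G_i = df/deta at the mode.  The objective (OFV) is minimized over
(theta, omega, sigma) with variances log-transformed and proportional
covariate coefficients tanh-bounded so all factors stay positive.  With an
additive residual the interaction term is immaterial and Sigma is constant;
for proportional/combined residuals Sigma is evaluated at the conditional
mode (FOCE with interaction).

The inner solve, predictions and the OFV assembly are vectorized across
subjects (observation grids are padded and masked), which keeps a full fit
of the final covariate model to a 51-subject study in the order of seconds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.optimize import minimize

from .covariate_model import CovariateEffect, ModelValidityError, covariate_term
from .io import EventDataset
from .units import mmol_to_mg

logger = logging.getLogger(__name__)

_BIG = 1e10
_OMEGA_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# model specification & residual error
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidualModel:
    """Residual (within-subject) error model.

    ``additive``      sigma2 = stdev0**2
    ``proportional``  sigma2 = (cv0 * f)**2
    ``combined``      sigma2 = stdev0**2 + (cv0 * f)**2
    """

    kind: str = "additive"
    stdev0: float | None = None
    cv0: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual kind {self.kind!r}")
        if self.kind in ("additive", "combined") and not (self.stdev0 or 0) > 0:
            raise ValueError(f"{self.kind} residual requires stdev0 > 0")
        if self.kind in ("proportional", "combined") and not (self.cv0 or 0) > 0:
            raise ValueError(f"{self.kind} residual requires cv0 > 0")

    @property
    def param_names(self) -> tuple[str, ...]:
        return {
            "additive": ("stdev0",),
            "proportional": ("cv0",),
            "combined": ("stdev0", "cv0"),
        }[self.kind]

    def variance(self, f):
        f = np.asarray(f, dtype=float)
        if self.kind == "additive":
            return np.full_like(f, self.stdev0**2)
        if self.kind == "proportional":
            return (self.cv0 * f) ** 2
        return self.stdev0**2 + (self.cv0 * f) ** 2


def _residual_variance(kind: str, params: Mapping[str, float], f):
    f = np.asarray(f, dtype=float)
    if kind == "additive":
        return np.full_like(f, params["stdev0"] ** 2)
    if kind == "proportional":
        return (params["cv0"] * f) ** 2
    return params["stdev0"] ** 2 + (params["cv0"] * f) ** 2


@dataclass(frozen=True)
class ModelSpec:
    """Structural + covariate + residual model specification.

    ``baseline`` chooses how the endogenous magnesium baseline enters
    predictions: per-subject value from the BASE column ("data"), a single
    global constant ("constant", in mg/L), or no baseline at all ("zero").
    """

    effects: tuple[CovariateEffect, ...] = ()
    residual: str = "additive"
    baseline: str = "data"
    baseline_value: float = mmol_to_mg(0.76)

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))
        if self.baseline not in ("data", "constant", "zero"):
            raise ValueError("baseline must be 'data', 'constant' or 'zero'")
        names = [e.name for e in self.effects]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate covariate effects: {names}")

    def with_effect(self, effect: CovariateEffect) -> "ModelSpec":
        return replace(self, effects=self.effects + (effect,))

    def without_effect(self, effect: CovariateEffect) -> "ModelSpec":
        return replace(self, effects=tuple(e for e in self.effects if e != effect))

    @property
    def residual_param_names(self) -> tuple[str, ...]:
        return {
            "additive": ("stdev0",),
            "proportional": ("cv0",),
            "combined": ("stdev0", "cv0"),
        }[self.residual]

    @property
    def param_names(self) -> tuple[str, ...]:
        return (
            ("tvCL", "tvV")
            + tuple(e.name for e in self.effects)
            + ("omega2_CL", "omega2_V")
            + self.residual_param_names
        )


# ---------------------------------------------------------------------------
# compiled design (padded arrays, vectorized across subjects)
# ---------------------------------------------------------------------------


@dataclass
class Design:
    ids: np.ndarray          # (N,) subject labels
    y: np.ndarray            # (N, J) observed DV, mg/L; padded with 0
    mask: np.ndarray         # (N, J) 1.0 where a real observation exists
    t: np.ndarray            # (N, J) observation times, h
    ev_start: np.ndarray     # (N, E) event start times
    ev_dur: np.ndarray       # (N, E) event durations (1.0 on padding)
    ev_rate: np.ndarray      # (N, E) event rates mg/h (0 on padding)
    baseline: np.ndarray     # (N,)
    cov: dict[str, np.ndarray]  # per-subject covariate vectors

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())


def compile_design(dataset: EventDataset, spec: ModelSpec) -> Design:
    """Pack a validated event dataset into padded per-subject arrays."""
    df = dataset.df
    ids = list(dict.fromkeys(df["ID"]))
    blocks = [df[df["ID"] == sid] for sid in ids]
    obs = [b[(b["EVID"] == 0) & b["DV"].notna()] for b in blocks]
    dos = [b[b["EVID"] == 1] for b in blocks]
    J = max(len(o) for o in obs)
    E = max(max(len(d) for d in dos), 1)
    N = len(ids)

    y = np.zeros((N, J))
    mask = np.zeros((N, J))
    t = np.zeros((N, J))
    ev_start = np.zeros((N, E))
    ev_dur = np.ones((N, E))
    ev_rate = np.zeros((N, E))
    baseline = np.zeros(N)
    for i, (o, d) in enumerate(zip(obs, dos)):
        n = len(o)
        y[i, :n] = o["DV"].to_numpy()
        t[i, :n] = o["TIME"].to_numpy()
        mask[i, :n] = 1.0
        m = len(d)
        if m:
            ev_start[i, :m] = d["TIME"].to_numpy()
            ev_dur[i, :m] = d["DUR"].to_numpy()
            ev_rate[i, :m] = d["AMT"].to_numpy() * dataset.salt_factor / d["DUR"].to_numpy()

    if spec.baseline == "data":
        if "BASE" not in df.columns:
            raise ValueError("baseline='data' requires a BASE column")
        baseline = df.groupby("ID", sort=False)["BASE"].first().reindex(ids).to_numpy(float)
    elif spec.baseline == "constant":
        baseline = np.full(N, spec.baseline_value)

    cov_cols = dataset.covariate_columns
    first = df.groupby("ID", sort=False)[cov_cols].first().reindex(ids) if cov_cols else None
    cov = {c: first[c].to_numpy(dtype=float) for c in cov_cols} if cov_cols else {}
    return Design(
        ids=np.asarray(ids, dtype=object),
        y=y, mask=mask, t=t,
        ev_start=ev_start, ev_dur=ev_dur, ev_rate=ev_rate,
        baseline=baseline, cov=cov,
    )


def _typical_params(design: Design, spec: ModelSpec, params: Mapping[str, float]):
    """Per-subject typical CL and V from the covariate model (vectorized)."""
    cl = np.full(design.n_subjects, params["tvCL"])
    v = np.full(design.n_subjects, params["tvV"])
    for e in spec.effects:
        if e.covariate not in design.cov:
            raise KeyError(f"covariate column {e.covariate!r} not in dataset")
        factor = covariate_term(e.form, design.cov[e.covariate], params[e.name], e.reference)
        if e.parameter == "CL":
            cl = cl * factor
        else:
            v = v * factor
    return cl, v


def _predict(design: Design, CL, V, grad: bool = False):
    """Model predictions f (N, J) and optionally G = df/deta (N, J, 2).

    Uses the closed-form infusion superposition; the eta-gradient follows
    from d f/d etaCL = -C + k*S and d f/d etaV = -k*S where C is the
    above-baseline prediction and S = sum over events of dc/dk.
    """
    k = (CL / V)[:, None, None]
    dt = design.t[:, :, None] - design.ev_start[:, None, :]
    tau1 = np.clip(dt, 0.0, design.ev_dur[:, None, :])
    tau2 = np.clip(dt - design.ev_dur[:, None, :], 0.0, None)
    em1 = np.exp(-k * tau1)
    e1 = 1.0 - em1
    e2 = np.exp(-k * tau2)
    pref = design.ev_rate[:, None, :] / CL[:, None, None]
    c_ev = pref * e1 * e2
    C = c_ev.sum(axis=2)
    f = design.baseline[:, None] + C
    if not grad:
        return f
    dcdk = pref * e2 * (tau1 * em1 - tau2 * e1)
    S = dcdk.sum(axis=2)
    kk = (CL / V)[:, None]
    G = np.stack([-C + kk * S, -kk * S], axis=-1)
    return f, G


# ---------------------------------------------------------------------------
# joint density and inner (eta) optimization
# ---------------------------------------------------------------------------


def individual_joint_neg2ll(y, f, eta, omega2, sigma2) -> float:
    """-2 log of the joint density p(y | eta) p(eta) for one subject.

    ``f`` and ``sigma2`` are the predictions and residual variances at this
    eta; ``omega2`` the diagonal of Omega.  Includes all 2*pi constants, so
    it matches the literal normal densities term by term.
    """
    y = np.asarray(y, float)
    f = np.asarray(f, float)
    eta = np.asarray(eta, float)
    omega2 = np.asarray(omega2, float)
    sigma2 = np.broadcast_to(np.asarray(sigma2, float), y.shape)
    if np.any(omega2 <= 0) and np.any(eta != 0):
        return np.inf
    obs_term = np.sum(np.log(2 * np.pi * sigma2) + (y - f) ** 2 / sigma2)
    om = np.maximum(omega2, _OMEGA_FLOOR)
    eta_term = np.sum(np.log(2 * np.pi * om) + eta**2 / om)
    return float(obs_term + eta_term)


def _inner_objective(design, CLtyp, Vtyp, winv, spec, params, eta):
    CL = CLtyp * np.exp(eta[:, 0])
    V = Vtyp * np.exp(eta[:, 1])
    f = _predict(design, CL, V)
    s2 = _residual_variance(spec.residual, params, f)
    s2 = np.maximum(s2, 1e-12)
    r = design.y - f
    terms = design.mask * (np.log(s2) + r * r / s2)
    return terms.sum(axis=1) + (eta**2 * winv).sum(axis=1)


def _solve_etas(design, CLtyp, Vtyp, omega2, spec, params,
                tol: float = 1e-8, max_iter: int = 100, eta0=None):
    """Vectorized damped Gauss-Newton search for every subject's conditional
    mode.  Exact gradient of the joint -2LL (including the d sigma2/d eta
    term for proportional/combined residuals); Gauss-Newton Hessian, which
    is SPD, with per-subject backtracking.  ``eta0`` warm-starts the search
    (the mode moves little between outer-optimizer steps)."""
    N = design.n_subjects
    winv = 1.0 / np.maximum(np.asarray(omega2, float), _OMEGA_FLOOR)
    eta = np.zeros((N, 2)) if eta0 is None else np.array(eta0, float)
    gval = _inner_objective(design, CLtyp, Vtyp, winv, spec, params, eta)
    cv0 = params.get("cv0", 0.0) if spec.residual in ("proportional", "combined") else 0.0

    for _ in range(max_iter):
        CL = CLtyp * np.exp(eta[:, 0])
        V = Vtyp * np.exp(eta[:, 1])
        f, G = _predict(design, CL, V, grad=True)
        s2 = np.maximum(_residual_variance(spec.residual, params, f), 1e-12)
        r = design.y - f
        m = design.mask
        w = m / s2
        grad = -2.0 * np.einsum("nj,njk->nk", w * r, G) + 2.0 * winv * eta
        if cv0:
            ds2 = 2.0 * cv0**2 * f[:, :, None] * G
            grad += np.einsum("nj,njk->nk", m * (1.0 / s2 - r**2 / s2**2), ds2)
        H = 2.0 * np.einsum("njk,njl->nkl", w[:, :, None] * G, G)
        H[:, 0, 0] += 2.0 * winv[0]
        H[:, 1, 1] += 2.0 * winv[1]
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] * H[:, 1, 0]
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        step = np.empty_like(eta)
        step[:, 0] = -(H[:, 1, 1] * grad[:, 0] - H[:, 0, 1] * grad[:, 1]) / det
        step[:, 1] = -(H[:, 0, 0] * grad[:, 1] - H[:, 1, 0] * grad[:, 0]) / det

        alpha = np.ones(N)
        accepted = np.zeros(N, dtype=bool)
        eta_new = eta.copy()
        g_new = gval.copy()
        for _bt in range(25):
            trial = eta + (alpha * ~accepted)[:, None] * step
            trial[accepted] = eta_new[accepted]
            g_trial = _inner_objective(design, CLtyp, Vtyp, winv, spec, params, trial)
            improved = ~accepted & (g_trial <= gval + 1e-13) & np.isfinite(g_trial)
            eta_new[improved] = trial[improved]
            g_new[improved] = g_trial[improved]
            accepted |= improved
            if accepted.all():
                break
            alpha[~accepted] *= 0.5
        step_size = np.abs(eta_new - eta).max()
        eta, gval = eta_new, g_new
        if step_size < tol:
            break
    return eta


def _foce_ofv(design: Design, spec: ModelSpec, params: Mapping[str, float],
              etas: np.ndarray, interaction: bool):
    """FOCE-linearized marginal -2 log-likelihood at the conditional modes."""
    CLtyp, Vtyp = _typical_params(design, spec, params)
    CL = CLtyp * np.exp(etas[:, 0])
    V = Vtyp * np.exp(etas[:, 1])
    f, G = _predict(design, CL, V, grad=True)
    if interaction or spec.residual == "additive":
        s2 = _residual_variance(spec.residual, params, f)
    else:
        f0 = _predict(design, CLtyp, Vtyp)
        s2 = _residual_variance(spec.residual, params, f0)
    m = design.mask
    omega2 = np.array([params["omega2_CL"], params["omega2_V"]], float)
    Gm = G * m[:, :, None]
    r = (design.y - f + np.einsum("njk,nk->nj", G, etas)) * m
    s2m = np.where(m > 0, np.maximum(s2, 1e-12), 1.0)
    Vmat = np.einsum("njk,k,nlk->njl", Gm, omega2, Gm)
    J = Vmat.shape[1]
    Vmat[:, np.arange(J), np.arange(J)] += s2m
    sign, logdet = np.linalg.slogdet(Vmat)
    if np.any(sign <= 0):
        return np.inf
    sol = np.linalg.solve(Vmat, r[:, :, None])[:, :, 0]
    quad = (r * sol).sum(axis=1)
    return float(logdet.sum() + quad.sum() + design.n_obs * np.log(2 * np.pi))


def evaluate_ofv(dataset_or_design, spec: ModelSpec, params: Mapping[str, float],
                 interaction: bool | None = None):
    """OFV (and the conditional modes) at fixed parameter values.

    Useful for likelihood-surface checks and as the hook the quadrature
    oracle in the test-suite compares against.
    """
    design = (dataset_or_design if isinstance(dataset_or_design, Design)
              else compile_design(dataset_or_design, spec))
    if interaction is None:
        interaction = spec.residual != "additive"
    CLtyp, Vtyp = _typical_params(design, spec, params)
    omega2 = np.array([params["omega2_CL"], params["omega2_V"]], float)
    etas = _solve_etas(design, CLtyp, Vtyp, omega2, spec, params)
    return _foce_ofv(design, spec, params, etas, interaction), etas


# ---------------------------------------------------------------------------
# outer optimization
# ---------------------------------------------------------------------------


class _ParamTransform:
    """Bijection between the natural parameter dict and the unconstrained
    vector the optimizer works in: log for typical values / variances /
    residual SDs, atanh for proportional coefficients (keeps |coef| < 1),
    identity for power exponents."""

    def __init__(self, spec: ModelSpec, fix: Mapping[str, float] | None = None):
        self.spec = spec
        self.fix = dict(fix or {})
        kinds: dict[str, str] = {"tvCL": "log", "tvV": "log",
                                 "omega2_CL": "log", "omega2_V": "log"}
        for e in spec.effects:
            kinds[e.name] = "raw" if e.form == "power" else "tanh"
        for name in spec.residual_param_names:
            kinds[name] = "log"
        self.kinds = kinds
        unknown = set(self.fix) - set(spec.param_names)
        if unknown:
            raise ValueError(f"cannot fix unknown parameters: {sorted(unknown)}")
        self.free = [n for n in spec.param_names if n not in self.fix]

    def encode(self, params: Mapping[str, float]) -> np.ndarray:
        x = np.empty(len(self.free))
        for i, name in enumerate(self.free):
            v = params[name]
            kind = self.kinds[name]
            if kind == "log":
                x[i] = np.log(max(v, 1e-8))
            elif kind == "tanh":
                x[i] = np.arctanh(np.clip(v, -0.995, 0.995))
            else:
                x[i] = v
        return x

    def decode(self, x: np.ndarray) -> dict[str, float]:
        params = dict(self.fix)
        for i, name in enumerate(self.free):
            kind = self.kinds[name]
            if kind == "log":
                params[name] = float(np.exp(x[i]))
            elif kind == "tanh":
                params[name] = float(np.tanh(x[i]))
            else:
                params[name] = float(x[i])
        return params


DEFAULT_INITS = {
    "tvCL": 4.0,
    "tvV": 20.0,
    "omega2_CL": 0.1,
    "omega2_V": 0.1,
    "stdev0": 3.0,
    "cv0": 0.2,
}


@dataclass
class FitResult:
    """Converged (or flagged) population fit."""

    params: dict[str, float]
    ofv: float
    aic: float
    bic: float
    etas: "np.ndarray"
    subject_ids: np.ndarray
    shrinkage: dict[str, float]
    spec: ModelSpec
    n_obs: int
    n_params: int
    converged: bool
    n_fev: int = 0
    message: str = ""
    se: dict[str, float] | None = None
    cv_pct: dict[str, float] | None = None

    @property
    def omega2(self) -> dict[str, float]:
        return {k: self.params[k] for k in ("omega2_CL", "omega2_V")}

    def eta_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"ID": self.subject_ids, "etaCL": self.etas[:, 0], "etaV": self.etas[:, 1]}
        )

    def parameter_table(self):
        import pandas as pd

        rows = []
        for name in self.spec.param_names:
            est = self.params[name]
            se = (self.se or {}).get(name, np.nan)
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "se": se,
                    "cv_pct": 100 * se / abs(est) if est and np.isfinite(se) else np.nan,
                    "shrinkage_pct": self.shrinkage.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "ofv": self.ofv,
            "aic": self.aic,
            "bic": self.bic,
            "shrinkage": self.shrinkage,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "se": self.se,
        }


def information_criteria(ofv: float, p: int, n: int) -> tuple[float, float]:
    """AIC = OFV + 2p; BIC = OFV + p ln(n)."""
    if p < 0 or n < 1:
        raise ValueError("need p >= 0 and n >= 1")
    return ofv + 2 * p, ofv + p * np.log(n)


def eta_shrinkage(etas: np.ndarray, omega2) -> dict[str, float]:
    """Per-effect shrinkage 100*(1 - SD(EBE)/omega), clipped to [0, 100]."""
    etas = np.asarray(etas, float)
    if etas.shape[0] < 2:
        raise ValueError("shrinkage requires >= 2 subjects")
    if isinstance(omega2, Mapping):
        om = np.array([omega2["omega2_CL"], omega2["omega2_V"]], float)
    else:
        om = np.asarray(omega2, float)
    out = {}
    for i, name in enumerate(("etaCL", "etaV")):
        if om[i] <= 0:
            warnings.warn(f"shrinkage undefined for {name}: omega2 = 0")
            out[name] = np.nan
            continue
        val = 100.0 * (1.0 - etas[:, i].std(ddof=1) / np.sqrt(om[i]))
        if val < 0:
            warnings.warn(f"negative shrinkage for {name} clipped to 0")
        out[name] = float(np.clip(val, 0.0, 100.0))
    return out


def foce_fit(
    dataset: EventDataset,
    spec: ModelSpec = ModelSpec(),
    inits: Mapping[str, float] | None = None,
    fix: Mapping[str, float] | None = None,
    options: Mapping | None = None,
    compute_se: bool = False,
) -> FitResult:
    """Fit the population model by FOCE.  Deterministic given inits/options.

    Non-convergence is flagged on the result, never raised.  ``fix`` pins
    named parameters (e.g. ``{"omega2_CL": 0.0, "omega2_V": 0.0}`` turns the
    fit into plain least squares with no random effects).
    """
    opts = {"maxfev": 4000, "xatol": 1e-4, "fatol": 1e-6, "restarts": 0}
    opts.update(options or {})
    design = compile_design(dataset, spec)
    if design.n_subjects < 1:
        raise ValueError("dataset has no subjects")

    # Internally re-center power covariates on their sample median: an exact
    # reparameterization (tvCL/tvV absorb the reference change) that removes
    # the near-collinearity between typical values and exponents when the
    # requested reference sits far outside the covariate range.
    power_effects = [e for e in spec.effects if e.form == "power"]
    recenter = bool(power_effects) and not ({"tvCL", "tvV"} & set(fix or {}))
    if recenter:
        int_spec = replace(
            spec,
            effects=tuple(
                replace(e, reference=float(np.median(design.cov[e.covariate])))
                if e.form == "power" else e
                for e in spec.effects
            ),
        )
    else:
        int_spec = spec

    def _ref_ratio(params, param_name):
        # prod over power effects on this parameter of (median_ref / ref)^coef
        ratio = 1.0
        for e_int, e_rep in zip(int_spec.effects, spec.effects):
            if e_int.form == "power" and e_int.parameter == param_name:
                ratio *= (e_int.reference / e_rep.reference) ** params[e_int.name]
        return ratio

    def to_internal(params):
        out = dict(params)
        out["tvCL"] = params["tvCL"] * _ref_ratio(params, "CL")
        out["tvV"] = params["tvV"] * _ref_ratio(params, "V")
        return out

    def to_reported(params):
        out = dict(params)
        out["tvCL"] = params["tvCL"] / _ref_ratio(params, "CL")
        out["tvV"] = params["tvV"] / _ref_ratio(params, "V")
        return out

    pt = _ParamTransform(int_spec, fix)
    init_params = dict(DEFAULT_INITS)
    for e in spec.effects:
        init_params.setdefault(e.name, 0.0)
    init_params.update(inits or {})
    missing = [n for n in pt.free if n not in init_params]
    if missing:
        raise ValueError(f"no initial value for {missing}")
    for name in pt.free:
        kind = pt.kinds[name]
        if kind == "log" and not init_params[name] > 0:
            raise ValueError(f"initial {name} must be > 0, got {init_params[name]}")
        if kind == "tanh" and not abs(init_params[name]) < 1:
            raise ValueError(f"initial |{name}| must be < 1, got {init_params[name]}")
    if recenter:
        init_params = to_internal(init_params)

    interaction = spec.residual != "additive"

    state = {"etas": None}

    def fun(x):
        params = pt.decode(x)
        try:
            ofv, etas = _evaluate(design, int_spec, params, interaction,
                                  eta0=state["etas"])
        except (ModelValidityError, FloatingPointError):
            return _BIG
        if not np.isfinite(ofv):
            return _BIG
        state["etas"] = etas
        return ofv

    def _evaluate(design, spec, params, interaction, eta0=None):
        CLtyp, Vtyp = _typical_params(design, spec, params)
        omega2 = np.array([params["omega2_CL"], params["omega2_V"]], float)
        etas = _solve_etas(design, CLtyp, Vtyp, omega2, spec, params, eta0=eta0)
        return _foce_ofv(design, spec, params, etas, interaction), etas

    x0 = pt.encode(init_params)
    f0 = fun(x0)
    if not np.isfinite(f0) or f0 >= _BIG:
        raise ValueError("objective is not finite at the initial values")

    # quasi-Newton descent first (cheap, handles the long ridge between
    # correlated parameters), then a simplex polish which is robust to the
    # small kinks the inner solve leaves on the surface
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(fun, x0, method="L-BFGS-B",
                       options={"maxiter": 300, "ftol": 1e-10, "gtol": 1e-7})
        nfev = res.nfev
        for _ in range(1 + int(opts["restarts"])):
            res2 = minimize(fun, res.x, method="Nelder-Mead",
                            options={"maxfev": opts["maxfev"], "xatol": opts["xatol"],
                                     "fatol": opts["fatol"], "adaptive": True})
            nfev += res2.nfev
            improved = res2.fun < res.fun - 1e-9
            res = res2
            if not improved:
                break

    params_int = pt.decode(res.x)
    # optimizer contract: never return a point worse than the inits
    if res.fun > f0 + 1e-9:
        params_int = pt.decode(x0)
    params = to_reported(params_int) if recenter else params_int
    ofv, etas = _evaluate(design, spec, params, interaction)
    p = len(pt.free)
    aic, bic = information_criteria(ofv, p, design.n_obs)
    shr_eta = eta_shrinkage(etas, [params["omega2_CL"], params["omega2_V"]]) \
        if design.n_subjects >= 2 else {"etaCL": np.nan, "etaV": np.nan}
    shrinkage = {"omega2_CL": shr_eta["etaCL"], "omega2_V": shr_eta["etaV"]}

    fit = FitResult(
        params=params, ofv=ofv, aic=aic, bic=bic,
        etas=etas, subject_ids=design.ids,
        shrinkage=shrinkage, spec=spec,
        n_obs=design.n_obs, n_params=p,
        converged=bool(res.success and np.isfinite(ofv)),
        n_fev=nfev, message=str(res.message),
    )
    if compute_se:
        se, cv = standard_errors(fit, dataset, _design=design)
        fit.se, fit.cv_pct = se, cv
    return fit


def standard_errors(fit: FitResult, dataset: EventDataset | None = None,
                    _design: Design | None = None,
                    rel_step: float = 1e-3) -> tuple[dict, dict]:
    """Asymptotic standard errors from the numerical Hessian of OFV/2.

    Central finite differences on the natural parameter scale; a
    non-invertible (or non-PD) Hessian yields NaN entries with a warning.
    Returns (se, cv_pct) keyed by parameter name.
    """
    spec = fit.spec
    design = _design if _design is not None else compile_design(dataset, spec)
    interaction = spec.residual != "additive"
    free = list(spec.param_names)
    fixed_at = dict(fit.params)
    x_hat = np.array([fit.params[n] for n in free], float)

    def half_ofv(x):
        params = dict(fixed_at)
        params.update({n: float(v) for n, v in zip(free, x)})
        if params["tvCL"] <= 0 or params["tvV"] <= 0:
            return _BIG
        if params["omega2_CL"] < 0 or params["omega2_V"] < 0:
            return _BIG
        try:
            ofv, _ = evaluate_ofv(design, spec, params, interaction)
        except (ModelValidityError, FloatingPointError):
            return _BIG
        return 0.5 * ofv if np.isfinite(ofv) else _BIG

    p = len(free)
    h = rel_step * np.maximum(np.abs(x_hat), 1e-2)
    H = np.empty((p, p))
    f0 = half_ofv(x_hat)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        fp = half_ofv(x_hat + ei)
        fm = half_ofv(x_hat - ei)
        H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            fpp = half_ofv(x_hat + ei + ej)
            fpm = half_ofv(x_hat + ei - ej)
            fmp = half_ofv(x_hat - ei + ej)
            fmm = half_ofv(x_hat - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])

    se = {n: np.nan for n in free}
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.any(d <= 0):
            warnings.warn("Hessian not positive definite; some SEs missing")
        for n, v in zip(free, d):
            se[n] = float(np.sqrt(v)) if v > 0 else np.nan
    except np.linalg.LinAlgError:
        warnings.warn("Hessian not invertible; SEs missing")
    cv = {
        n: (100.0 * se[n] / abs(fit.params[n])
            if np.isfinite(se[n]) and fit.params[n] != 0 else np.nan)
        for n in free
    }
    return se, cv
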