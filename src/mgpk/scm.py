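"""Stepwise covariate modeling (SCM): forward inclusion, backward elimination.

Candidate covariate-parameter attachments are tested one at a time by the
likelihood-ratio criterion on the FOCE objective.  The forward phase adds,
at each step, the candidate with the largest drop in OFV provided the drop
is at least the chi-square(1) quantile at alpha = 0.01 (6.63); it stops when
no candidate qualifies.  The backward phase then removes effects one at a
time, starting with the least supported, keeping an effect only if its
removal raises the OFV by at least the chi-square(1) quantile at
alpha = 0.001 (10.83).

Every decision is logged to an :class:`SCMTrace` whose rows contain both
OFVs and the threshold, so the selection path can be audited or replayed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd
from scipy.stats import chi2

from .covariate_model import CovariateEffect
from .estimation import FitResult, ModelSpec, foce_fit
from .io import EventDataset

logger = logging.getLogger(__name__)

#: absolute slack for threshold comparisons so that a ΔOFV exactly at the
#: critical value counts as qualifying despite floating-point round-off
_EPS = 1e-9


def lrt_threshold(alpha: float, df: int = 1) -> float:
    """Critical ΔOFV: upper-``alpha`` quantile of chi-square with ``df``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.ppf(1.0 - alpha, df))


@dataclass(frozen=True)
class SCMStep:
    phase: str                  # "forward" | "backward"
    step: int
    candidate: str
    ofv_reference: float
    ofv_alternative: float
    delta_ofv: float            # forward: drop on inclusion; backward: rise on removal
    threshold: float
    decision: str               # "accepted" | "rejected" | "removed" | "retained" | "skipped"


@dataclass
class SCMTrace:
    steps: list[SCMStep]
    final_spec: ModelSpec
    final_fit: FitResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _default_fit(dataset, spec, inits=None):
    return foce_fit(dataset, spec, inits=inits)


def _warm_inits(fit: FitResult, new_effect: CovariateEffect | None = None):
    inits = dict(fit.params)
    if new_effect is not None:
        inits[new_effect.name] = 0.0
    return inits


def forward_step(
    dataset: EventDataset,
    current_spec: ModelSpec,
    current_fit: FitResult,
    candidates: Sequence[CovariateEffect],
    threshold: float | None = None,
    fit_fn: Callable = _default_fit,
    step_index: int = 0,
):
    """One forward-inclusion step.

    Fits ``current + candidate`` for every remaining candidate and accepts
    the one with the largest OFV drop if it reaches the threshold
    (inclusive).  Ties break lexicographically on candidate name.  Returns
    ``(accepted_effect_or_None, accepted_fit_or_None, trace_rows)``.
    """
    threshold = lrt_threshold(0.01, 1) if threshold is None else threshold
    results = []
    rows = []
    for cand in sorted(candidates, key=lambda c: c.name):
        spec_new = current_spec.with_effect(cand)
        try:
            fit_new = fit_fn(dataset, spec_new, inits=_warm_inits(current_fit, cand))
        except Exception as exc:  # candidate fit failed outright
            logger.warning("forward candidate %s failed: %s", cand.name, exc)
            rows.append(SCMStep("forward", step_index, cand.name, current_fit.ofv,
                                float("nan"), float("nan"), threshold, "skipped"))
            continue
        if not fit_new.converged:
            logger.warning("forward candidate %s did not converge; skipped", cand.name)
            rows.append(SCMStep("forward", step_index, cand.name, current_fit.ofv,
                                fit_new.ofv, float("nan"), threshold, "skipped"))
            continue
        delta = current_fit.ofv - fit_new.ofv
        results.append((cand, fit_new, delta))

    best = None
    if results:
        results.sort(key=lambda r: (-r[2], r[0].name))
        cand, fit_new, delta = results[0]
        if delta >= threshold - _EPS:
            best = (cand, fit_new)
    for cand, fit_new, delta in results:
        decision = "accepted" if best is not None and cand == best[0] else "rejected"
        rows.append(SCMStep("forward", step_index, cand.name, current_fit.ofv,
                            fit_new.ofv, delta, threshold, decision))
    if best is None:
        return None, None, rows
    return best[0], best[1], rows


def backward_step(
    dataset: EventDataset,
    spec: ModelSpec,
    fit: FitResult,
    threshold: float | None = None,
    fit_fn: Callable = _default_fit,
    removable: Sequence[CovariateEffect] | None = None,
    step_index: int = 0,
):
    """One backward-elimination step over ``removable`` effects (default:
    all effects in the model).  Refits with each effect removed; the effect
    whose removal raises OFV least is eliminated if that rise is below the
    threshold.  Returns ``(removed_effect_or_None, new_fit_or_None, rows)``."""
    threshold = lrt_threshold(0.001, 1) if threshold is None else threshold
    removable = spec.effects if removable is None else removable
    results = []
    rows = []
    for eff in sorted(removable, key=lambda e: e.name):
        spec_red = spec.without_effect(eff)
        reduced_inits = {k: v for k, v in fit.params.items() if k != eff.name}
        try:
            fit_red = fit_fn(dataset, spec_red, inits=reduced_inits)
        except Exception as exc:
            logger.warning("backward removal of %s failed: %s", eff.name, exc)
            rows.append(SCMStep("backward", step_index, eff.name, fit.ofv,
                                float("nan"), float("nan"), threshold, "skipped"))
            continue
        if not fit_red.converged:
            rows.append(SCMStep("backward", step_index, eff.name, fit.ofv,
                                fit_red.ofv, float("nan"), threshold, "skipped"))
            continue
        delta = fit_red.ofv - fit.ofv
        results.append((eff, fit_red, delta))

    removed = None
    if results:
        results.sort(key=lambda r: (r[2], r[0].name))
        eff, fit_red, delta = results[0]
        if delta < threshold - _EPS:
            removed = (eff, fit_red)
    for eff, fit_red, delta in results:
        if removed is not None and eff == removed[0]:
            decision = "removed"
        else:
            decision = "retained"
        rows.append(SCMStep("backward", step_index, eff.name, fit.ofv,
                            fit_red.ofv, delta, threshold, decision))
    if removed is None:
        return None, None, rows
    return removed[0], removed[1], rows


def run_scm(
    dataset: EventDataset,
    base_spec: ModelSpec = ModelSpec(),
    candidates: Sequence[CovariateEffect] = (),
    forward_alpha: float = 0.01,
    backward_alpha: float = 0.001,
    fit_fn: Callable = _default_fit,
    base_fit: FitResult | None = None,
) -> SCMTrace:
    """Full stepwise search: forward until no acceptance, then backward.

    Deterministic given the dataset, candidate list and fit settings.
    """
    fwd_thr = lrt_threshold(forward_alpha, 1)
    bwd_thr = lrt_threshold(backward_alpha, 1)
    steps: list[SCMStep] = []

    spec = base_spec
    fit = base_fit if base_fit is not None else fit_fn(dataset, spec, inits=None)
    remaining = list(candidates)
    step_idx = 0
    while remaining:
        accepted, fit_new, rows = forward_step(
            dataset, spec, fit, remaining, fwd_thr, fit_fn, step_idx
        )
        steps.extend(rows)
        if accepted is None:
            break
        spec = spec.with_effect(accepted)
        fit = fit_new
        remaining = [c for c in remaining if c != accepted]
        step_idx += 1

    added = [e for e in spec.effects if e not in base_spec.effects]
    while added:
        removed, fit_new, rows = backward_step(
            dataset, spec, fit, bwd_thr, fit_fn, removable=added, step_index=step_idx
        )
        steps.extend(rows)
        if removed is None:
            break
        spec = spec.without_effect(removed)
        fit = fit_new
        added = [e for e in added if e != removed]
        step_idx += 1

    return SCMTrace(steps=steps, final_spec=spec, final_fit=fit)


def default_candidates(
    continuous_refs: dict[str, float] | None = None,
    continuous: Sequence[str] = ("CCR", "BMI", "age", "albumin", "calcium"),
    categorical: Sequence[str] = ("furosemide", "labetalol", "nifedipine", "ADR"),
    parameters: Sequence[str] = ("CL", "V"),
) -> list[CovariateEffect]:
    """Candidate grid: each covariate on each parameter, power form for
    continuous covariates (normalized by the supplied reference, e.g. the
    dataset median) and proportional form for categorical ones."""
    refs = continuous_refs or {}
    out = []
    for p in parameters:
        for c in continuous:
            out.append(CovariateEffect(p, c, "power", refs.get(c, 1.0)))
        for c in categorical:
            out.append(CovariateEffect(p, c, "proportional"))
    return out
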