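"""Stepwise covariate modeling: thresholds, step semantics (with stubbed
fits), trace reproducibility.  Operating-characteristic simulations live in
the acceptance suite."""

import numpy as np
import pytest
from scipy.stats import chi2

from mgpk import CovariateEffect, ModelSpec, lrt_threshold
from mgpk.estimation import FitResult
from mgpk.scm import backward_step, forward_step, run_scm


def make_fit(spec, ofv):
    """Minimal FitResult stub carrying just what SCM reads."""
    return FitResult(
        params={n: 0.1 for n in spec.param_names}, ofv=ofv,
        aic=np.nan, bic=np.nan, etas=np.zeros((2, 2)),
        subject_ids=np.array([0, 1]), shrinkage={}, spec=spec,
        n_obs=4, n_params=len(spec.param_names), converged=True,
    )


class StubFitter:
    """Deterministic OFV lookup keyed by the set of effect names."""

    def __init__(self, ofv_by_model):
        self.ofv_by_model = ofv_by_model
        self.calls = []

    def __call__(self, dataset, spec, inits=None):
        key = frozenset(e.name for e in spec.effects)
        self.calls.append(key)
        return make_fit(spec, self.ofv_by_model[key])


CAND_A = CovariateEffect("CL", "CCR", "power", 180.0)
CAND_B = CovariateEffect("CL", "furosemide", "proportional")
CAND_C = CovariateEffect("V", "furosemide", "proportional")


class TestThresholds:
    def test_published_thresholds_to_2dp(self):
        assert lrt_threshold(0.01, 1) == pytest.approx(6.63, abs=0.005)
        assert lrt_threshold(0.001, 1) == pytest.approx(10.83, abs=0.005)
        assert lrt_threshold(0.05, 1) == pytest.approx(3.84, abs=0.005)

    def test_equals_chi2_quantile(self):
        for alpha in (0.05, 0.01, 0.001):
            for df in (1, 2, 3):
                assert lrt_threshold(alpha, df) == chi2.ppf(1 - alpha, df)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lrt_threshold(0.0, 1)
        with pytest.raises(ValueError):
            lrt_threshold(0.01, 0)


class TestForwardStep:
    def test_accepts_largest_qualifying_drop(self):
        base = ModelSpec()
        fits = StubFitter({
            frozenset(): 1000.0,
            frozenset({"dCLdCCR"}): 990.0,          # drop 10
            frozenset({"dCLdfurosemide"}): 992.0,   # drop 8
        })
        fit0 = make_fit(base, 1000.0)
        acc, fit_new, rows = forward_step(None, base, fit0, [CAND_A, CAND_B],
                                          fit_fn=fits)
        assert acc == CAND_A
        assert fit_new.ofv == 990.0
        decisions = {r.candidate: r.decision for r in rows}
        assert decisions == {"dCLdCCR": "accepted", "dCLdfurosemide": "rejected"}

    def test_no_candidate_reaches_threshold(self):
        base = ModelSpec()
        fits = StubFitter({frozenset(): 1000.0, frozenset({"dCLdCCR"}): 995.0})
        acc, _, rows = forward_step(None, base, make_fit(base, 1000.0), [CAND_A],
                                    fit_fn=fits)
        assert acc is None
        assert rows[0].decision == "rejected"

    def test_threshold_boundary_is_inclusive(self):
        base = ModelSpec()
        fits = StubFitter({frozenset(): 1000.0, frozenset({"dCLdCCR"}): 1000.0 - 6.63})
        acc, _, _ = forward_step(None, base, make_fit(base, 1000.0), [CAND_A],
                                 threshold=6.63, fit_fn=fits)
        assert acc == CAND_A

    def test_tie_broken_lexicographically(self):
        base = ModelSpec()
        fits = StubFitter({
            frozenset(): 1000.0,
            frozenset({"dCLdCCR"}): 990.0,
            frozenset({"dCLdfurosemide"}): 990.0,
        })
        acc, _, _ = forward_step(None, base, make_fit(base, 1000.0),
                                 [CAND_B, CAND_A], fit_fn=fits)
        assert acc.name == "dCLdCCR"  # dCLdCCR < dCLdfurosemide


class TestBackwardStep:
    def test_removal_semantics(self):
        spec = ModelSpec(effects=(CAND_A, CAND_B))
        fits = StubFitter({
            frozenset({"dCLdfurosemide"}): 1005.0,  # removing A raises by 5 -> out
            frozenset({"dCLdCCR"}): 1012.0,         # removing B raises by 12 -> kept
        })
        removed, fit_new, rows = backward_step(None, spec, make_fit(spec, 1000.0),
                                               fit_fn=fits)
        assert removed == CAND_A
        assert fit_new.ofv == 1005.0
        decisions = {r.candidate: r.decision for r in rows}
        assert decisions == {"dCLdCCR": "removed", "dCLdfurosemide": "retained"}

    def test_all_effects_survive(self):
        spec = ModelSpec(effects=(CAND_A,))
        fits = StubFitter({frozenset(): 1012.0})
        removed, _, rows = backward_step(None, spec, make_fit(spec, 1000.0),
                                         fit_fn=fits)
        assert removed is None
        assert rows[0].decision == "retained"


class TestRunScm:
    def test_empty_candidate_list_returns_base(self):
        base = ModelSpec()
        fits = StubFitter({frozenset(): 1000.0})
        trace = run_scm(None, base, [], fit_fn=fits)
        assert trace.final_spec == base
        assert trace.steps == []

    def test_forward_then_backward_composition(self):
        base = ModelSpec()
        fits = StubFitter({
            frozenset(): 1000.0,
            frozenset({"dCLdCCR"}): 980.0,
            frozenset({"dCLdfurosemide"}): 992.0,
            frozenset({"dVdfurosemide"}): 999.0,
            frozenset({"dCLdCCR", "dCLdfurosemide"}): 972.0,
            frozenset({"dCLdCCR", "dVdfurosemide"}): 979.0,
            frozenset({"dCLdCCR", "dCLdfurosemide", "dVdfurosemide"}): 971.5,
        })
        trace = run_scm(None, base, [CAND_A, CAND_B, CAND_C], fit_fn=fits)
        # forward: CCR (drop 20), then furo on CL (drop 8 >= 6.63), then
        # furo on V (drop 0.5, rejected).  backward: removing furo-on-CL
        # raises by 8 < 10.83 -> eliminated; removing CCR raises 25 -> kept.
        assert {e.name for e in trace.final_spec.effects} == {"dCLdCCR"}
        assert trace.final_fit.ofv == 980.0

    def test_trace_decisions_reproducible_from_logged_values(self):
        base = ModelSpec()
        fits = StubFitter({
            frozenset(): 1000.0,
            frozenset({"dCLdCCR"}): 980.0,
            frozenset({"dCLdfurosemide"}): 992.0,
            frozenset({"dCLdCCR", "dCLdfurosemide"}): 972.0,
        })
        trace = run_scm(None, base, [CAND_A, CAND_B], fit_fn=fits)
        for row in trace.to_frame().itertuples():
            if row.decision in ("accepted", "rejected"):
                qualifies = row.delta_ofv >= row.threshold
                if row.decision == "accepted":
                    assert qualifies
            elif row.decision == "removed":
                assert row.delta_ofv < row.threshold
            elif row.decision == "retained":
                pass  # retained rows may still be below threshold if another
                      # effect was removed first
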