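"""FOCE estimation: joint-density algebra, information criteria, shrinkage,
least-squares and quadrature oracles, rich-data parameter recovery, SEs."""

import numpy as np
import pytest
from scipy import stats

from mgpk import (
    ModelSpec,
    ResidualModel,
    eta_shrinkage,
    evaluate_ofv,
    foce_fit,
    generate_study,
    information_criteria,
    reference_model_spec,
    standard_errors,
)
from mgpk.covariate_model import OmegaMatrix, ThetaVector
from mgpk.estimation import compile_design, individual_joint_neg2ll
from mgpk.synthetic_data import StudyDesign

from oracles import gauss_hermite_neg2ll


class TestJointDensity:
    def test_matches_direct_normal_density_product(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(1, 6)
            y = rng.normal(20, 5, size=n)
            f = rng.normal(20, 5, size=n)
            s2 = rng.uniform(0.5, 10, size=n)
            eta = rng.normal(0, 0.3, size=2)
            om = rng.uniform(0.01, 0.3, size=2)
            expected = -2 * (
                stats.norm.logpdf(y, f, np.sqrt(s2)).sum()
                + stats.norm.logpdf(eta, 0, np.sqrt(om)).sum()
            )
            assert individual_joint_neg2ll(y, f, eta, om, s2) == pytest.approx(expected)

    def test_perfect_prediction_leaves_normalization_constants(self):
        y = np.array([20.0, 30.0])
        s2 = np.array([4.0, 9.0])
        om = np.array([0.1, 0.2])
        val = individual_joint_neg2ll(y, y, np.zeros(2), om, s2)
        assert val == pytest.approx(
            np.log(2 * np.pi * s2).sum() + np.log(2 * np.pi * om).sum()
        )

    def test_single_observation_additive_residual_term(self):
        y, f, sd = np.array([25.0]), np.array([22.0]), 3.65
        base = individual_joint_neg2ll(f, f, np.zeros(2), np.array([0.1, 0.1]),
                                       np.array([sd**2]))
        val = individual_joint_neg2ll(y, f, np.zeros(2), np.array([0.1, 0.1]),
                                      np.array([sd**2]))
        assert val - base == pytest.approx((y[0] - f[0]) ** 2 / sd**2)


class TestInformationCriteria:
    def test_identities(self):
        aic, bic = information_criteria(100.0, 5, 199)
        assert aic == pytest.approx(110.0)
        assert bic == pytest.approx(100 + 5 * np.log(199))
        assert bic == pytest.approx(126.4665, abs=1e-3)
        assert information_criteria(50.0, 0, 10) == (50.0, 50.0)

    def test_hold_for_every_fit(self, final_fit1):
        fit = final_fit1
        aic, bic = information_criteria(fit.ofv, fit.n_params, fit.n_obs)
        assert fit.aic == pytest.approx(aic)
        assert fit.bic == pytest.approx(bic)


class TestShrinkage:
    def test_all_ebes_zero_gives_full_shrinkage(self):
        out = eta_shrinkage(np.zeros((10, 2)), np.array([0.08, 0.02]))
        assert out == {"etaCL": 100.0, "etaV": 100.0}

    def test_sd_equal_omega_gives_zero(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=(2000, 2))
        e = (e - e.mean(0)) / e.std(0, ddof=1)  # exactly unit SD
        e = e * np.sqrt([0.08, 0.02])
        out = eta_shrinkage(e, np.array([0.08, 0.02]))
        assert out["etaCL"] == pytest.approx(0.0, abs=1e-9)
        assert out["etaV"] == pytest.approx(0.0, abs=1e-9)

    def test_partial_shrinkage_value(self):
        e = np.zeros((3, 2))
        e[:, 0] = np.array([-1.0, 0.0, 1.0]) * 0.87 * np.sqrt(0.08)
        out = eta_shrinkage(e, np.array([0.08, 1.0]))
        assert out["etaCL"] == pytest.approx(13.0, abs=0.05)

    def test_omega_zero_flagged(self):
        with pytest.warns(UserWarning):
            out = eta_shrinkage(np.zeros((5, 2)), np.array([0.0, 0.1]))
        assert np.isnan(out["etaCL"])


class TestLeastSquaresReduction:
    def test_omega_zero_single_subject_recovers_noise_free_params(self):
        # no random effects, no noise: FOCE collapses to least squares and
        # must recover the generating CL and V to 4 significant digits
        design = StudyDesign(
            n_subjects=1,
            sampling_offsets=(0.0, 1.0, 2.0, 4.0, 5.0, 8.0, 12.0),
            sample_dropout=0.0,
        )
        theta = ThetaVector(dCLdCCR=0.0, dCLdBMI=0.0,
                            dCLdfurosemide=0.0, dVdfurosemide=0.0)
        ds, truth = generate_study(
            seed=2, design=design, theta=theta,
            omega=OmegaMatrix(0.0, 0.0), sigma=ResidualModel("additive", 1e-12),
        )
        spec = ModelSpec(effects=(), residual="additive", baseline="data")
        fit = foce_fit(
            ds, spec,
            fix={"omega2_CL": 0.0, "omega2_V": 0.0, "stdev0": 1.0},
            inits={"tvCL": 4.0, "tvV": 20.0},
        )
        assert fit.params["tvCL"] == pytest.approx(2.98, rel=5e-4)
        assert fit.params["tvV"] == pytest.approx(25.07, rel=5e-4)


class TestQuadratureOracle:
    def test_foce_ofv_matches_exact_marginal_when_nearly_linear(self):
        # with small omega the model is near-linear in eta, where the FOCE
        # (Laplace-type) approximation must agree with exact quadrature
        design = StudyDesign(n_subjects=8, sample_dropout=0.0)
        omega = OmegaMatrix(0.01**2, 0.01**2)
        ds, truth = generate_study(seed=4, design=design, omega=omega)
        spec = reference_model_spec()
        params = dict(truth["params"])
        ofv_foce, _ = evaluate_ofv(ds, spec, params)
        ofv_exact = gauss_hermite_neg2ll(compile_design(ds, spec), spec, params)
        assert ofv_foce == pytest.approx(ofv_exact, rel=0.01)

    def test_foce_ofv_close_at_moderate_omega(self):
        design = StudyDesign(n_subjects=8, sample_dropout=0.0)
        ds, truth = generate_study(seed=4, design=design)
        spec = reference_model_spec()
        ofv_foce, _ = evaluate_ofv(ds, spec, truth["params"])
        ofv_exact = gauss_hermite_neg2ll(compile_design(ds, spec), spec,
                                         truth["params"])
        assert ofv_foce == pytest.approx(ofv_exact, rel=0.02)


class TestRichDataRecovery:
    def test_theta_recovered_within_5pct_on_rich_low_noise_study(self):
        design = StudyDesign(
            n_subjects=200,
            sampling_offsets=(0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0,
                              8.0, 10.0, 12.0),
            sample_dropout=0.0,
        )
        # small between-subject and residual variability so the remaining
        # deviation measures estimator consistency, not sampling noise
        ds, truth = generate_study(
            seed=10, design=design,
            omega=OmegaMatrix(0.03**2, 0.03**2),
            sigma=ResidualModel("additive", 0.5),
        )
        fit = foce_fit(ds, reference_model_spec())
        for name in ("tvCL", "tvV", "dCLdCCR", "dCLdBMI",
                     "dCLdfurosemide", "dVdfurosemide"):
            assert fit.params[name] == pytest.approx(truth["params"][name],
                                                     rel=0.05), name


class TestFitContract:
    def test_ofv_not_worse_than_inits_and_deterministic(self, study1):
        ds, truth = study1
        spec = reference_model_spec()
        ofv_init, _ = evaluate_ofv(ds, spec, truth["params"])
        fit = foce_fit(ds, spec, inits=truth["params"])
        assert fit.ofv <= ofv_init + 1e-9
        fit2 = foce_fit(ds, spec, inits=truth["params"])
        assert fit2.ofv == fit.ofv
        assert fit2.params == fit.params

    def test_residual_variants_fit(self, small_study):
        ds, _ = small_study
        for kind in ("proportional", "combined"):
            spec = ModelSpec(effects=(), residual=kind)
            fit = foce_fit(ds, spec)
            assert np.isfinite(fit.ofv)
            for name in spec.residual_param_names:
                assert fit.params[name] > 0

    def test_invalid_inputs(self, small_study):
        ds, _ = small_study
        with pytest.raises(ValueError):
            foce_fit(ds, ModelSpec(), inits={"tvCL": -1.0})
        with pytest.raises(ValueError):
            foce_fit(ds, ModelSpec(), fix={"nonexistent": 1.0})


class TestStandardErrors:
    def test_se_matches_independent_hessian_and_flip_symmetry(self, small_study):
        ds, _ = small_study
        spec = ModelSpec()
        fit = foce_fit(ds, spec)
        se, cv = standard_errors(fit, ds)
        assert all(np.isfinite(se[n]) and se[n] > 0 for n in spec.param_names)
        # independent check: coarser-step Hessian built in this test
        from mgpk.estimation import evaluate_ofv as eofv

        names = list(spec.param_names)
        x0 = np.array([fit.params[n] for n in names])

        def half(x):
            p = dict(zip(names, x))
            return 0.5 * eofv(ds, spec, p)[0]

        h = 3e-3 * np.maximum(np.abs(x0), 1e-2)
        H = np.zeros((len(x0), len(x0)))
        f0 = half(x0)
        for i in range(len(x0)):
            for j in range(len(x0)):
                xi = x0.copy(); xi[i] += h[i]; xi[j] += h[j]
                xj = x0.copy(); xj[i] += h[i]; xj[j] -= h[j]
                xk = x0.copy(); xk[i] -= h[i]; xk[j] += h[j]
                xl = x0.copy(); xl[i] -= h[i]; xl[j] -= h[j]
                H[i, j] = (half(xi) - half(xj) - half(xk) + half(xl)) / (4 * h[i] * h[j])
        se_ind = np.sqrt(np.diag(np.linalg.inv(H)))
        for n, s in zip(names, se_ind):
            assert se[n] == pytest.approx(s, rel=0.1), n
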