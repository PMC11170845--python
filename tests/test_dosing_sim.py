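"""Monte Carlo dose simulation: regimen construction, PTA counting vs a
brute-force oracle, the appropriateness rule, and ordering properties."""

import numpy as np
import pytest

from mgpk.covariate_model import OmegaMatrix, ThetaVector
from mgpk.dosing_sim import (
    PTAResult,
    pta,
    regimen_appropriate,
    run_grid,
    recommend,
    simulate_population,
    standard_regimens,
)
from mgpk.units import MG_PER_MMOL

from oracles import brute_force_pta

CELL = {"CCR": 175.0, "BMI": 29.0, "furosemide": 0}


class TestStandardRegimens:
    def test_four_regimens_with_expected_totals_and_durations(self):
        regs = standard_regimens()
        assert len(regs) == 4
        assert regs["load5g_maint10g"].total_grams == pytest.approx(15.0)
        assert regs["load2.5g_maint10g"].total_grams == pytest.approx(12.5)
        # total infusion spans: 20 min + 6.7 h or 7.7 h
        assert regs["load5g_maint10g"].end_of_last_infusion == pytest.approx(7.0333, abs=1e-3)
        assert regs["load2.5g_maint15g"].end_of_last_infusion == pytest.approx(8.0333, abs=1e-3)

    def test_rates(self):
        regs = standard_regimens()
        load, maint = regs["load5g_maint10g"].events
        salt = regs["load5g_maint10g"].salt_factor
        assert load.rate / salt == pytest.approx(15.0)   # 5 g / 20 min = 15 g/h labeled
        assert maint.rate / salt == pytest.approx(10 / 6.7)
        assert maint.start_time == pytest.approx(load.end_time)


class TestSimulatePopulation:
    def test_omega_zero_gives_identical_profiles(self):
        reg = standard_regimens()["load5g_maint10g"]
        _, conc = simulate_population(ThetaVector(), OmegaMatrix(0, 0), CELL, reg,
                                      n=20, seed=3)
        assert np.allclose(conc, conc[0])

    def test_seed_stream_extension(self):
        reg = standard_regimens()["load5g_maint10g"]
        _, c1 = simulate_population(ThetaVector(), OmegaMatrix(), CELL, reg, n=50, seed=9)
        _, c2 = simulate_population(ThetaVector(), OmegaMatrix(), CELL, reg, n=100, seed=9)
        assert np.allclose(c1, c2[:50])

    def test_median_converges_to_typical_profile(self):
        # median of the log-normal eta multiplier is 1
        reg = standard_regimens()["load5g_maint10g"]
        t, typ = simulate_population(ThetaVector(), OmegaMatrix(0, 0), CELL, reg,
                                     n=1, seed=0)
        _, conc = simulate_population(ThetaVector(), OmegaMatrix(), CELL, reg,
                                      n=10_000, seed=1)
        med = np.median(conc, axis=0)
        sel = t >= 1.0
        assert np.allclose(med[sel], typ[0][sel], rtol=0.03)

    def test_invalid_cell(self):
        reg = standard_regimens()["load5g_maint10g"]
        with pytest.raises(ValueError):
            simulate_population(ThetaVector(), OmegaMatrix(), {"CCR": 175.0}, reg)


class TestPTA:
    def test_all_inside_and_all_below(self):
        times = np.arange(0.0, 8.1, 1.0)
        inside = np.full((10, len(times)), 2.5 * MG_PER_MMOL)
        assert np.all(pta(inside, times).fraction == 1.0)
        below = np.full((10, len(times)), 0.76 * MG_PER_MMOL)  # baseline only
        assert np.all(pta(below, times).fraction == 0.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(12)
        times = np.arange(0.0, 8.1, 1.0)
        window_mg = (2.0 * MG_PER_MMOL, 3.5 * MG_PER_MMOL)
        for _ in range(10):
            conc = rng.uniform(20, 100, size=(50, len(times)))
            got = pta(conc, times).fraction
            want = brute_force_pta(conc, times, window_mg, range(1, 9))
            assert np.array_equal(got, want)

    def test_requires_grid_coverage(self):
        with pytest.raises(ValueError):
            pta(np.zeros((5, 4)), np.array([0.0, 1.0, 2.0, 3.0]))


class TestAppropriatenessRule:
    def make(self, fractions):
        hours = np.arange(1.0, 9.0)
        return PTAResult(hours=hours, fraction=np.asarray(fractions, float), n=100)

    def test_rule_on_fraction_sequences(self):
        ok = self.make([0.1, 0.3, 0.8, 0.95, 0.95, 0.95, 0.95, 0.95])
        assert regimen_appropriate(ok)
        boundary = self.make([1, 1, 1, 1, 0.90, 1, 1, 1])  # exactly 0.90 at h5
        assert not regimen_appropriate(boundary)

    def test_matches_direct_rule_on_random_sequences(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            f = rng.uniform(0.7, 1.0, size=8)
            res = self.make(f)
            assert regimen_appropriate(res) == bool(np.all(f[3:] > 0.90))

    def test_missing_hours_error(self):
        res = PTAResult(hours=np.array([1.0, 2.0, 3.0]), fraction=np.ones(3), n=10)
        with pytest.raises(ValueError):
            regimen_appropriate(res)


class TestOrderingProperties:
    def test_furosemide_cell_has_higher_concentrations(self):
        # furosemide reduces both CL and V -> higher exposure for the same dose
        reg = standard_regimens()["load5g_maint10g"]
        t, c0 = simulate_population(ThetaVector(), OmegaMatrix(0, 0),
                                    {**CELL, "furosemide": 0}, reg, n=1, seed=0)
        _, c1 = simulate_population(ThetaVector(), OmegaMatrix(0, 0),
                                    {**CELL, "furosemide": 1}, reg, n=1, seed=0)
        sel = t > 0.5
        assert np.all(c1[0][sel] > c0[0][sel])

    def test_higher_loading_dose_dominates_first_two_hours(self):
        regs = standard_regimens()
        t, lo = simulate_population(ThetaVector(), OmegaMatrix(0, 0), CELL,
                                    regs["load2.5g_maint10g"], n=1, seed=0)
        _, hi = simulate_population(ThetaVector(), OmegaMatrix(0, 0), CELL,
                                    regs["load5g_maint10g"], n=1, seed=0)
        sel = (t > 0) & (t <= 2.0)
        assert np.all(hi[0][sel] > lo[0][sel])

    def test_pta_monotone_in_clearance_before_overshoot(self):
        # typical individual, before any window overshoot: lower CL -> conc
        # closer to / inside the window from below
        reg = standard_regimens()["load5g_maint10g"]
        fracs = []
        for ccr in (140.0, 175.0, 213.0):  # CL increases with CCR
            _, conc = simulate_population(
                ThetaVector(), OmegaMatrix(0, 0),
                {"CCR": ccr, "BMI": 29.0, "furosemide": 0}, reg, n=1, seed=0)
            fracs.append(conc[0][-1])
        assert fracs[0] > fracs[1] > fracs[2]


class TestGridAndRecommendation:
    def test_grid_shape_and_single_recommendation_per_group(self):
        grid = run_grid(n=50, seed=4)
        assert set(grid["regimen"]) == set(standard_regimens())
        assert len(grid) == 4 * 3 * 3 * 2 * 8  # regimen x CCR x BMI x furo x hour
        assert grid["pta"].between(0, 1).all()
        rec = recommend(grid)
        assert set(rec) == {"furosemide=0", "furosemide=1"}
        for group in rec.values():
            assert group["first_line"] in standard_regimens()

    def test_pta_unit_invariance(self):
        # same fractions whether concentrations and window are in mg/L or
        # rescaled by a common factor
        rng = np.random.default_rng(2)
        times = np.arange(0.0, 8.1, 1.0)
        conc = rng.uniform(20, 100, size=(30, len(times)))
        base = pta(conc, times).fraction
        scaled = pta(conc * 10, times,
                     window_mmol=(20.0, 35.0)).fraction
        assert np.array_equal(base, scaled)
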