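"""Random predator equation: closed form vs. oracle, fitting, CL comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import funcresp as fr
from funcresp import DesignError, DomainError, InfiniteCapacityError
from funcresp.rogers import assign_group_letters


class TestPredictNa:
    def test_zero_attack_rate_means_zero_consumption(self):
        for th, n0 in [(0.0, 2), (5.0, 16), (30.0, 128)]:
            assert fr.predict_na(0.0, th, n0, 24.0) == 0.0

    def test_zero_handling_time_closed_form(self):
        # th -> 0 collapses to the depletion-only form n0*(1 - exp(-a t))
        assert fr.predict_na(0.1, 0.0, 2, 24.0) == pytest.approx(2 * (1 - np.exp(-2.4)), abs=1e-12)

    def test_matches_bisection_on_spec_point(self):
        oracle = fr.predict_na_bisection(0.14, 8.23, 4, 24.0, tol=1e-12)
        assert fr.predict_na(0.14, 8.23, 4, 24.0) == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("a", [0.005, 0.05, 0.5])
    @pytest.mark.parametrize("th", [0.1, 1.0, 8.0, 30.0])
    @pytest.mark.parametrize("n0", [2, 8, 32, 128])
    def test_lambertw_equals_bisection_grid(self, a, th, n0):
        oracle = fr.predict_na_bisection(a, th, n0, 24.0, tol=1e-12)
        assert fr.predict_na(a, th, n0, 24.0) == pytest.approx(oracle, abs=1e-8)

    def test_large_argument_stability(self):
        # a*th*n0 huge: exp overflows unless evaluated in log space
        na = fr.predict_na(10.0, 30.0, 128, 24.0)
        assert 0.0 <= na <= 128.0 and np.isfinite(na)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            fr.predict_na(-0.1, 1.0, 2, 24.0)
        with pytest.raises(DomainError):
            fr.predict_na(0.1, -1.0, 2, 24.0)
        with pytest.raises(DomainError):
            fr.predict_na(0.1, 1.0, 2, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.001, 1.0),
        th=st.floats(0.0, 30.0),
        n0=st.integers(1, 128),
        t=st.floats(1.0, 48.0),
    )
    def test_bounds_and_monotonicity(self, a, th, n0, t):
        na = fr.predict_na(a, th, n0, t)
        assert 0.0 <= na <= n0
        if th > 0:
            assert na <= t / th + 1.0  # handling-time capacity bound
        # non-decreasing in density, attack rate and time
        assert fr.predict_na(a, th, n0 + 1, t) >= na - 1e-9
        assert fr.predict_na(a * 1.5, th, n0, t) >= na - 1e-9
        assert fr.predict_na(a, th, n0, t * 1.5) >= na - 1e-9

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.floats(0.005, 0.5), th=st.floats(0.1, 30.0), n0=st.integers(2, 64))
    def test_type2_proportion_declines_with_density(self, a, th, n0):
        p1 = fr.predict_na(a, th, n0, 24.0) / n0
        p2 = fr.predict_na(a, th, 2 * n0, 24.0) / (2 * n0)
        assert p2 <= p1 + 1e-9

    def test_small_handling_time_approaches_limit(self):
        for a, n0 in [(0.05, 4), (0.3, 16)]:
            assert fr.predict_na(a, 1e-9, n0, 24.0) == pytest.approx(fr.holling_na(a, n0, 24.0), abs=1e-6)


class TestFitRogers:
    def test_noiseless_self_consistency(self):
        n0 = np.repeat([2.0, 4.0, 8.0, 16.0], 15)
        na = fr.predict_na(0.07, 5.05, n0, 24.0)
        f = fr.fit_rogers_arrays(n0, na, 24.0)
        assert f.a_hat == pytest.approx(0.07, abs=1e-6)
        assert f.th_hat == pytest.approx(5.05, abs=1e-6)
        assert f.converged

    def test_optimum_beats_coarse_grid(self, toy_trials):
        f = fr.fit_rogers(toy_trials)
        n0 = np.array([t.n0 for t in toy_trials], dtype=float)
        na = np.array([t.na for t in toy_trials], dtype=float)
        grid_sse = min(
            float(np.sum((fr.predict_na(a, th, n0, 24.0) - na) ** 2))
            for a in np.linspace(0.001, 0.5, 60)
            for th in np.linspace(0.1, 30.0, 60)
        )
        assert f.sse <= grid_sse * (1 + 1e-6)

    def test_saturated_trials_flagged_unconverged(self):
        trials = [
            fr.PredationTrial(predator_instar=1, treatment="control", n0=n0, na=n0, replicate_id=r)
            for n0 in (2, 4, 8)
            for r in range(1, 6)
        ]
        f = fr.fit_rogers(trials)
        assert not f.converged
        assert "boundary" in f.diagnostic or "bound" in f.diagnostic or "saturated" in f.diagnostic

    def test_single_density_rejected(self):
        trials = [
            fr.PredationTrial(predator_instar=1, treatment="control", n0=4, na=i % 3, replicate_id=i)
            for i in range(1, 7)
        ]
        with pytest.raises(DesignError):
            fr.fit_rogers(trials)

    def test_all_zero_consumption_rejected(self):
        trials = [
            fr.PredationTrial(predator_instar=1, treatment="control", n0=n0, na=0, replicate_id=r)
            for n0 in (2, 4)
            for r in range(1, 4)
        ]
        with pytest.raises(DesignError):
            fr.fit_rogers(trials)

    def test_mixed_groups_rejected(self):
        trials = [
            fr.PredationTrial(predator_instar=1, treatment="control", n0=2, na=1),
            fr.PredationTrial(predator_instar=2, treatment="control", n0=4, na=1),
        ]
        with pytest.raises(DesignError):
            fr.fit_rogers(trials)

    def test_bootstrap_cls_bracket_estimate(self, ladder2):
        trials = fr.simulate_trials(fr.FR_PRESETS["instar2_cry3aa"], seed=11)
        f = fr.fit_rogers(trials, ci_method="bootstrap", bootstrap_b=60, seed=11)
        assert f.a_cl[0] <= f.a_hat <= f.a_cl[1]
        assert f.th_cl[0] <= f.th_hat <= f.th_cl[1]

    def test_fit_is_deterministic(self):
        trials = fr.simulate_trials(fr.FR_PRESETS["instar2_control"], seed=21)
        f1 = fr.fit_rogers(trials, seed=3)
        f2 = fr.fit_rogers(trials, seed=3)
        assert f1 == f2


class TestMaxAttack:
    def test_first_instar_control_row(self):
        # printed: Th 17.84 (13.02-22.65) -> T/Th 1.34 (1.05-1.84)
        tth, (lo, hi) = fr.max_attack(17.84, (13.02, 22.65), 24.0)
        assert tth == pytest.approx(1.34, abs=0.02)
        assert lo == pytest.approx(1.05, abs=0.02)
        assert hi == pytest.approx(1.84, abs=0.02)

    def test_third_instar_cry3aa_row(self):
        tth, _ = fr.max_attack(0.57, (0.54, 0.59), 24.0)
        assert tth == pytest.approx(42.105, abs=1e-3)
        assert tth == pytest.approx(42.1, abs=0.02)

    def test_one_prey_per_window(self):
        tth, _ = fr.max_attack(24.0, (20.0, 28.0), 24.0)
        assert tth == 1.0

    def test_cl_order_reversed_by_decreasing_transform(self):
        _, (lo, hi) = fr.max_attack(10.0, (5.0, 20.0), 24.0)
        assert (lo, hi) == (24.0 / 20.0, 24.0 / 5.0)

    def test_zero_handling_time_flagged(self):
        with pytest.raises(InfiniteCapacityError):
            fr.max_attack(0.0, (0.0, 1.0), 24.0)


class TestComparisons:
    def _fit(self, th, th_cl, a=0.1, a_cl=(0.05, 0.2), converged=True, treatment="control"):
        tth, tth_cl = fr.max_attack(th, th_cl, 24.0)
        return fr.RogersFit(
            instar=1, treatment=treatment, a_hat=a, th_hat=th, a_cl=a_cl, th_cl=th_cl,
            tth_hat=tth, tth_cl=tth_cl, exposure_h=24.0, n_trials=45, sse=1.0, converged=converged,
        )

    def test_disjoint_th_intervals_significant(self):
        # published first-instar handling times: 17.84 (13.02-22.65) vs 8.23 (7.48-8.99)
        r = fr.compare_parameters(
            self._fit(17.84, (13.02, 22.65)), self._fit(8.23, (7.48, 8.99), treatment="cry3aa"), "th"
        )
        assert r.significant and set(r.letters) == {"a", "b"}

    def test_overlapping_attack_rates_not_significant(self):
        # published first-instar attack rates: 0.1 (0.03-0.23) vs 0.14 (0.03-0.25)
        r = fr.compare_parameters(
            self._fit(17.84, (13.02, 22.65), a=0.1, a_cl=(0.03, 0.23)),
            self._fit(8.23, (7.48, 8.99), a=0.14, a_cl=(0.03, 0.25), treatment="cry3aa"),
            "a",
        )
        assert not r.significant and r.letters == ("a", "a")

    def test_identical_intervals_not_significant(self):
        r = fr.compare_parameters(self._fit(10.0, (8.0, 12.0)), self._fit(10.0, (8.0, 12.0)), "th")
        assert not r.significant

    def test_unconverged_fit_refused(self):
        with pytest.raises(ValueError, match="converge"):
            fr.compare_parameters(self._fit(10.0, (8.0, 12.0)), self._fit(9.0, (7.0, 11.0), converged=False), "th")

    def test_letters_chain_through_overlap(self):
        # A overlaps B, B overlaps C, A disjoint C: one connected component
        letters = assign_group_letters([1.0, 2.0, 3.0], [(0.5, 1.6), (1.5, 2.6), (2.5, 3.5)])
        assert letters == ["a", "a", "a"]
        letters = assign_group_letters([1.0, 3.0], [(0.5, 1.5), (2.5, 3.5)])
        assert letters == ["a", "b"]
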