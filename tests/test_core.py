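"""Closed-form dispersion formulas: examples, invariants, matrix oracle."""

import json
import math

import numpy as np
import pytest
from scipy.integrate import quad

import tiaprop as tp
from tiaprop.core import SingularDesignError

LN2 = math.log(2.0)


class TestHalfLifeConversion:
    @pytest.mark.parametrize(
        "t_eff, t_phys, expected, tol",
        [
            (50.0, 159.5, 0.009518, 1e-6),  # published rounded constant
            (70.0, 70.0, 0.0, 1e-15),
            (40.0, 159.5, LN2 / 40 - LN2 / 159.5, 1e-15),
        ],
    )
    def test_values(self, t_eff, t_phys, expected, tol):
        assert tp.lambda_biol_from_half_lives(t_eff, t_phys) == pytest.approx(
            expected, abs=tol
        )

    def test_effective_longer_than_physical_rejected(self):
        with pytest.raises(ValueError):
            tp.lambda_biol_from_half_lives(200.0, 159.5)

    def test_round_trip(self):
        lam = tp.lambda_biol_from_half_lives(50.0, 159.5)
        assert tp.effective_half_life(lam, 159.5) == pytest.approx(50.0, rel=1e-12)


class TestMonoExpTAC:
    @pytest.mark.parametrize("t, expected", [(0, 100.0), (50, 50.0), (100, 25.0)])
    def test_eval_half_lives(self, tac50, t, expected):
        assert tac50(t) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing(self, tac50):
        t = np.linspace(0, 300, 100)
        assert np.all(np.diff(tac50(t)) < 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            tp.MonoExpTAC(-1.0, 0.01, 0.004)
        with pytest.raises(ValueError):
            tp.MonoExpTAC(100.0, -0.01, 0.004)
        with pytest.raises(ValueError):
            tp.MonoExpTAC(100.0, 0.01, 0.0)

    def test_zero_biological_decay_allowed(self):
        tac = tp.MonoExpTAC(100.0, 0.0, LN2 / 159.5)
        assert tac.tau == pytest.approx(159.5 / LN2, rel=1e-12)


class TestTiaClosedForm:
    def test_zero_amplitude(self):
        assert tp.tia_closed_form(tp.MonoExpTAC(0.0, 0.01, 0.004)) == 0.0

    def test_reference_value_and_quadrature(self, tac50):
        # 100 / (ln2/50) = 7213.5 MBq h; cross-check by adaptive quadrature
        assert tac50.tia == pytest.approx(100.0 / (LN2 / 50.0), rel=1e-12)
        num, _ = quad(tac50.activity, 0, np.inf)
        assert tac50.tia == pytest.approx(num, rel=1e-6)

    def test_linearity_in_A0(self, tac50):
        doubled = tp.MonoExpTAC(2 * tac50.A0, tac50.lambda_biol, tac50.lambda_phys)
        assert doubled.tia == pytest.approx(2 * tac50.tia, rel=1e-14)


class TestScheduleMoments:
    @pytest.mark.parametrize(
        "times, mean, var",
        [
            ((21, 93, 165), 93.0, 3456.0),
            ((24, 96, 168), 96.0, 3456.0),
            ((24, 96), 60.0, 1296.0),
        ],
    )
    def test_examples(self, times, mean, var):
        m = tp.schedule_moments(tp.Schedule(times))
        assert (m.mean_t, m.var_t, m.n) == (mean, var, len(times))

    def test_divisor_is_n_not_n_minus_1(self):
        times = (10.0, 20.0, 60.0)
        m = tp.schedule_moments(tp.Schedule(times))
        assert m.var_t == pytest.approx(np.var(times, ddof=0))
        assert m.var_t != pytest.approx(np.var(times, ddof=1))

    def test_identical_times_rejected(self):
        with pytest.raises(SingularDesignError):
            tp.Schedule([24.0, 24.0, 24.0])

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            tp.Schedule([24.0])
        with pytest.raises(ValueError):
            tp.Schedule([-1.0, 24.0])

    def test_nesting_multiset_with_tolerance(self):
        full = tp.Schedule([24.0, 24.0, 96.0])
        assert tp.Schedule([24.0, 96.0]).is_nested_in(full)
        assert tp.Schedule([24.0, 24.0, 96.0]).is_nested_in(full)
        # multiset semantics: the duplicate 96 is not available twice
        assert not tp.Schedule([24.0, 96.0, 96.0]).is_nested_in(full)
        assert tp.Schedule([24.0 + 5e-10, 96.0]).is_nested_in(full)
        assert not tp.Schedule([24.1, 96.0]).is_nested_in(full)


class TestParamCovariance:
    def test_centered_design_uncorrelated(self, tac50):
        # mean time 0 (formal design): correlation vanishes, CV(A0) = r/sqrt(n)
        m = tp.ScheduleMoments(mean_t=0.0, var_t=1000.0, n=4)
        pc = tp.param_covariance_monoexp(tac50, m, 0.1)
        assert pc.corr == 0.0
        assert pc.cv_A0 == pytest.approx(0.1 / 2.0, rel=1e-14)

    def test_reference_design(self, tac50, sched_full):
        pc = tp.param_covariance_monoexp(tac50, sched_full.moments(), 0.1)
        assert pc.cv_A0 == pytest.approx(0.11055, rel=1e-4)
        assert pc.sd_lambda == pytest.approx(9.821e-4, rel=1e-3)
        assert pc.corr == pytest.approx(0.8528, rel=1e-4)

    def test_matches_weighted_normal_matrix_oracle(self, tac50, sched_full):
        # independent oracle: r^2 (J^T W J)^-1 built element-wise
        t = np.asarray(sched_full.times)
        a = tac50.activity(t)
        J = np.column_stack([a / tac50.A0, -t * a])
        W = np.diag(a**-2.0)
        oracle = 0.1**2 * np.linalg.inv(J.T @ W @ J)
        pc = tp.param_covariance_monoexp(tac50, sched_full.moments(), 0.1)
        assert np.allclose(pc.matrix, oracle, rtol=1e-10)


class TestVarRelativeError:
    def test_minimum_at_matched_mean(self):
        pop = tp.PopulationTauStats.fixed(72.0)
        m = tp.ScheduleMoments(mean_t=72.0, var_t=3456.0, n=3)
        assert tp.var_relative_error(m, pop, 0.1) == pytest.approx(0.01 / 3, rel=1e-14)

    def test_reference_value(self, tac50, sched_full):
        v = tp.var_relative_error(
            sched_full.moments(), tp.PopulationTauStats.fixed(tac50.tau), 0.1
        )
        assert v == pytest.approx(0.0038827, rel=1e-4)
        assert math.sqrt(v) == pytest.approx(0.0623, abs=2e-4)

    def test_symmetric_about_population_mean(self):
        pop = tp.PopulationTauStats.from_mean_cv(80.0, 0.1)
        for off in (5.0, 20.0, 55.0):
            lo = tp.var_relative_error(tp.ScheduleMoments(80 - off, 2000.0, 3), pop, 0.1)
            hi = tp.var_relative_error(tp.ScheduleMoments(80 + off, 2000.0, 3), pop, 0.1)
            assert lo == pytest.approx(hi, rel=1e-14)

    def test_grid_minimum_and_s2_monotonicity(self):
        pop = tp.PopulationTauStats.from_mean_cv(78.0, 0.2)
        tbars = np.linspace(10, 150, 141)
        vals = [
            tp.var_relative_error(tp.ScheduleMoments(tb, 2500.0, 3), pop, 0.1)
            for tb in tbars
        ]
        assert tbars[int(np.argmin(vals))] == pytest.approx(78.0, abs=1.0)
        # strictly decreasing in s2 when offset or population spread is nonzero
        v_small = tp.var_relative_error(tp.ScheduleMoments(50.0, 1000.0, 3), pop, 0.1)
        v_large = tp.var_relative_error(tp.ScheduleMoments(50.0, 4000.0, 3), pop, 0.1)
        assert v_large < v_small


class TestVarRelativeDifference:
    def test_identical_schedules_give_zero(self, sched_full, right_kidney_stats):
        m = sched_full.moments()
        v = tp.var_relative_difference(m, m, right_kidney_stats, 0.1)
        assert v == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize(
        "reduced, expected",
        [((21, 93), 0.38552), ((21, 165), 0.16667)],
    )
    def test_reference_values(self, right_kidney_stats, reduced, expected):
        full = tp.Schedule([21, 93, 165])
        v = tp.var_relative_difference(
            full.moments(), tp.Schedule(reduced).moments(), right_kidney_stats, 1.0
        )
        assert v == pytest.approx(expected, rel=1e-4)

    def test_nonnegative_for_random_nested_pairs(self, rng):
        for _ in range(1000):
            n = rng.integers(3, 7)
            times = np.sort(rng.uniform(0, 200, n))
            times[-1] += 1.0  # guarantee spread
            keep = rng.choice(n, size=rng.integers(2, n), replace=False)
            if np.ptp(times[keep]) < 1e-6:
                continue
            pop = tp.PopulationTauStats.from_mean_cv(
                rng.uniform(20, 200), rng.uniform(0, 0.6)
            )
            v = tp.var_relative_difference(
                tp.Schedule(times).moments(),
                tp.Schedule(times[keep]).moments(),
                pop,
                rng.uniform(0.01, 0.3),
            )
            assert v >= -1e-12


class TestTiaJointCovariance:
    def test_identical_schedules_all_entries_equal(self, tac50, sched_full):
        m = sched_full.moments()
        tj = tp.tia_joint_covariance(tac50, m, m, 0.1)
        assert np.allclose(tj.matrix, tj.matrix[0, 0])
        assert tj.corr == pytest.approx(1.0)

    def test_correlation_identity(self, tac50, sched_full, sched_reduced):
        tj = tp.tia_joint_covariance(
            tac50, sched_full.moments(), sched_reduced.moments(), 0.1
        )
        assert tj.matrix[0, 1] == tj.matrix[0, 0]
        assert tj.corr == pytest.approx(tj.sd_full / tj.sd_reduced, rel=1e-14)


class TestSdRatioPrediction:
    def test_identical_reduced_schedules(self, right_kidney_stats):
        full = tp.Schedule([21, 93, 165])
        red = tp.Schedule([21, 93])
        assert tp.sd_ratio_prediction(full, red, red, right_kidney_stats) == 1.0

    def test_published_right_kidney_ratio(self, right_kidney_stats):
        full = tp.Schedule([21, 93, 165])
        ratio = tp.sd_ratio_prediction(
            full, tp.Schedule([21, 93]), tp.Schedule([21, 165]), right_kidney_stats
        )
        assert ratio == pytest.approx(1.52, abs=0.01)

    def test_published_liver_ratio(self):
        full = tp.Schedule([21, 93, 165])
        pop = tp.PopulationTauStats.from_mean_cv(111.0, 0.21)
        ratio = tp.sd_ratio_prediction(
            full, tp.Schedule([21, 93]), tp.Schedule([21, 165]), pop
        )
        assert ratio == pytest.approx(2.9, abs=0.05)

    def test_measurement_cv_cancels(self, right_kidney_stats):
        full = tp.Schedule([21, 93, 165])
        a, b = tp.Schedule([21, 93]), tp.Schedule([21, 165])
        base = tp.sd_ratio_prediction(full, a, b, right_kidney_stats)
        for r in (0.01, 0.1, 0.5):
            rep_a = tp.compare_schedules(full, a, right_kidney_stats, r)
            rep_b = tp.compare_schedules(full, b, right_kidney_stats, r)
            assert rep_a.sd_delta / rep_b.sd_delta == pytest.approx(base, rel=1e-12)


class TestReports:
    def test_compare_schedules_requires_nesting(self, right_kidney_stats):
        with pytest.raises(ValueError, match="nested"):
            tp.compare_schedules(
                tp.Schedule([21, 93, 165]),
                tp.Schedule([21, 100]),
                right_kidney_stats,
                0.1,
            )

    def test_report_json_round_trip(self, right_kidney_stats):
        rep = tp.compare_schedules(
            tp.Schedule([21, 93, 165]), tp.Schedule([21, 93]), right_kidney_stats, 0.1
        )
        payload = json.loads(rep.to_json())
        assert payload["schedule_reduced_times_h"] == [21.0, 93.0]
        assert payload["var_delta"] == pytest.approx(rep.var_delta)
        assert payload["tau_stats"]["mean_tau_h"] == 78.0

    def test_tau_stats_from_samples_uses_sample_variance(self):
        taus = [70.0, 80.0, 90.0]
        ts = tp.PopulationTauStats.from_samples(taus)
        assert ts.var_tau == pytest.approx(np.var(taus, ddof=1))

    def test_measurement_model_warns_above_linearization_regime(self):
        with pytest.warns(UserWarning):
            tp.MeasurementModel(0.35)
        with pytest.raises(ValueError):
            tp.MeasurementModel(1.5)
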