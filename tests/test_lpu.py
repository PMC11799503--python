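"""Matrix propagation engine vs closed forms, symbolic and numeric oracles."""

import math

import numpy as np
import pytest
import sympy

import tiaprop as tp
from tiaprop.core import SingularDesignError


@pytest.fixture
def design(tac50, sched_full, sched_reduced):
    curve = tp.monoexp_curve(tac50.lambda_phys)
    return tp.build_design(curve, [tac50.A0, tac50.lambda_biol], sched_full, sched_reduced)


class TestBuildDesign:
    def test_jacobian_matches_symbolic_oracle(self, tac50, sched_full, sched_reduced, design):
        A0, lam_b, t = sympy.symbols("A0 lambda_b t", positive=True)
        expr = A0 * sympy.exp(-(tac50.lambda_phys + lam_b) * t)
        dA0 = sympy.lambdify((A0, lam_b, t), sympy.diff(expr, A0))
        dlam = sympy.lambdify((A0, lam_b, t), sympy.diff(expr, lam_b))
        for J, sched in (
            (design.jacobian_full, sched_full),
            (design.jacobian_reduced, sched_reduced),
        ):
            ts = np.asarray(sched.times)
            expected = np.column_stack(
                [dA0(tac50.A0, tac50.lambda_biol, ts), dlam(tac50.A0, tac50.lambda_biol, ts)]
            )
            assert np.allclose(J, expected, rtol=1e-12)

    def test_numeric_jacobian_agrees_with_analytic(self, tac50, sched_full, sched_reduced):
        analytic = tp.monoexp_curve(tac50.lambda_phys)
        numeric = tp.ParametricCurve(fun=analytic.fun)
        p = [tac50.A0, tac50.lambda_biol]
        da = tp.build_design(analytic, p, sched_full, sched_reduced)
        dn = tp.build_design(numeric, p, sched_full, sched_reduced)
        assert np.allclose(da.jacobian_full, dn.jacobian_full, rtol=1e-6)

    def test_flat_curve_weights(self, sched_full, sched_reduced):
        flat = tp.ParametricCurve(fun=lambda t, p: np.full(np.size(t), p[0]), n_params=1)
        d = tp.build_design(flat, [4.0], sched_full, sched_reduced)
        assert np.allclose(d.weights_full, 4.0**-2)

    def test_non_nested_rejected(self, tac50, sched_full):
        curve = tp.monoexp_curve(tac50.lambda_phys)
        with pytest.raises(ValueError, match="nested"):
            tp.build_design(curve, [100.0, 0.01], sched_full, tp.Schedule([24.0, 100.0]))

    def test_rank_deficient_design_rejected(self, tac50):
        # one effective time-point cannot identify two parameters
        with pytest.raises(SingularDesignError):
            tp.Schedule([24.0, 24.0])
        near = tp.Schedule([24.0, 24.0 + 1e-9, 96.0])
        curve = tp.monoexp_curve(tac50.lambda_phys)
        with pytest.raises(SingularDesignError):
            tp.build_design(
                curve, [tac50.A0, tac50.lambda_biol], near, tp.Schedule([24.0, 24.0 + 1e-9])
            )


class TestActivityCovariance:
    def test_cross_block_duplicates_reduced_variances(self, design):
        S = design.activity_covariance(0.1)
        n, m = design.n, design.n_reduced
        assert np.allclose(S[:m, n:], S[n:, n:])
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S)[:n], 0.1**2 / design.weights_full)


class TestJointParamCovariance:
    def test_identical_schedules_all_blocks_equal(self, tac50, sched_full):
        curve = tp.monoexp_curve(tac50.lambda_phys)
        d = tp.build_design(curve, [tac50.A0, tac50.lambda_biol], sched_full, sched_full)
        jpc = tp.joint_param_covariance(d, 0.1)
        assert np.allclose(jpc.block_full, jpc.block_reduced, rtol=1e-12)
        assert np.allclose(jpc.block_full, jpc.block_cross, rtol=1e-12)

    def test_reproduces_closed_form(self, tac50, sched_full, design):
        jpc = tp.joint_param_covariance(d=design, r=0.1)
        pc = tp.param_covariance_monoexp(tac50, sched_full.moments(), 0.1)
        assert np.allclose(jpc.block_full, pc.matrix, rtol=1e-10)
        assert np.allclose(jpc.block_cross, pc.matrix, rtol=1e-10)

    def test_quadratic_scaling_in_r(self, design):
        a = tp.joint_param_covariance(design, 0.1).matrix
        b = tp.joint_param_covariance(design, 0.2).matrix
        assert np.allclose(b, 4.0 * a, rtol=1e-12)

    def test_psd_on_random_designs(self, rng):
        lam_p = math.log(2) / 159.5
        curve = tp.monoexp_curve(lam_p)
        for _ in range(50):
            # well-separated time-points keep the design well conditioned
            times = rng.uniform(1, 30) + np.cumsum(rng.uniform(10, 60, 4))
            full = tp.Schedule(times)
            red = tp.Schedule(times[np.sort(rng.choice(4, 2, replace=False))])
            tac = tp.MonoExpTAC(rng.uniform(10, 500), rng.uniform(0, 0.05), lam_p)
            d = tp.build_design(curve, [tac.A0, tac.lambda_biol], full, red)
            jpc = tp.joint_param_covariance(d, 0.1)
            # the brute-force block algebra must reproduce the closed block
            # structure (cross block == full block) essentially exactly
            assert np.allclose(
                jpc.block_cross, jpc.block_full,
                rtol=1e-12, atol=1e-12 * np.trace(jpc.matrix),
            )
            M = tp.propagate_to_tia(jpc, tp.tia_transform_monoexp(tac)).matrix
            for mat in (jpc.matrix, M):
                assert np.linalg.eigvalsh(mat).min() >= -1e-10 * np.trace(mat)


class TestPropagateToTia:
    def test_selector_row_extracts_A0_block(self, design):
        jpc = tp.joint_param_covariance(design, 0.1)
        u = tp.TiaTransform(row=np.array([1.0, 0.0]), tia=1.0)
        M = tp.propagate_to_tia(jpc, u).matrix
        assert M[0, 0] == pytest.approx(jpc.block_full[0, 0], rel=1e-12)
        assert M[1, 1] == pytest.approx(jpc.block_reduced[0, 0], rel=1e-12)

    def test_matches_closed_form_tia_covariance(self, tac50, sched_full, sched_reduced, design):
        jpc = tp.joint_param_covariance(design, 0.1)
        lp = tp.propagate_to_tia(jpc, tp.tia_transform_monoexp(tac50))
        cf = tp.tia_joint_covariance(
            tac50, sched_full.moments(), sched_reduced.moments(), 0.1
        )
        assert np.allclose(lp.matrix, cf.matrix, rtol=1e-10)
        assert lp.corr == pytest.approx(cf.corr, rel=1e-10)

    def test_relative_variance_closed_form(self, tac50, sched_full, design):
        # V[eps] for the full schedule: (r^2/n)(1 + (tbar - tau)^2 / s2)
        jpc = tp.joint_param_covariance(design, 0.1)
        M = tp.propagate_to_tia(jpc, tp.tia_transform_monoexp(tac50)).matrix
        m = sched_full.moments()
        expected = 0.1**2 / m.n * (1 + (m.mean_t - tac50.tau) ** 2 / m.var_t)
        assert M[0, 0] / tac50.tia**2 == pytest.approx(expected, rel=1e-10)


class TestExpectedVariances:
    def test_degenerate_population_matches_fixed_curve(self, tac50, sched_full, sched_reduced):
        pop = tp.PopulationModel(
            mean_A0=tac50.A0, cv_A0=0.0, mean_lambda_biol=tac50.lambda_biol,
            cv_lambda_biol=0.0, lambda_phys=tac50.lambda_phys, measurement_cv=0.1,
        )
        for method in ("moments", "quadrature"):
            rep = tp.expected_variances(pop, sched_full, sched_reduced, method=method)
            fixed = tp.var_relative_error(
                sched_full.moments(), tp.PopulationTauStats.fixed(tac50.tau), 0.1
            )
            assert rep.var_epsilon_full == pytest.approx(fixed, rel=1e-10)

    @pytest.mark.parametrize("cv_lam", [0.05, 0.4])
    def test_quadrature_agrees_with_moment_shortcut(self, sched_full, sched_reduced, cv_lam):
        pop = tp.PopulationModel(cv_lambda_biol=cv_lam)
        a = tp.expected_variances(pop, sched_full, sched_reduced, method="moments")
        b = tp.expected_variances(pop, sched_full, sched_reduced, method="quadrature")
        assert b.var_epsilon_full == pytest.approx(a.var_epsilon_full, rel=5e-3)
        assert b.var_delta == pytest.approx(a.var_delta, rel=5e-3)

    def test_delta_variance_nonnegative_on_random_nested_designs(self, rng):
        for _ in range(100):
            times = rng.uniform(1, 30) + np.cumsum(rng.uniform(10, 60, 4))
            keep = np.sort(rng.choice(4, rng.integers(2, 4), replace=False))
            pop = tp.PopulationModel(
                mean_lambda_biol=rng.uniform(0.001, 0.05),
                cv_lambda_biol=rng.uniform(0.0, 0.5),
            )
            rep = tp.expected_variances(
                pop, tp.Schedule(times), tp.Schedule(times[keep]), method="quadrature",
                n_nodes=16,
            )
            assert rep.var_delta >= -1e-12
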