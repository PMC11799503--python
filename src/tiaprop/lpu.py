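"""General matrix law-of-propagation-of-uncertainty for joint full/reduced fits.

This module implements the linearized covariance propagation for a pair of
weighted least-squares fits of an arbitrary parametric time-activity curve
to a full schedule and a nested, reduced schedule.  The measurement errors
are independent with fixed CV ``r``, so the activity covariance is
``r**2 diag(A(t_i)**2)``; the measurements shared between the two fits are
identical, hence perfectly correlated, which makes the stacked activity
covariance block-structured.  Propagating through both fits jointly yields
a ``2p x 2p`` parameter covariance whose cross block equals the
full-schedule block, and a final Jacobian ("sandwich") step maps it to the
joint covariance of the two TIA estimates.

Weights here use the TRUE curve (the analytic idealization); the fitting
module deliberately weighs with the noisy estimates, as the simulations do.
The discrepancy is intentional: the analytic results assume ideal
weighting, and the Monte-Carlo verification probes how much that matters.

For the mono-exponential curve these matrix results collapse to the closed
forms of :mod:`tiaprop.core`; tests assert equality to 1e-10 relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss

from .core import (
    ComparisonReport,
    MeasurementModel,
    MonoExpTAC,
    Schedule,
    SingularDesignError,
    TiaJointCovariance,
    compare_schedules,
)
from .synthetic import PopulationModel

__all__ = [
    "ParametricCurve",
    "monoexp_curve",
    "DesignMatrices",
    "JointParamCovariance",
    "TiaTransform",
    "build_design",
    "joint_param_covariance",
    "tia_transform_monoexp",
    "propagate_to_tia",
    "expected_variances",
]

#: Condition-number threshold above which a design is treated as singular.
COND_MAX = 1e12


@dataclass(frozen=True)
class ParametricCurve:
    """A parametric TAC ``A(t, p)`` with optional analytic Jacobian.

    ``fun(t, p)`` maps an array of times and a parameter vector to
    activities; ``jac(t, p)``, if given, returns the ``len(t) x len(p)``
    matrix of partials dA/dp.  Missing Jacobians are computed by central
    differences with relative step 1e-6.
    """

    fun: callable
    jac: callable = None
    n_params: int = 2

    def jacobian(self, t, p):
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        if self.jac is not None:
            return np.asarray(self.jac(t, p), dtype=float)
        J = np.empty((t.size, p.size))
        for j in range(p.size):
            h = 1e-6 * max(abs(p[j]), 1e-12)
            pp, pm = p.copy(), p.copy()
            pp[j] += h
            pm[j] -= h
            J[:, j] = (self.fun(t, pp) - self.fun(t, pm)) / (2 * h)
        return J


def monoexp_curve(lambda_phys: float) -> ParametricCurve:
    """Mono-exponential curve with parameters ``p = (A0, lambda_biol)``."""

    def fun(t, p):
        return p[0] * np.exp(-(lambda_phys + p[1]) * np.asarray(t, dtype=float))

    def jac(t, p):
        t = np.asarray(t, dtype=float)
        a = fun(t, p)
        return np.column_stack([a / p[0], -t * a])

    return ParametricCurve(fun=fun, jac=jac, n_params=2)


@dataclass(frozen=True)
class DesignMatrices:
    """Jacobians and diagonal weights of the joint full/reduced design.

    Weights are the inverse squared true-curve values; Jacobians are
    evaluated at the true parameters.
    """

    jacobian_full: np.ndarray
    jacobian_reduced: np.ndarray
    weights_full: np.ndarray  # diagonal entries, length n
    weights_reduced: np.ndarray  # diagonal entries, length n - k
    #: for each reduced point, the index of the matching full-schedule point
    reduced_indices: tuple = None

    @property
    def n(self) -> int:
        return self.weights_full.size

    @property
    def n_reduced(self) -> int:
        return self.weights_reduced.size

    @property
    def p(self) -> int:
        return self.jacobian_full.shape[1]

    def block_jacobian(self) -> np.ndarray:
        J = np.zeros((self.n + self.n_reduced, 2 * self.p))
        J[: self.n, : self.p] = self.jacobian_full
        J[self.n :, self.p :] = self.jacobian_reduced
        return J

    def block_weights(self) -> np.ndarray:
        return np.diag(np.concatenate([self.weights_full, self.weights_reduced]))

    def activity_covariance(self, r) -> np.ndarray:
        """Stacked covariance of [A_full; A_reduced] (shared points duplicated).

        The cross blocks duplicate the reduced-set variances exactly since
        the shared activity estimates are identical, hence perfectly
        correlated.
        """
        cv = r.cv_activity if isinstance(r, MeasurementModel) else float(r)
        n, m = self.n, self.n_reduced
        var_full = 1.0 / self.weights_full  # A(t_i)^2
        var_red = 1.0 / self.weights_reduced
        S = np.zeros((n + m, n + m))
        S[:n, :n] = np.diag(var_full)
        S[n:, n:] = np.diag(var_red)
        idx = self.reduced_indices if self.reduced_indices is not None else range(m)
        for j, i in enumerate(idx):
            S[i, n + j] = S[n + j, i] = var_red[j]
        return cv**2 * S


def build_design(
    curve: ParametricCurve, params, full: Schedule, reduced: Schedule
) -> DesignMatrices:
    """Assemble Jacobians and true-curve weights for a nested schedule pair."""
    if not reduced.is_nested_in(full):
        raise ValueError("reduced schedule must be nested in the full schedule")
    p = np.asarray(params, dtype=float)
    tf = np.asarray(full.times)
    tr = np.asarray(reduced.times)
    # match each reduced point to a distinct full-schedule point (multiset)
    free = list(range(tf.size))
    idx = []
    for t in tr:
        i = min(free, key=lambda i: abs(tf[i] - t))
        idx.append(i)
        free.remove(i)
    jf = curve.jacobian(tf, p)
    jr = curve.jacobian(tr, p)
    wf = curve.fun(tf, p) ** -2.0
    wr = curve.fun(tr, p) ** -2.0
    d = DesignMatrices(jacobian_full=jf, jacobian_reduced=jr,
                       weights_full=wf, weights_reduced=wr,
                       reduced_indices=tuple(idx))
    for J, w, label in ((jf, wf, "full"), (jr, wr, "reduced")):
        nrm = J.T @ (w[:, None] * J)
        dg = np.diag(nrm)
        if np.any(dg <= 0):
            raise SingularDesignError(f"{label} design has a dead parameter")
        scaled = nrm / np.sqrt(np.outer(dg, dg))
        if np.linalg.cond(scaled) > COND_MAX:
            raise SingularDesignError(
                f"{label} design is numerically singular "
                f"(condition number > {COND_MAX:g}); near-duplicate "
                "time-points or an unidentifiable parametrization"
            )
    return d


def _scaled_inv(M: np.ndarray) -> np.ndarray:
    """Inverse via Jacobi (diagonal) preconditioning.

    TAC parameters live on wildly different scales (amplitude in MBq,
    decay constant in 1/h), which pushes the raw normal-matrix condition
    number to ~1e10 even for benign designs; scaling to unit diagonal
    removes the artificial part of the conditioning.
    """
    dg = np.diag(M)
    if np.any(dg <= 0):
        raise SingularDesignError("normal matrix has non-positive diagonal")
    s = np.sqrt(dg)
    outer = np.outer(s, s)
    try:
        inv = np.linalg.inv(M / outer)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("non-invertible normal matrix") from exc
    return inv / outer


@dataclass(frozen=True)
class JointParamCovariance:
    """``2p x 2p`` covariance of the stacked (full, reduced) fit parameters."""

    matrix: np.ndarray
    p: int

    @property
    def block_full(self) -> np.ndarray:
        return self.matrix[: self.p, : self.p]

    @property
    def block_reduced(self) -> np.ndarray:
        return self.matrix[self.p :, self.p :]

    @property
    def block_cross(self) -> np.ndarray:
        return self.matrix[: self.p, self.p :]


def joint_param_covariance(d: DesignMatrices, r) -> JointParamCovariance:
    """Joint parameter covariance by explicit block propagation.

    Computes the full sandwich ``(J^T W J)^-1 J^T W Sigma_A W J (J^T W
    J)^-1`` with the block-structured stacked activity covariance, and
    cross-checks it against the closed block form ``r^2 [[C', C'], [C',
    C'']]`` with ``C' = (J'^T W' J')^-1`` (the cross block equals the
    full-schedule block).  Returns the sandwich result.
    """
    cv = r.cv_activity if isinstance(r, MeasurementModel) else float(r)
    J = d.block_jacobian()
    W = d.block_weights()
    S = d.activity_covariance(cv)
    N = J.T @ W @ J
    Ninv = _scaled_inv(N)
    cov = Ninv @ J.T @ W @ S @ W @ J @ Ninv
    # closed block evaluation (shortcut)
    cf = cv**2 * _scaled_inv(
        d.jacobian_full.T @ (d.weights_full[:, None] * d.jacobian_full)
    )
    cr = cv**2 * _scaled_inv(
        d.jacobian_reduced.T @ (d.weights_reduced[:, None] * d.jacobian_reduced)
    )
    shortcut = np.block([[cf, cf], [cf, cr]])
    if not np.allclose(cov, shortcut, rtol=1e-6, atol=1e-9 * abs(cov).max()):
        raise SingularDesignError(
            "block propagation and closed block form disagree; design is "
            "ill-conditioned"
        )
    cov = 0.5 * (cov + cov.T)
    return JointParamCovariance(matrix=cov, p=d.p)


@dataclass(frozen=True)
class TiaTransform:
    """Jacobian row of TIA with respect to the curve parameters."""

    row: np.ndarray
    tia: float

    def block(self) -> np.ndarray:
        p = self.row.size
        U = np.zeros((2, 2 * p))
        U[0, :p] = self.row
        U[1, p:] = self.row
        return U


def tia_transform_monoexp(tac: MonoExpTAC) -> TiaTransform:
    """Mono-exponential TIA Jacobian ``tia * [1/A0, -tau]``."""
    return TiaTransform(
        row=tac.tia * np.array([1.0 / tac.A0, -tac.tau]), tia=tac.tia
    )


def propagate_to_tia(jpc: JointParamCovariance, u: TiaTransform) -> TiaJointCovariance:
    """Sandwich the joint parameter covariance into TIA space."""
    U = u.block()
    M = U @ jpc.matrix @ U.T
    M = 0.5 * (M + M.T)
    return TiaJointCovariance(
        matrix=M,
        cv_full=math.sqrt(M[0, 0]) / u.tia,
        cv_reduced=math.sqrt(M[1, 1]) / u.tia,
        corr=M[0, 1] / math.sqrt(M[0, 0] * M[1, 1]),
    )


def expected_variances(
    pop: PopulationModel,
    full: Schedule,
    reduced: Schedule,
    r=None,
    n_nodes: int = 64,
    method: str = "moments",
) -> ComparisonReport:
    """Population-expected error/difference variances for a schedule pair.

    ``method="moments"`` (default) plugs the exact induced ``E[tau]``,
    ``V[tau]`` into the mono-exponential closed forms — this is the
    two-moment shortcut the published predictions use.  ``method=
    "quadrature"`` instead averages the conditional matrix-LPU variances
    over the lognormal ``lambda_biol`` by Gauss-Hermite quadrature in log
    space.  The conditional variances are exactly quadratic in ``tau``, so
    the two routes agree to quadrature accuracy; both are kept as mutually
    independent implementations.
    """
    cv = pop.measurement_cv if r is None else (
        r.cv_activity if isinstance(r, MeasurementModel) else float(r)
    )
    if method == "moments":
        return compare_schedules(full, reduced, pop.tau_stats(n_nodes=n_nodes), cv)
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")
    if not reduced.is_nested_in(full):
        raise ValueError("reduced schedule must be nested in the full schedule")

    if pop.cv_lambda_biol == 0:
        lams = np.array([pop.mean_lambda_biol])
        wts = np.array([1.0])
    else:
        sigma2 = math.log1p(pop.cv_lambda_biol**2)
        mu = math.log(pop.mean_lambda_biol) - sigma2 / 2.0
        x, wts = hermegauss(n_nodes)
        wts = wts / math.sqrt(2.0 * math.pi)
        lams = np.exp(mu + math.sqrt(sigma2) * x)
        # drop extreme-tail nodes whose curve values underflow (their
        # Gauss-Hermite weights are < 1e-40; renormalization is exact to
        # machine precision)
        keep = (lams + pop.lambda_phys) * max(full.times) < 250.0
        lams, wts = lams[keep], wts[keep]
        wts = wts / wts.sum()

    curve = monoexp_curve(pop.lambda_phys)
    v_eps_full = v_eps_red = v_delta = 0.0
    for lam, wt in zip(lams, wts):
        tac = MonoExpTAC(pop.mean_A0, float(lam), pop.lambda_phys)
        d = build_design(curve, [tac.A0, tac.lambda_biol], full, reduced)
        jpc = joint_param_covariance(d, cv)
        M = propagate_to_tia(jpc, tia_transform_monoexp(tac)).matrix
        tia2 = tac.tia**2
        v_eps_full += wt * M[0, 0] / tia2
        v_eps_red += wt * M[1, 1] / tia2
        v_delta += wt * (M[0, 0] + M[1, 1] - 2.0 * M[0, 1]) / tia2
    return ComparisonReport(
        var_epsilon_full=v_eps_full,
        var_epsilon_reduced=v_eps_red,
        var_delta=v_delta,
        schedule_full=full,
        schedule_reduced=reduced,
        tau_stats=pop.tau_stats(n_nodes=n_nodes),
        measurement_cv=cv,
    )
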