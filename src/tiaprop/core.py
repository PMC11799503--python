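"""Closed-form dispersion formulas for mono-exponential time-activity curves.

The central objects are a mono-exponential time-activity curve (TAC),
``A(t) = A0 * exp(-(lambda_phys + lambda_biol) * t)``, an imaging *schedule*
(the acquisition time-points, in hours), and the coefficient of variation
``r`` of the individual activity estimates.  Under weighted least-squares
fitting with inverse-squared-activity weights, first-order (GUM / law of
propagation of uncertainty) linearization yields closed forms for

* the covariance of the fitted parameters ``(A0, lambda_biol)``
  (:func:`param_covariance_monoexp`),
* the variance of the relative error of the time-integrated activity (TIA)
  over a population of curves (:func:`var_relative_error`),
* the joint covariance of TIA estimates from a full and a reduced, nested
  schedule (:func:`tia_joint_covariance`), and
* the variance of the relative difference between those two estimates
  (:func:`var_relative_difference`).

All formulas depend on the schedule only through its point count ``n``, mean
``t_bar`` and variance ``s2``.  **The schedule variance uses divisor n**
(population convention), not ``n - 1``; this convention enters every
downstream number and is fixed by :func:`schedule_moments`.

Units are hours for time and MBq for activity throughout (any fixed
activity unit works since all dispersion measures are relative).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LN2",
    "LU177_HALF_LIFE_H",
    "SingularDesignError",
    "MonoExpTAC",
    "Schedule",
    "ScheduleMoments",
    "MeasurementModel",
    "PopulationTauStats",
    "ParamCovariance",
    "TiaJointCovariance",
    "ComparisonReport",
    "lambda_biol_from_half_lives",
    "effective_half_life",
    "tia_closed_form",
    "schedule_moments",
    "param_covariance_monoexp",
    "var_relative_error",
    "var_relative_difference",
    "tia_joint_covariance",
    "compare_schedules",
    "sd_ratio_prediction",
]

LN2 = math.log(2.0)

#: Physical half-life of 177Lu in hours.
LU177_HALF_LIFE_H = 159.5


class SingularDesignError(ValueError):
    """The schedule (design) does not identify both TAC parameters."""


def _as_cv(r) -> float:
    """Accept a :class:`MeasurementModel` or a bare CV float."""
    if isinstance(r, MeasurementModel):
        return r.cv_activity
    return float(r)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonoExpTAC:
    """A mono-exponential time-activity curve.

    Parameters
    ----------
    A0 : float
        Activity at ``t = 0`` (MBq).
    lambda_biol : float
        Biological decay constant (1/h).  May be 0 (physical decay only).
    lambda_phys : float
        Physical decay constant (1/h); must be positive.
    """

    A0: float
    lambda_biol: float
    lambda_phys: float

    def __post_init__(self):
        if not self.A0 >= 0:
            raise ValueError(f"A0 must be >= 0, got {self.A0}")
        if not self.lambda_biol >= 0:
            raise ValueError(f"lambda_biol must be >= 0, got {self.lambda_biol}")
        if not self.lambda_phys > 0:
            raise ValueError(f"lambda_phys must be > 0, got {self.lambda_phys}")

    @classmethod
    def from_half_lives(cls, A0: float, t_eff_half: float, t_phys_half: float) -> "MonoExpTAC":
        """Construct from the effective and physical half-lives (hours)."""
        lam_b = lambda_biol_from_half_lives(t_eff_half, t_phys_half)
        return cls(A0=A0, lambda_biol=lam_b, lambda_phys=LN2 / t_phys_half)

    @property
    def lambda_eff(self) -> float:
        return self.lambda_biol + self.lambda_phys

    @property
    def tau(self) -> float:
        """Time constant 1 / lambda_eff (h)."""
        return 1.0 / self.lambda_eff

    @property
    def tia(self) -> float:
        """Time-integrated activity A0 * tau (MBq h)."""
        return self.A0 * self.tau

    def activity(self, t):
        """Evaluate the curve at time ``t`` (hours; scalar or array)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be >= 0")
        out = self.A0 * np.exp(-self.lambda_eff * t)
        return out if out.ndim else float(out)

    __call__ = activity

    def to_dict(self) -> dict:
        return {
            "A0_MBq": self.A0,
            "lambda_biol_per_h": self.lambda_biol,
            "lambda_phys_per_h": self.lambda_phys,
            "tau_h": self.tau,
            "tia_MBq_h": self.tia,
        }


@dataclass(frozen=True)
class Schedule:
    """An ordered set of acquisition time-points (hours)."""

    times: tuple

    def __init__(self, times):
        object.__setattr__(self, "times", tuple(float(t) for t in times))
        if len(self.times) < 2:
            raise ValueError("a schedule needs at least 2 time-points")
        if any((not math.isfinite(t)) or t < 0 for t in self.times):
            raise ValueError("all time-points must be finite and >= 0")
        if max(self.times) - min(self.times) <= 0:
            raise SingularDesignError(
                "schedule needs at least two distinct time-points (s2 would be 0)"
            )

    @property
    def n(self) -> int:
        return len(self.times)

    def moments(self) -> "ScheduleMoments":
        return schedule_moments(self)

    def with_point(self, t: float) -> "Schedule":
        """Return a new schedule with ``t`` appended."""
        return Schedule(self.times + (float(t),))

    def subset(self, indices) -> "Schedule":
        """Schedule retaining the given 0-based time-point indices."""
        return Schedule(tuple(self.times[i] for i in indices))

    def is_nested_in(self, other: "Schedule", tol: float = 1e-9) -> bool:
        """Multiset inclusion of time values within absolute tolerance ``tol`` h."""
        remaining = list(other.times)
        for t in self.times:
            for i, u in enumerate(remaining):
                if abs(t - u) <= tol:
                    del remaining[i]
                    break
            else:
                return False
        return True

    def to_dict(self) -> dict:
        return {"times_h": list(self.times)}


@dataclass(frozen=True)
class ScheduleMoments:
    """Mean, divisor-``n`` variance and count of a schedule's time-points."""

    mean_t: float
    var_t: float
    n: int

    def __post_init__(self):
        if self.var_t < 0:
            raise ValueError("var_t must be >= 0")

    @property
    def sd_t(self) -> float:
        return math.sqrt(self.var_t)


@dataclass(frozen=True)
class MeasurementModel:
    """Fixed coefficient of variation ``r`` of the estimated activities."""

    cv_activity: float

    def __post_init__(self):
        if not 0 < self.cv_activity < 1:
            raise ValueError(f"cv_activity must be in (0, 1), got {self.cv_activity}")
        if self.cv_activity > 0.3:
            warnings.warn(
                "cv_activity > 0.3: the linearization behind the closed forms "
                "becomes questionable at this noise level",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PopulationTauStats:
    """Mean and variance of the time constant tau across a population."""

    mean_tau: float
    var_tau: float

    def __post_init__(self):
        if not self.mean_tau > 0:
            raise ValueError("mean_tau must be > 0")
        if self.var_tau < 0:
            raise ValueError("var_tau must be >= 0")

    @property
    def cv_tau(self) -> float:
        return math.sqrt(self.var_tau) / self.mean_tau

    @classmethod
    def from_mean_cv(cls, mean_tau: float, cv_tau: float) -> "PopulationTauStats":
        return cls(mean_tau=mean_tau, var_tau=(cv_tau * mean_tau) ** 2)

    @classmethod
    def fixed(cls, tau: float) -> "PopulationTauStats":
        """Degenerate population: a single fixed curve."""
        return cls(mean_tau=tau, var_tau=0.0)

    @classmethod
    def from_samples(cls, taus) -> "PopulationTauStats":
        """Sample mean and sample variance (divisor n-1) of per-subject taus."""
        taus = np.asarray(taus, dtype=float)
        if taus.size < 2:
            raise ValueError("need at least 2 tau samples for a variance")
        return cls(mean_tau=float(taus.mean()), var_tau=float(taus.var(ddof=1)))

    def to_dict(self) -> dict:
        return {"mean_tau_h": self.mean_tau, "var_tau_h2": self.var_tau, "cv_tau": self.cv_tau}


@dataclass(frozen=True)
class ParamCovariance:
    """Covariance of the fitted ``(A0, lambda_biol)`` for one schedule."""

    matrix: np.ndarray
    cv_A0: float
    sd_lambda: float
    corr: float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2) or not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric 2x2")
        if np.linalg.eigvalsh(m).min() < -1e-10 * max(np.trace(m), 1.0):
            raise ValueError("matrix must be positive semi-definite")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class TiaJointCovariance:
    """Joint covariance of (TIA_full, TIA_reduced), units (MBq h)^2.

    The off-diagonal equals the full-schedule variance, hence the
    correlation equals ``sd_full / sd_reduced``.
    """

    matrix: np.ndarray
    cv_full: float
    cv_reduced: float
    corr: float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2) or not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric 2x2")
        object.__setattr__(self, "matrix", m)

    @property
    def sd_full(self) -> float:
        return math.sqrt(self.matrix[0, 0])

    @property
    def sd_reduced(self) -> float:
        return math.sqrt(self.matrix[1, 1])


@dataclass(frozen=True)
class ComparisonReport:
    """Predicted dispersions for a (full, reduced) schedule pair.

    ``var_epsilon_*`` is the variance of the relative TIA error against the
    true TIA; ``var_delta`` is the variance of the relative difference
    between the reduced- and full-schedule TIA estimates.
    """

    var_epsilon_full: float
    var_epsilon_reduced: float
    var_delta: float
    schedule_full: Schedule
    schedule_reduced: Schedule
    tau_stats: PopulationTauStats = None
    measurement_cv: float = None

    @property
    def sd_epsilon_full(self) -> float:
        return math.sqrt(self.var_epsilon_full)

    @property
    def sd_epsilon_reduced(self) -> float:
        return math.sqrt(self.var_epsilon_reduced)

    @property
    def sd_delta(self) -> float:
        return math.sqrt(max(self.var_delta, 0.0))

    def to_dict(self) -> dict:
        d = {
            "var_epsilon_full": self.var_epsilon_full,
            "var_epsilon_reduced": self.var_epsilon_reduced,
            "var_delta": self.var_delta,
            "sd_delta": self.sd_delta,
            "schedule_full_times_h": list(self.schedule_full.times),
            "schedule_reduced_times_h": list(self.schedule_reduced.times),
            "units": "dimensionless (relative) variances",
        }
        if self.tau_stats is not None:
            d["tau_stats"] = self.tau_stats.to_dict()
        if self.measurement_cv is not None:
            d["measurement_cv"] = self.measurement_cv
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def lambda_biol_from_half_lives(t_eff_half: float, t_phys_half: float) -> float:
    """Biological decay constant (1/h) from effective and physical half-lives.

    ``lambda_biol = ln2 / T_eff - ln2 / T_phys``.  Raises if the effective
    half-life exceeds the physical one (which would imply biological
    *accumulation*, i.e. a negative decay constant).
    """
    if not 0 < t_eff_half <= t_phys_half:
        raise ValueError(
            f"need 0 < t_eff_half <= t_phys_half, got {t_eff_half} and {t_phys_half}"
        )
    return LN2 / t_eff_half - LN2 / t_phys_half


def effective_half_life(lambda_biol: float, t_phys_half: float) -> float:
    """Inverse of :func:`lambda_biol_from_half_lives` (hours)."""
    if lambda_biol < 0 or t_phys_half <= 0:
        raise ValueError("lambda_biol must be >= 0 and t_phys_half > 0")
    return LN2 / (lambda_biol + LN2 / t_phys_half)


def tia_closed_form(tac: MonoExpTAC) -> float:
    """Time-integrated activity ``A0 / (lambda_biol + lambda_phys)`` (MBq h)."""
    return tac.tia


def schedule_moments(s: Schedule) -> ScheduleMoments:
    """Mean and divisor-``n`` (population-convention) variance of the times."""
    t = np.asarray(s.times, dtype=float)
    var = float(t.var(ddof=0))
    if var <= 0:
        raise SingularDesignError("all time-points identical: schedule variance is 0")
    return ScheduleMoments(mean_t=float(t.mean()), var_t=var, n=t.size)


def param_covariance_monoexp(tac: MonoExpTAC, m: ScheduleMoments, r) -> ParamCovariance:
    """First-order covariance of the fitted ``(A0, lambda_biol)``.

    With inverse-squared-activity weights the weighted normal matrix of the
    mono-exponential fit depends on the schedule only through ``(n, t_bar,
    s2)``, and its inverse scaled by ``r**2`` is the parameter covariance:

    * ``CV(A0)    = r * sqrt((1 + t_bar**2 / s2) / n)``
    * ``sd(lambda)= r * sqrt(1 / (n * s2))``
    * ``corr      = t_bar / sqrt(s2 + t_bar**2)``
    """
    cv = _as_cv(r)
    if m.var_t <= 0:
        raise SingularDesignError("schedule variance must be > 0")
    n, tbar, s2 = m.n, m.mean_t, m.var_t
    A0 = tac.A0
    var_A0 = cv**2 * A0**2 * (s2 + tbar**2) / (n * s2)
    cov = cv**2 * A0 * tbar / (n * s2)
    var_lam = cv**2 / (n * s2)
    mat = np.array([[var_A0, cov], [cov, var_lam]])
    return ParamCovariance(
        matrix=mat,
        cv_A0=cv * math.sqrt((1 + tbar**2 / s2) / n),
        sd_lambda=cv * math.sqrt(1.0 / (n * s2)),
        corr=tbar / math.sqrt(s2 + tbar**2),
    )


def var_relative_error(m: ScheduleMoments, pop: PopulationTauStats, r) -> float:
    """Variance of the relative TIA error for one schedule.

    ``V[eps] = r**2 / n * (1 + (t_bar - E[tau])**2 / s2 + V[tau] / s2)``.

    For a single fixed curve pass ``PopulationTauStats.fixed(tau)``.
    """
    cv = _as_cv(r)
    if m.var_t <= 0:
        raise SingularDesignError("schedule variance must be > 0")
    return (
        cv**2
        / m.n
        * (1.0 + ((m.mean_t - pop.mean_tau) ** 2 + pop.var_tau) / m.var_t)
    )


def var_relative_difference(
    full: ScheduleMoments, reduced: ScheduleMoments, pop: PopulationTauStats, r
) -> float:
    """Variance of the relative difference between reduced- and full-schedule TIAs.

    Valid for a reduced schedule *nested* in the full one (the caller
    enforces nesting at the :class:`Schedule` level); then the two estimates
    are positively correlated with covariance equal to the full-schedule
    variance, and

    ``V[delta] = r**2 * { (1/m)(1 + (t_bar'' - E[tau])**2 / s2'')
    - (1/n)(1 + (t_bar' - E[tau])**2 / s2')
    + V[tau]/(m s2'') - V[tau]/(n s2') }``

    with ``m = n - k`` the reduced count.  Non-negative for nested designs.
    """
    cv = _as_cv(r)
    if reduced.n < 2:
        raise SingularDesignError("reduced schedule needs at least 2 distinct points")
    if full.var_t <= 0 or reduced.var_t <= 0:
        raise SingularDesignError("schedule variances must be > 0")

    def _term(mom: ScheduleMoments) -> float:
        return (
            1.0 / mom.n * (1.0 + (mom.mean_t - pop.mean_tau) ** 2 / mom.var_t)
            + pop.var_tau / (mom.n * mom.var_t)
        )

    return cv**2 * (_term(reduced) - _term(full))


def tia_joint_covariance(
    tac: MonoExpTAC, full: ScheduleMoments, reduced: ScheduleMoments, r
) -> TiaJointCovariance:
    """Joint covariance of (TIA_full, TIA_reduced) for a single fixed curve.

    The off-diagonal equals the full-schedule variance: the full and
    reduced estimates are positively correlated with correlation
    ``sd_full / sd_reduced``.
    """
    cv = _as_cv(r)
    if full.var_t <= 0 or reduced.var_t <= 0:
        raise SingularDesignError("schedule variances must be > 0")
    tia2 = tac.tia**2
    pop = PopulationTauStats.fixed(tac.tau)
    v_full = tia2 * var_relative_error(full, pop, cv)
    v_red = tia2 * var_relative_error(reduced, pop, cv)
    mat = np.array([[v_full, v_full], [v_full, v_red]])
    return TiaJointCovariance(
        matrix=mat,
        cv_full=math.sqrt(v_full) / tac.tia,
        cv_reduced=math.sqrt(v_red) / tac.tia,
        corr=math.sqrt(v_full / v_red),
    )


def compare_schedules(
    full: Schedule, reduced: Schedule, pop: PopulationTauStats, r
) -> ComparisonReport:
    """Predicted error/difference dispersions for a nested schedule pair."""
    if not reduced.is_nested_in(full):
        raise ValueError(
            f"reduced schedule {reduced.times} is not nested in full {full.times}"
        )
    cv = _as_cv(r)
    mf, mr = full.moments(), reduced.moments()
    return ComparisonReport(
        var_epsilon_full=var_relative_error(mf, pop, cv),
        var_epsilon_reduced=var_relative_error(mr, pop, cv),
        var_delta=var_relative_difference(mf, mr, pop, cv),
        schedule_full=full,
        schedule_reduced=reduced,
        tau_stats=pop,
        measurement_cv=cv,
    )


def sd_ratio_prediction(
    full: Schedule, reduced_a: Schedule, reduced_b: Schedule, pop: PopulationTauStats
) -> float:
    """Predicted ratio ``sd(delta_a) / sd(delta_b)`` for two reduced schedules.

    Independent of the measurement CV ``r`` (it cancels in the ratio).
    """
    for red in (reduced_a, reduced_b):
        if not red.is_nested_in(full):
            raise ValueError(f"reduced schedule {red.times} not nested in full")
    mf = full.moments()
    va = var_relative_difference(mf, reduced_a.moments(), pop, 1.0)
    vb = var_relative_difference(mf, reduced_b.moments(), pop, 1.0)
    if vb <= 0:
        raise ZeroDivisionError("reference schedule pair has zero predicted variance")
    return math.sqrt(va / vb)
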