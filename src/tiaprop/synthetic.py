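"""Synthetic populations and cohorts with the assumed statistical structure.

A population is defined by independent lognormal distributions of the
initial activity ``A0`` and the biological decay constant ``lambda_biol``
across subjects, plus a fixed multiplicative lognormal measurement error
with arithmetic mean exactly 1 and CV ``r`` (so noisy activities are
conditionally unbiased).  The generator defaults reproduce the verification
study conditions: ``A0 = 100 MBq`` with 50% population CV, mean effective
half-life 50 h for 177Lu (``lambda_biol`` with 40% population CV), and
``r = 10%``.

The fixture registry (:func:`paper_fixture`) provides ready-made scenario
configurations, the four organ surrogate populations (kidneys, liver,
spleen) and the published theoretical/empirical standard-deviation-ratio
table used for ordinal-agreement checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from numpy.polynomial.hermite_e import hermegauss

from .core import (
    LN2,
    LU177_HALF_LIFE_H,
    MonoExpTAC,
    PopulationTauStats,
    Schedule,
    lambda_biol_from_half_lives,
)

__all__ = [
    "PopulationModel",
    "ScenarioConfig",
    "OrganSurrogate",
    "sample_lognormal",
    "generate_cohort",
    "paper_fixture",
    "fixture_names",
]


def sample_lognormal(mean, cv, size, rng):
    """Lognormal samples with the given *arithmetic* mean and CV.

    Uses ``sigma_ln**2 = ln(1 + cv**2)`` and ``mu_ln = ln(mean) -
    sigma_ln**2 / 2``; ``cv = 0`` returns the mean exactly.
    """
    mean = float(mean)
    cv = float(cv)
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.full(size, mean)
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class PopulationModel:
    """Independent lognormal population of ``(A0, lambda_biol)``.

    ``mean_lambda_biol`` may be 0 only with ``cv_lambda_biol = 0`` (pure
    physical decay for every subject).
    """

    mean_A0: float = 100.0
    cv_A0: float = 0.50
    mean_lambda_biol: float = lambda_biol_from_half_lives(50.0, LU177_HALF_LIFE_H)
    cv_lambda_biol: float = 0.40
    lambda_phys: float = LN2 / LU177_HALF_LIFE_H
    measurement_cv: float = 0.10

    def __post_init__(self):
        if self.mean_A0 <= 0 or self.lambda_phys <= 0:
            raise ValueError("mean_A0 and lambda_phys must be > 0")
        if self.mean_lambda_biol < 0 or (
            self.mean_lambda_biol == 0 and self.cv_lambda_biol != 0
        ):
            raise ValueError("mean_lambda_biol must be > 0 (or 0 with cv 0)")
        if self.cv_A0 < 0 or self.cv_lambda_biol < 0 or self.measurement_cv < 0:
            raise ValueError("CVs must be >= 0")

    @property
    def mean_tac(self) -> MonoExpTAC:
        return MonoExpTAC(self.mean_A0, self.mean_lambda_biol, self.lambda_phys)

    def sample_params(self, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``(A0, lambda_biol)`` for ``n`` subjects (independent)."""
        a0 = sample_lognormal(self.mean_A0, self.cv_A0, n, rng)
        lam = sample_lognormal(
            self.mean_lambda_biol, self.cv_lambda_biol, n, rng
        ) if self.mean_lambda_biol > 0 else np.zeros(n)
        return a0, lam

    def tau_stats(self, n_nodes: int = 64) -> PopulationTauStats:
        """Exact E[tau], V[tau] induced by the lognormal lambda_biol.

        Computed by Gauss-Hermite quadrature over ``ln(lambda_biol)``;
        deterministic (no sampling).
        """
        lam_p = self.lambda_phys
        if self.cv_lambda_biol == 0:
            return PopulationTauStats.fixed(1.0 / (self.mean_lambda_biol + lam_p))
        sigma2 = math.log1p(self.cv_lambda_biol**2)
        mu = math.log(self.mean_lambda_biol) - sigma2 / 2.0
        x, w = hermegauss(n_nodes)  # weights for standard normal * sqrt(2 pi)
        w = w / math.sqrt(2.0 * math.pi)
        lam = np.exp(mu + math.sqrt(sigma2) * x)
        tau = 1.0 / (lam + lam_p)
        m1 = float(w @ tau)
        m2 = float(w @ tau**2)
        return PopulationTauStats(mean_tau=m1, var_tau=max(m2 - m1**2, 0.0))

    @classmethod
    def from_tau_stats(
        cls,
        mean_tau: float,
        cv_tau: float,
        lambda_phys: float = LN2 / LU177_HALF_LIFE_H,
        mean_A0: float = 100.0,
        cv_A0: float = 0.50,
        measurement_cv: float = 0.10,
    ) -> "PopulationModel":
        """Population whose induced tau distribution has the given mean/CV.

        Inverts :meth:`tau_stats` numerically (root finding on the lognormal
        ``lambda_biol`` mean and CV).
        """
        lam0 = 1.0 / mean_tau - lambda_phys
        if lam0 <= 0:
            raise ValueError("mean_tau implies non-positive mean lambda_biol")
        if cv_tau == 0:
            return cls(mean_A0, cv_A0, lam0, 0.0, lambda_phys, measurement_cv)
        # delta-method initial guess: CV[tau] ~= CV[lam] * lam / (lam + lam_p)
        cv0 = cv_tau * (lam0 + lambda_phys) / lam0

        def resid(x):
            pop = cls(mean_A0, cv_A0, math.exp(x[0]), math.exp(x[1]),
                      lambda_phys, measurement_cv)
            ts = pop.tau_stats(n_nodes=96)
            return [ts.mean_tau / mean_tau - 1.0, ts.cv_tau / cv_tau - 1.0]

        sol = optimize.root(resid, [math.log(lam0), math.log(cv0)], tol=1e-12)
        if not sol.success:
            raise RuntimeError(f"tau-stat inversion failed: {sol.message}")
        return cls(mean_A0, cv_A0, math.exp(sol.x[0]), math.exp(sol.x[1]),
                   lambda_phys, measurement_cv)

    def to_dict(self) -> dict:
        return {
            "mean_A0_MBq": self.mean_A0,
            "cv_A0": self.cv_A0,
            "mean_lambda_biol_per_h": self.mean_lambda_biol,
            "cv_lambda_biol": self.cv_lambda_biol,
            "lambda_phys_per_h": self.lambda_phys,
            "measurement_cv": self.measurement_cv,
        }


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of one verification sweep.

    ``truth`` is a :class:`~tiaprop.core.MonoExpTAC` (fixed-curve scenario)
    or a :class:`PopulationModel` (population scenario).  The mobile grid
    places one extra time-point at each position in turn, on top of the
    fixed time-points.
    """

    fixed_times: tuple
    truth: object
    mobile_grid: tuple = tuple(float(t) for t in range(0, 171, 10))
    n_reps: int = 10_000
    measurement_cv: float = 0.10
    seed: int = 0
    exclude_flagged: bool = False

    def __post_init__(self):
        object.__setattr__(self, "fixed_times", tuple(float(t) for t in self.fixed_times))
        object.__setattr__(self, "mobile_grid", tuple(float(t) for t in self.mobile_grid))
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100")
        if len(self.mobile_grid) == 0:
            raise ValueError("mobile grid must be non-empty")

    def with_(self, **changes) -> "ScenarioConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        truth = (
            self.truth.to_dict() if hasattr(self.truth, "to_dict") else repr(self.truth)
        )
        return {
            "fixed_times_h": list(self.fixed_times),
            "mobile_grid_h": list(self.mobile_grid),
            "n_reps": self.n_reps,
            "measurement_cv": self.measurement_cv,
            "seed": self.seed,
            "exclude_flagged": self.exclude_flagged,
            "truth": truth,
        }


@dataclass(frozen=True)
class OrganSurrogate:
    """Printed per-organ tau statistics and the common acquisition times."""

    name: str
    tau_stats: PopulationTauStats
    schedule: Schedule

    def to_population_model(self, **kwargs) -> PopulationModel:
        return PopulationModel.from_tau_stats(
            self.tau_stats.mean_tau, self.tau_stats.cv_tau, **kwargs
        )


def generate_cohort(
    pop: PopulationModel, schedule: Schedule, n_subjects: int, seed
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an observable cohort table and a hidden truth sidecar.

    Per subject, draw ``(A0, lambda_biol)`` from the population, evaluate
    the true curve at the schedule times, and multiply each value by an
    independent lognormal noise factor with mean 1 and CV
    ``pop.measurement_cv``.

    Returns
    -------
    cohort : DataFrame with columns ``subject_id, organ, time_h, value``.
    truth : DataFrame with per-subject true ``A0, lambda_biol, tau, tia``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    a0, lam = pop.sample_params(n_subjects, rng)
    t = np.asarray(schedule.times)
    lam_eff = lam + pop.lambda_phys
    clean = a0[:, None] * np.exp(-lam_eff[:, None] * t[None, :])
    noise = (
        sample_lognormal(1.0, pop.measurement_cv, clean.shape, rng)
        if pop.measurement_cv > 0
        else np.ones_like(clean)
    )
    values = clean * noise
    n, m = n_subjects, t.size
    cohort = pd.DataFrame(
        {
            "subject_id": np.repeat([f"s{i:05d}" for i in range(n)], m),
            "organ": "synthetic",
            "time_h": np.tile(t, n),
            "value": values.ravel(),
        }
    )
    truth = pd.DataFrame(
        {
            "subject_id": [f"s{i:05d}" for i in range(n)],
            "A0": a0,
            "lambda_biol": lam,
            "tau": 1.0 / lam_eff,
            "tia": a0 / lam_eff,
        }
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------

_ORGAN_STATS = {
    # organ: (mean tau [h], CV of tau)
    "left_kidney": (81.0, 0.13),
    "right_kidney": (78.0, 0.20),
    "liver": (111.0, 0.21),
    "spleen": (110.0, 0.22),
}

_ORGAN_TIMES = Schedule((21.0, 93.0, 165.0))

# Published ratio table (theoretical predictions vs patient data) used for
# ordinal-agreement checks; columns are sd(delta) ratios with subscripts
# naming the retained time-points of the 3-point reference schedule.
_RATIO_TABLE = pd.DataFrame(
    {
        "organ": ["left_kidney", "right_kidney", "liver", "spleen"],
        "theo_sd12_over_sd13": [1.53, 1.52, 2.90, 2.86],
        "theo_sd23_over_sd13": [2.58, 2.72, 1.60, 1.66],
        "exp_sd12_over_sd13": [0.86, 0.91, 1.94, 3.01],
        "exp_sd23_over_sd13": [2.17, 2.17, 0.91, 1.46],
    }
).set_index("organ")

_SCENARIO2_FIXED = {
    "24_96_168": (24.0, 96.0, 168.0),
    "24_168": (24.0, 168.0),
    "24_96": (24.0, 96.0),
    "96_168": (96.0, 168.0),
}


def _registry() -> dict:
    reg = {}
    truth1 = MonoExpTAC.from_half_lives(100.0, 50.0, LU177_HALF_LIFE_H)
    reg["scenario1"] = lambda: ScenarioConfig(fixed_times=(24.0, 96.0), truth=truth1)
    for key, fixed in _SCENARIO2_FIXED.items():
        reg[f"scenario2:{key}"] = (
            lambda fixed=fixed: ScenarioConfig(fixed_times=fixed, truth=PopulationModel())
        )
    for organ, (mean_tau, cv_tau) in _ORGAN_STATS.items():
        reg[f"organ:{organ}"] = (
            lambda mt=mean_tau, cv=cv_tau, nm=organ: OrganSurrogate(
                name=nm,
                tau_stats=PopulationTauStats.from_mean_cv(mt, cv),
                schedule=_ORGAN_TIMES,
            )
        )
    reg["table3"] = lambda: _RATIO_TABLE.copy()
    return reg


def fixture_names() -> list[str]:
    return sorted(_registry())


def paper_fixture(name: str):
    """Return a registered study fixture by name.

    Known names: ``scenario1``, ``scenario2:<fixed set>`` (fixed sets
    ``24_96_168``, ``24_168``, ``24_96``, ``96_168``), ``organ:<organ>``
    (left_kidney, right_kidney, liver, spleen) and ``table3``.
    """
    reg = _registry()
    if name not in reg:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(reg)}")
    return reg[name]()
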