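"""Cohort-level comparison of reduced imaging schedules.

Given per-subject time-activity(-concentration) tables, this module
reproduces the schedule-comparison procedure used on patient data: fit a
mono-exponential per subject to the full (reference) schedule, derive the
population statistics of the time constant tau from those reference fits,
compute per subject the relative TIA difference ``delta`` for every
two-point reduced schedule, take standard deviations over subjects, and
compare the resulting sd ratios with the theoretical predictions.  The
measurement CV ``r`` is unknown for real data but cancels in the ratios.

Subscript convention: ``sd12`` is the sd over subjects of ``delta`` for
the reduced schedule retaining time-points 1 and 2 (1-based) of the
3-point reference, and ratios are formed against a designated reference
pair (``sd13`` in the published tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PopulationTauStats, Schedule, sd_ratio_prediction
from .fitting import fit_monoexp_ensemble

__all__ = [
    "CohortTable",
    "OrganComparison",
    "CohortComparison",
    "CohortComparisonResults",
    "derive_population_tau",
    "empirical_sd_ratios",
    "ordinal_agreement",
]

logger = logging.getLogger(__name__)

_HOURS_PER_UNIT = {"h": 1.0, "d": 24.0}


@dataclass(frozen=True)
class CohortTable:
    """Validated cohort records ``(subject_id, organ, time_h, value)``.

    An optional ``unit`` column (``h`` or ``d``) on input is converted to
    hours.  Subjects with fewer than 3 time-points are excluded (with a
    logged warning) since they cannot support a reference fit; times must
    be strictly increasing within each subject-organ series.
    """

    data: pd.DataFrame

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        missing = {"subject_id", "organ", "time_h", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
        if "unit" in df.columns:
            factors = df["unit"].map(_HOURS_PER_UNIT)
            if factors.isna().any():
                bad = sorted(df.loc[factors.isna(), "unit"].unique())
                raise ValueError(f"unknown time units: {bad} (accepted: h, d)")
            df["time_h"] = df["time_h"] * factors
            df = df.drop(columns="unit")
        if (df["value"] <= 0).any():
            raise ValueError("values must be > 0")
        df = df.sort_values(["organ", "subject_id", "time_h"], kind="mergesort")
        for (organ, subj), grp in df.groupby(["organ", "subject_id"], sort=False):
            if not grp["time_h"].is_unique:
                raise ValueError(f"duplicate time-points for {subj}/{organ}")
        counts = df.groupby(["organ", "subject_id"]).size()
        short = counts[counts < 3]
        if len(short):
            logger.warning(
                "excluding %d subject-organ series with < 3 time-points", len(short)
            )
            keep = counts[counts >= 3].index
            df = df.set_index(["organ", "subject_id"]).loc[keep].reset_index()
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def organs(self) -> list:
        return sorted(self.data["organ"].unique())

    def organ_matrix(self, organ: str):
        """Times and value matrix for one organ (subjects sharing a schedule).

        Returns ``(subject_ids, times, values)`` with ``values`` of shape
        ``(n_subjects, n_times)``.  Requires every subject in the organ to
        have the same number of time-points (series are aligned by rank;
        exact acquisition times may differ slightly per subject, so the
        *mean* time per rank is returned).
        """
        sub = self.data[self.data["organ"] == organ]
        if sub.empty:
            raise KeyError(f"no records for organ {organ!r}")
        counts = sub.groupby("subject_id").size()
        if counts.nunique() != 1:
            raise ValueError(
                f"organ {organ!r}: subjects have differing numbers of time-points"
            )
        m = counts.iloc[0]
        ids = counts.index.to_numpy()
        piv_t = sub.pivot_table(index="subject_id", columns=sub.groupby("subject_id").cumcount(), values="time_h")
        piv_v = sub.pivot_table(index="subject_id", columns=sub.groupby("subject_id").cumcount(), values="value")
        times = piv_t.mean(axis=0).to_numpy()
        return ids, times, piv_v.loc[ids].to_numpy()


def derive_population_tau(
    cohort: CohortTable, organ: str, lambda_phys: float
) -> tuple[PopulationTauStats, np.ndarray]:
    """Population tau statistics from per-subject reference fits.

    Fits every subject's full series, computes the per-subject time
    constants, and returns their sample mean and sample (divisor n-1)
    variance together with the mean acquisition time per rank.
    """
    ids, times, values = cohort.organ_matrix(organ)
    if len(ids) < 2:
        raise ValueError(
            f"organ {organ!r}: need at least 2 subjects for population statistics"
        )
    fit = fit_monoexp_ensemble(times, values, lambda_phys)
    taus = 1.0 / (fit["lambda_biol"] + lambda_phys)
    return PopulationTauStats.from_samples(taus), times


@dataclass(frozen=True)
class OrganComparison:
    """Empirical and theoretical sd ratios for one organ.

    ``pairs`` are 1-based index pairs of retained time-points; ratios are
    against ``reference_pair``.  Empirical sds over subjects use divisor
    ``n_subjects - 1``.
    """

    organ: str
    pairs: tuple
    reference_pair: tuple
    empirical_sd: dict
    empirical_ratio: dict
    theoretical_ratio: dict
    tau_stats: PopulationTauStats
    mean_times: np.ndarray
    n_subjects: int

    def ratio_frame(self) -> pd.DataFrame:
        ref = "".join(map(str, self.reference_pair))
        rows = {}
        for pair in self.pairs:
            key = "".join(map(str, pair))
            rows[f"theo_sd{key}_over_sd{ref}"] = self.theoretical_ratio[pair]
            rows[f"exp_sd{key}_over_sd{ref}"] = self.empirical_ratio[pair]
        return pd.DataFrame(rows, index=[self.organ])


def empirical_sd_ratios(
    cohort: CohortTable,
    organ: str,
    lambda_phys: float,
    pairs=((1, 2), (2, 3)),
    reference_pair=(1, 3),
) -> OrganComparison:
    """Empirical and predicted sd(delta) ratios for two-point schedules.

    Per subject, ``delta = TIA_reduced / TIA_full - 1`` for each retained
    pair; the sd is taken over subjects and divided by the sd of the
    reference pair.  Theoretical ratios evaluate the closed-form
    ``V[delta]`` at the organ's derived tau statistics and mean
    acquisition times.
    """
    ids, times, values = cohort.organ_matrix(organ)
    tau_stats, _ = derive_population_tau(cohort, organ, lambda_phys)
    fit_full = fit_monoexp_ensemble(times, values, lambda_phys)

    all_pairs = tuple(tuple(p) for p in pairs) + (tuple(reference_pair),)
    sds = {}
    for pair in dict.fromkeys(all_pairs):
        idx = [i - 1 for i in pair]
        fit_red = fit_monoexp_ensemble(times[idx], values[:, idx], lambda_phys)
        delta = fit_red["tia"] / fit_full["tia"] - 1.0
        sds[pair] = float(np.std(delta, ddof=1))
    ref = tuple(reference_pair)
    if sds[ref] == 0:
        raise ZeroDivisionError("reference pair has zero empirical sd")

    full_sched = Schedule(times)
    theo = {}
    emp = {}
    for pair in (tuple(p) for p in pairs):
        idx = [i - 1 for i in pair]
        theo[pair] = sd_ratio_prediction(
            full_sched,
            Schedule(times[idx]),
            Schedule([times[i - 1] for i in ref]),
            tau_stats,
        )
        emp[pair] = sds[pair] / sds[ref]
    return OrganComparison(
        organ=organ,
        pairs=tuple(tuple(p) for p in pairs),
        reference_pair=ref,
        empirical_sd=sds,
        empirical_ratio=emp,
        theoretical_ratio=theo,
        tau_stats=tau_stats,
        mean_times=times,
        n_subjects=len(ids),
    )


def ordinal_agreement(theory: pd.DataFrame, empirical: pd.DataFrame) -> dict:
    """Count ordinal agreements between theoretical and empirical ratios.

    Both tables are indexed by organ with columns ``sd12_over_sd13`` and
    ``sd23_over_sd13`` (any common prefix is stripped).  Per organ three
    ordinal relations are evaluated: sd12 vs sd23, sd12/sd13 vs 1, and
    sd23/sd13 vs 1; an agreement is a matching direction of the
    inequality.  Returns the agreement count, the total (3 x organs), and
    a per-case table.
    """

    def _clean(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        renames = {}
        for c in out.columns:
            if "sd12_over_sd13" in c:
                renames[c] = "sd12_over_sd13"
            elif "sd23_over_sd13" in c:
                renames[c] = "sd23_over_sd13"
        return out.rename(columns=renames)

    th, em = _clean(theory), _clean(empirical)
    needed = {"sd12_over_sd13", "sd23_over_sd13"}
    for name, df in (("theory", th), ("empirical", em)):
        if not needed <= set(df.columns):
            raise ValueError(f"{name} table is missing ratio columns {needed}")
    organs = list(th.index)
    if set(organs) != set(em.index):
        raise ValueError("theory and empirical tables cover different organs")

    cases = []
    for organ in organs:
        t12, t23 = th.loc[organ, "sd12_over_sd13"], th.loc[organ, "sd23_over_sd13"]
        e12, e23 = em.loc[organ, "sd12_over_sd13"], em.loc[organ, "sd23_over_sd13"]
        if any(pd.isna(x) for x in (t12, t23, e12, e23)):
            raise ValueError(f"missing ratio cells for organ {organ!r}")
        relations = [
            ("sd12_vs_sd23", np.sign(t12 - t23), np.sign(e12 - e23)),
            ("sd12_vs_sd13", np.sign(t12 - 1.0), np.sign(e12 - 1.0)),
            ("sd23_vs_sd13", np.sign(t23 - 1.0), np.sign(e23 - 1.0)),
        ]
        for name, st, se in relations:
            cases.append(
                {
                    "organ": organ,
                    "relation": name,
                    "theory_sign": st,
                    "empirical_sign": se,
                    "agree": st == se,
                }
            )
    table = pd.DataFrame(cases)
    return {
        "agreements": int(table["agree"].sum()),
        "total": len(table),
        "cases": table,
    }


class CohortComparison:
    """Model object: a cohort plus the schedule-comparison configuration."""

    def __init__(
        self,
        cohort: CohortTable,
        lambda_phys: float,
        pairs=((1, 2), (2, 3)),
        reference_pair=(1, 3),
    ):
        self.cohort = cohort
        self.lambda_phys = float(lambda_phys)
        self.pairs = tuple(tuple(p) for p in pairs)
        self.reference_pair = tuple(reference_pair)

    @classmethod
    def from_csv(cls, path, lambda_phys: float, **kwargs) -> "CohortComparison":
        return cls(CohortTable.from_csv(path), lambda_phys, **kwargs)

    def fit(self) -> "CohortComparisonResults":
        comps = [
            empirical_sd_ratios(
                self.cohort, organ, self.lambda_phys, self.pairs, self.reference_pair
            )
            for organ in self.cohort.organs
        ]
        return CohortComparisonResults(self, comps)


class CohortComparisonResults:
    """Per-organ ratio tables plus the ordinal agreement count."""

    def __init__(self, model: CohortComparison, comparisons):
        self.model = model
        self.comparisons = {c.organ: c for c in comparisons}
        self.table = pd.concat([c.ratio_frame() for c in comparisons])
        theo = self.table[[c for c in self.table.columns if c.startswith("theo_")]]
        emp = self.table[[c for c in self.table.columns if c.startswith("exp_")]]
        self.agreement = ordinal_agreement(theo, emp)

    def summary(self) -> str:
        lines = [
            "Schedule comparison over cohort",
            "-" * 60,
            self.table.round(3).to_string(),
            "",
            f"ordinal agreement: {self.agreement['agreements']} of "
            f"{self.agreement['total']} cases",
        ]
        return "\n".join(lines)
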