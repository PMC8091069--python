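"""End-to-end study orchestration: from worker tables to the cost report.

A study processes worker-level inputs (roster, absence records,
questionnaire responses, salary table, normative thresholds) into one row
per homogenous group — absence days by type, questionnaire response rate,
group day cost ch_i, absence cost, work-related-stress attributable
fraction, and the stress cost ch_i x days x PAF — plus a totals block with
sums, the simple average of group PAFs, respondent-weighted averages and
the dispersion of group stress costs.

Groups whose questionnaire response rate falls below the configured minimum
(default 75%) are excluded from all aggregates but still appear in the
report flagged as excluded.  The group PAF estimated from respondents is
applied to the group's total recorded absence cost.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from stresscost import msit_exposure
from stresscost.attributable_fraction import tally_group, wrs_attributable_fraction
from stresscost.msit_exposure import ExposureThresholds, ItemMap, classify_exposure
from stresscost.workday_cost import (
    GroupComposition,
    JobSalaryEntry,
    group_absence_cost,
    group_day_cost,
)

logger = logging.getLogger(__name__)

ABSENCE_TYPES = ("days_injury", "days_sickness", "days_other")


class StudyInputError(ValueError):
    """Raised for malformed or inconsistent study inputs."""


@dataclass(frozen=True)
class GroupAbsenceSummary:
    """Absence days by type for one homogenous group."""

    group_id: str
    days_injury: float
    days_sickness: float
    days_other: float

    def __post_init__(self) -> None:
        if min(self.days_injury, self.days_sickness, self.days_other) < 0:
            raise StudyInputError(f"group {self.group_id}: negative absence days")

    @property
    def total_days(self) -> float:
        return self.days_injury + self.days_sickness + self.days_other


@dataclass(frozen=True)
class GroupResult:
    """One homogenous group's row of the study report."""

    group_id: str
    absence: GroupAbsenceSummary
    response_rate: float
    day_cost: float
    absence_cost: float
    paf: float
    stress_cost: float
    included: bool
    n_members: int = 0
    n_respondents: int = 0
    n_exposed: int = 0
    n_unexposed: int = 0


@dataclass(frozen=True)
class StudyResult:
    """All group rows plus the totals block of the study report.

    Totals, averages and dispersion cover included groups only.  The
    weighted averages use valid-respondent counts as weights and are
    ``None`` when those counts are unavailable (e.g. when aggregating
    published per-group rows); they are model-defined quantities.
    """

    groups: tuple[GroupResult, ...]
    total_days: float
    total_absence_cost: float
    total_stress_cost: float
    mean_paf: float
    mean_response_rate: float
    weighted_mean_paf: Optional[float]
    weighted_mean_cost: Optional[float]
    stress_cost_sd: float
    paf_sd: float

    @property
    def included_groups(self) -> tuple[GroupResult, ...]:
        return tuple(g for g in self.groups if g.included)


@dataclass
class StudyConfig:
    """Tunable study parameters.

    min_response_rate:
        Inclusion threshold on the fraction of a group's workers returning
        a valid questionnaire (default 0.75).
    binary_percentile:
        Normative percentile of the exposure cutoff (default 25, the first
        quartile) — used only when thresholds are derived inside the run.
    score_method:
        Overall-score combination rule: ``dimension_mean`` (default) or
        ``item_mean``.
    min_fraction_present:
        Minimum fraction of a dimension's items that must be answered for
        the dimension score to count (default 0.5).
    tally_scope:
        How non-respondents enter the PAF tally (``respondents_only``
        default, or ``all_workers``).
    """

    min_response_rate: float = 0.75
    binary_percentile: float = 25.0
    score_method: str = "dimension_mean"
    min_fraction_present: float = 0.5
    tally_scope: str = "respondents_only"
    item_map: Optional[ItemMap] = None


@dataclass
class StudyDataset:
    """In-memory worker-level study inputs.

    roster:
        columns worker_id, group_id, job_category — one row per worker.
    absences:
        columns worker_id, days_injury, days_sickness, days_other;
        workers absent from this table have zero absence days.
    questionnaire:
        columns worker_id, item_01 .. item_35 (blank = missing answer);
        one row per returned questionnaire.
    """

    roster: pd.DataFrame
    absences: pd.DataFrame
    questionnaire: pd.DataFrame

    def __post_init__(self) -> None:
        for name, frame, required in (
            ("roster", self.roster, ("worker_id", "group_id", "job_category")),
            ("absences", self.absences, ("worker_id",) + ABSENCE_TYPES),
            ("questionnaire", self.questionnaire, ("worker_id",)),
        ):
            missing = [c for c in required if c not in frame.columns]
            if missing:
                raise StudyInputError(f"{name} table lacks columns: {missing}")
        if self.roster["worker_id"].duplicated().any():
            dups = self.roster.loc[self.roster["worker_id"].duplicated(), "worker_id"]
            raise StudyInputError(f"duplicate worker ids in roster: {sorted(set(dups))[:5]}")
        roster_ids = set(self.roster["worker_id"].astype(str))
        for name, frame in (("absences", self.absences), ("questionnaire", self.questionnaire)):
            stray = set(frame["worker_id"].astype(str)) - roster_ids
            if stray:
                raise StudyInputError(
                    f"{name} table references workers missing from roster: {sorted(stray)[:5]}"
                )

    @classmethod
    def from_csv(
        cls, roster: str | Path, absences: str | Path, questionnaire: str | Path
    ) -> "StudyDataset":
        return cls(
            roster=pd.read_csv(roster, dtype={"worker_id": str}),
            absences=pd.read_csv(absences, dtype={"worker_id": str}),
            questionnaire=pd.read_csv(questionnaire, dtype={"worker_id": str}),
        )


def response_rate(members: int, respondents: int) -> float:
    """Fraction of a group's workers returning a valid questionnaire."""
    if members <= 0:
        raise StudyInputError(f"group has no members (members={members})")
    if respondents < 0 or respondents > members:
        raise StudyInputError(
            f"respondents ({respondents}) outside [0, members={members}]"
        )
    return respondents / members


def estimate_group_cost(summary: GroupAbsenceSummary, ch_i: float, paf: float) -> float:
    """Stress cost of one group: total absence days x day cost x PAF."""
    if ch_i < 0:
        raise StudyInputError(f"group {summary.group_id}: negative day cost")
    if not 0.0 <= paf <= 1.0:
        raise StudyInputError(f"group {summary.group_id}: PAF {paf} outside [0, 1]")
    return summary.total_days * ch_i * paf


def weighted_average(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted mean sum(v*w)/sum(w); weights must not all be zero."""
    if len(values) != len(weights):
        raise StudyInputError("values and weights differ in length")
    if any(w < 0 for w in weights):
        raise StudyInputError("weights must be non-negative")
    total = float(sum(weights))
    if total == 0:
        raise StudyInputError("all weights are zero")
    return float(sum(v * w for v, w in zip(values, weights)) / total)


def summarize_groups(
    groups: Sequence[GroupResult], *, respondent_weights: bool = True
) -> StudyResult:
    """Aggregate group rows into study totals and averages.

    Totals sum over included groups; the headline average PAF is the
    unweighted mean of the included groups' PAFs.  When
    ``respondent_weights`` is set and respondent counts are available,
    respondent-weighted means of PAF and stress cost are also reported.
    """
    included = [g for g in groups if g.included]
    if not included:
        raise StudyInputError("no group meets the inclusion threshold")
    pafs = [g.paf for g in included]
    costs = [g.stress_cost for g in included]
    weights = [g.n_respondents for g in included]
    have_weights = respondent_weights and sum(weights) > 0
    return StudyResult(
        groups=tuple(groups),
        total_days=float(sum(g.absence.total_days for g in included)),
        total_absence_cost=float(sum(g.absence_cost for g in included)),
        total_stress_cost=float(sum(costs)),
        mean_paf=float(np.mean(pafs)),
        mean_response_rate=float(np.mean([g.response_rate for g in included])),
        weighted_mean_paf=weighted_average(pafs, weights) if have_weights else None,
        weighted_mean_cost=weighted_average(costs, weights) if have_weights else None,
        stress_cost_sd=float(np.std(costs, ddof=1)) if len(costs) > 1 else 0.0,
        paf_sd=float(np.std(pafs, ddof=1)) if len(pafs) > 1 else 0.0,
    )


def run_study(
    dataset: StudyDataset,
    salary_table: Mapping[str, JobSalaryEntry],
    thresholds: ExposureThresholds,
    config: Optional[StudyConfig] = None,
) -> StudyResult:
    """Run the full cost-estimation pipeline on a worker-level dataset.

    Per group: compute the questionnaire response rate and mark the group
    excluded when it falls below the configured minimum; score respondents
    and classify them against the normative thresholds; tally absence days
    by exposure status into the group PAF; price the group's total absence
    days at the headcount-weighted day cost; stress cost = absence cost x
    PAF.  Aggregates cover included groups only.
    """
    config = config or StudyConfig()
    if dataset.roster.empty:
        raise StudyInputError("empty study: roster has no workers")

    overall = msit_exposure.score_questionnaire_frame(
        dataset.questionnaire,
        config.item_map,
        method=config.score_method,
        min_fraction_present=config.min_fraction_present,
    )

    absences = dataset.absences.copy()
    absences["worker_id"] = absences["worker_id"].astype(str)
    absences = absences.set_index("worker_id")
    for col in ABSENCE_TYPES:
        if (absences[col] < 0).any():
            bad = absences.index[absences[col] < 0][0]
            raise StudyInputError(f"negative {col} for worker {bad!r}")

    job_costs = {cat: entry.day_cost for cat, entry in salary_table.items()}

    results: list[GroupResult] = []
    roster = dataset.roster.copy()
    roster["worker_id"] = roster["worker_id"].astype(str)
    for group_id, members in roster.groupby("group_id", sort=True):
        gid = str(group_id)
        worker_ids = list(members["worker_id"])

        # Absence totals over all group members, by type
        present = [w for w in worker_ids if w in absences.index]
        sums = (
            absences.loc[present, list(ABSENCE_TYPES)].sum()
            if present
            else pd.Series(0.0, index=list(ABSENCE_TYPES))
        )
        summary = GroupAbsenceSummary(
            group_id=gid,
            days_injury=float(sums["days_injury"]),
            days_sickness=float(sums["days_sickness"]),
            days_other=float(sums["days_other"]),
        )

        # Exposure labels for every member (missing/invalid questionnaire -> unknown)
        labels = [
            classify_exposure(overall.get(w), thresholds, worker_id=w) for w in worker_ids
        ]
        n_respondents = sum(1 for lab in labels if lab.status != "unknown")
        rate = response_rate(len(worker_ids), n_respondents)
        included = rate >= config.min_response_rate
        if not included:
            logger.warning(
                "group %s excluded: response rate %.1f%% below %.0f%%",
                gid, 100 * rate, 100 * config.min_response_rate,
            )

        worker_days = {
            w: float(absences.loc[w, list(ABSENCE_TYPES)].sum()) if w in absences.index else 0.0
            for w in worker_ids
        }
        counts = tally_group(gid, worker_days, labels, scope=config.tally_scope)
        paf = wrs_attributable_fraction(counts).paf

        composition = GroupComposition(
            group_id=gid,
            job_headcounts=members["job_category"].astype(str).value_counts().to_dict(),
        )
        ch = group_day_cost(composition, job_costs).ch_i
        absence_cost = group_absence_cost(summary.total_days, ch)

        results.append(
            GroupResult(
                group_id=gid,
                absence=summary,
                response_rate=rate,
                day_cost=ch,
                absence_cost=absence_cost,
                paf=paf,
                stress_cost=estimate_group_cost(summary, ch, paf),
                included=included,
                n_members=len(worker_ids),
                n_respondents=n_respondents,
                n_exposed=counts.n_exposed,
                n_unexposed=counts.n_unexposed,
            )
        )

    return summarize_groups(results)


def report_frame(study: StudyResult) -> pd.DataFrame:
    """Render the study as the standard report table.

    One row per group (absence days by type, total, response rate %,
    absence cost, PAF %, stress cost) plus a Total/Average row.  PAF and
    response rate are rounded to 0.1 percentage point and currency to whole
    units — rounding happens only here, never inside the computation.
    """
    rows = []
    for g in study.groups:
        rows.append(
            {
                "group": g.group_id,
                "days_injury": g.absence.days_injury,
                "days_sickness": g.absence.days_sickness,
                "days_other": g.absence.days_other,
                "total_days": g.absence.total_days,
                "response_rate_pct": round(100 * g.response_rate, 1),
                "absence_cost": round(g.absence_cost),
                "paf_pct": round(100 * g.paf, 1),
                "stress_cost": round(g.stress_cost),
                "included": g.included,
            }
        )
    inc = study.included_groups
    rows.append(
        {
            "group": "Total/Average",
            "days_injury": sum(g.absence.days_injury for g in inc),
            "days_sickness": sum(g.absence.days_sickness for g in inc),
            "days_other": sum(g.absence.days_other for g in inc),
            "total_days": study.total_days,
            "response_rate_pct": round(100 * study.mean_response_rate, 1),
            "absence_cost": round(study.total_absence_cost),
            "paf_pct": round(100 * study.mean_paf, 1),
            "stress_cost": round(study.total_stress_cost),
            "included": True,
        }
    )
    return pd.DataFrame(rows)


def summary_dict(study: StudyResult) -> dict[str, float]:
    """Machine-readable study summary for downstream use."""
    out = {
        "n_groups": len(study.groups),
        "n_groups_included": len(study.included_groups),
        "total_days": study.total_days,
        "total_absence_cost": study.total_absence_cost,
        "total_stress_cost": study.total_stress_cost,
        "mean_paf_pct": 100 * study.mean_paf,
        "stress_cost_sd": study.stress_cost_sd,
        "paf_sd_pct": 100 * study.paf_sd,
    }
    if study.weighted_mean_paf is not None:
        out["weighted_mean_paf_pct"] = 100 * study.weighted_mean_paf
    if study.weighted_mean_cost is not None:
        out["weighted_mean_cost"] = study.weighted_mean_cost
    return out


def write_report(study: StudyResult, path: str | Path) -> None:
    """Write the report table to CSV."""
    report_frame(study).to_csv(path, index=False)
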