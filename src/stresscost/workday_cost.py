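"""Human-capital working-day costs per job category and homogenous group.

The model prices one day of absence at the salary-derived cost of a working
day.  Per job category j, the yearly cost per worker (total staff cost
divided by headcount, or supplied directly, or monthly salary times the
number of yearly payments) is divided by the number of monthly payments and
then by the average working days in a month (working days per year / 12):

    cw_j = (yearly_cost / payments) / (working_days / 12)

The Italian convention is 14 monthly payments and 253 working days a year;
both are configurable so the model ports to other countries.  A homogenous
group's day cost ch_i is the headcount-weighted mean of its categories'
day costs, and the cost of the group's absence is ch_i times its total
absence days.  All values are carried at full floating precision; rounding
happens only at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

DEFAULT_MONTHLY_PAYMENTS = 14
DEFAULT_WORKING_DAYS_PER_YEAR = 253


class CostInputError(ValueError):
    """Raised for invalid or incomplete salary-cost inputs."""


def yearly_cost_per_worker(staff_cost: float, headcount: int) -> float:
    """Average yearly cost of one worker: total staff cost / headcount."""
    if headcount <= 0:
        raise CostInputError(f"headcount must be positive, got {headcount}")
    if staff_cost < 0:
        raise CostInputError(f"staff cost must be non-negative, got {staff_cost}")
    return staff_cost / headcount


def day_cost(
    yearly_cost: float,
    monthly_payments: int = DEFAULT_MONTHLY_PAYMENTS,
    working_days_per_year: int = DEFAULT_WORKING_DAYS_PER_YEAR,
) -> float:
    """Cost of one working day from the yearly cost per worker.

    Monthly cost = yearly / payments; day cost = monthly / (working days
    in a month), where a month averages working_days_per_year / 12 days.
    """
    if yearly_cost < 0:
        raise CostInputError(f"yearly cost must be non-negative, got {yearly_cost}")
    if monthly_payments <= 0 or working_days_per_year <= 0:
        raise CostInputError(
            f"payments ({monthly_payments}) and working days ({working_days_per_year}) "
            "must be positive"
        )
    monthly = yearly_cost / monthly_payments
    return monthly / (working_days_per_year / 12)


@dataclass
class JobSalaryEntry:
    """Salary-cost inputs for one job category, with the derived day cost.

    Exactly one costing route must be supplied:

    * ``staff_cost`` + ``headcount`` (yearly cost per worker derived), or
    * ``yearly_cost_per_worker`` directly, or
    * ``monthly_salary`` (yearly = monthly x payments).
    """

    job_category: str
    staff_cost: Optional[float] = None
    headcount: Optional[int] = None
    yearly_cost_per_worker: Optional[float] = None
    monthly_salary: Optional[float] = None
    monthly_payments: int = DEFAULT_MONTHLY_PAYMENTS
    working_days_per_year: int = DEFAULT_WORKING_DAYS_PER_YEAR
    day_cost: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        routes = [
            self.staff_cost is not None or self.headcount is not None,
            self.yearly_cost_per_worker is not None,
            self.monthly_salary is not None,
        ]
        if sum(routes) != 1:
            raise CostInputError(
                f"{self.job_category}: exactly one costing route required "
                "(staff_cost+headcount, yearly_cost_per_worker, or monthly_salary)"
            )
        if routes[0] and (self.staff_cost is None or self.headcount is None):
            raise CostInputError(
                f"{self.job_category}: staff_cost and headcount must be given together"
            )
        yearly = self._resolve_yearly()
        self.day_cost = day_cost(yearly, self.monthly_payments, self.working_days_per_year)
        if not self.day_cost > 0:
            raise CostInputError(f"{self.job_category}: derived day cost is not positive")

    def _resolve_yearly(self) -> float:
        if self.yearly_cost_per_worker is not None:
            return float(self.yearly_cost_per_worker)
        if self.monthly_salary is not None:
            return float(self.monthly_salary) * self.monthly_payments
        try:
            return yearly_cost_per_worker(float(self.staff_cost), int(self.headcount))  # type: ignore[arg-type]
        except CostInputError as exc:
            raise CostInputError(f"{self.job_category}: {exc}") from exc


@dataclass(frozen=True)
class GroupComposition:
    """Headcount per job category within one homogenous group."""

    group_id: str
    job_headcounts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.job_headcounts.values()):
            raise CostInputError(f"group {self.group_id}: negative headcount")
        if self.total_workers <= 0:
            raise CostInputError(f"group {self.group_id}: no workers")

    @property
    def total_workers(self) -> int:
        return int(sum(self.job_headcounts.values()))


@dataclass(frozen=True)
class GroupDayCost:
    """Average cost of a working day for one homogenous group (ch_i)."""

    group_id: str
    ch_i: float


def group_day_cost(
    composition: GroupComposition, job_costs: Mapping[str, float]
) -> GroupDayCost:
    """Headcount-weighted mean day cost over a group's job categories.

    ch_i = sum_j (w_ij / w_i) * cw_j — a convex combination, so the result
    always lies between the cheapest and the most expensive category.
    """
    missing = [j for j, c in composition.job_headcounts.items() if c > 0 and j not in job_costs]
    if missing:
        raise CostInputError(
            f"group {composition.group_id}: no day cost for job categories {missing}"
        )
    total = composition.total_workers
    ch = sum(
        count * job_costs[job]
        for job, count in composition.job_headcounts.items()
        if count > 0
    ) / total
    return GroupDayCost(group_id=composition.group_id, ch_i=float(ch))


def group_absence_cost(total_absence_days: float, ch_i: float) -> float:
    """Cost of a group's total absence days: a_i x ch_i."""
    if total_absence_days < 0 or ch_i < 0:
        raise CostInputError(
            f"absence days ({total_absence_days}) and day cost ({ch_i}) must be non-negative"
        )
    return float(total_absence_days) * float(ch_i)


def read_salary_table(path: str | Path) -> dict[str, JobSalaryEntry]:
    """Read a salary CSV into per-category entries with derived day costs.

    Columns: ``job_category`` plus exactly one costing route per row among
    ``staff_cost``+``headcount``, ``yearly_cost_per_worker`` or
    ``monthly_salary``; optional ``monthly_payments`` and
    ``working_days_per_year`` override the Italian defaults (14, 253).
    """
    frame = pd.read_csv(path)
    return salary_table_from_frame(frame)


def salary_table_from_frame(frame: pd.DataFrame) -> dict[str, JobSalaryEntry]:
    """Build salary entries from an in-memory table (see read_salary_table)."""
    if "job_category" not in frame.columns:
        raise CostInputError("salary table lacks a job_category column")

    def _opt(row, col, cast):
        if col not in frame.columns:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return cast(v)

    entries: dict[str, JobSalaryEntry] = {}
    for _, row in frame.iterrows():
        category = str(row["job_category"])
        if category in entries:
            raise CostInputError(f"duplicate job category in salary table: {category}")
        entries[category] = JobSalaryEntry(
            job_category=category,
            staff_cost=_opt(row, "staff_cost", float),
            headcount=_opt(row, "headcount", int),
            yearly_cost_per_worker=_opt(row, "yearly_cost_per_worker", float),
            monthly_salary=_opt(row, "monthly_salary", float),
            monthly_payments=_opt(row, "monthly_payments", int) or DEFAULT_MONTHLY_PAYMENTS,
            working_days_per_year=_opt(row, "working_days_per_year", int)
            or DEFAULT_WORKING_DAYS_PER_YEAR,
        )
    return entries
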