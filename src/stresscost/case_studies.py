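"""Published inputs from the two Italian case studies.

The model was evaluated in two organizations: a public hospital (14
homogenous groups of healthcare workers, N=1014) and a public
administration unit (6 homogenous groups, N=534).  The worker-level
microdata behind those studies are unpublished; what the organizations
released are the salary-cost table of the hospital workforce, one fully
worked group example (Reconstructive Plastic Surgery), and the per-group
results tables (absence days by type, response rate, absence cost, PAF and
stress cost).  Those published values are bundled here so the package can
re-derive every quantity that is derivable from them: the working-day
costs, the worked example's group costing, and both studies' totals and
averages.

All monetary values are euros per year (2018 price level for the hospital).
"""

from __future__ import annotations

from dataclasses import dataclass

from stresscost.cost_pipeline import (
    GroupAbsenceSummary,
    GroupResult,
    StudyResult,
    estimate_group_cost,
    summarize_groups,
)
from stresscost.workday_cost import (
    GroupComposition,
    JobSalaryEntry,
    group_absence_cost,
    group_day_cost,
)

#: Hospital workforce salary inputs: job category -> (total yearly staff
#: cost in EUR, headcount).  14 monthly payments, 253 working days/year.
HOSPITAL_SALARY_INPUTS: dict[str, tuple[float, int]] = {
    "management_physicians": (26_822_757.0, 301),
    "health_staff": (18_917_827.0, 446),
    "management_other": (1_062_772.0, 11),
    "staff_other": (8_579_999.0, 256),
}

#: Published (rounded) working-day costs for the same categories, EUR.
HOSPITAL_PUBLISHED_DAY_COSTS: dict[str, float] = {
    "management_physicians": 301.90,
    "health_staff": 143.70,
    "management_other": 327.30,
    "staff_other": 113.50,
}

#: The worked example: job composition of the Reconstructive Plastic
#: Surgery group (25 workers) with each job's published day cost.
PLASTIC_SURGERY_COMPOSITION: dict[str, int] = {
    "medical_director": 7,
    "nurse": 14,
    "healthcare_social_worker": 1,
    "care_technician": 1,
    "healthcare_social_assistant": 2,
}
PLASTIC_SURGERY_JOB_DAY_COSTS: dict[str, float] = {
    "medical_director": 301.90,
    "nurse": 143.70,
    "healthcare_social_worker": 113.50,
    "care_technician": 113.50,
    "healthcare_social_assistant": 113.50,
}
PLASTIC_SURGERY_TOTAL_ABSENCES = 1417
PLASTIC_SURGERY_PUBLISHED_GROUP_DAY_COST = 183.20
PLASTIC_SURGERY_PUBLISHED_ABSENCE_COST = 259_559.0


@dataclass(frozen=True)
class PublishedGroupRow:
    """One published per-group results row.

    ``paf_pct`` is the printed attributable fraction in percent (one
    decimal), ``absence_cost`` and ``stress_cost`` whole euros.
    """

    group: str
    days_injury: int
    days_sickness: int
    days_other: int
    total_days: int
    response_rate_pct: float
    absence_cost: float
    paf_pct: float
    stress_cost: float


#: Hospital case study: all 14 homogenous groups.
HOSPITAL_GROUP_ROWS: tuple[PublishedGroupRow, ...] = (
    PublishedGroupRow("Reconstructive Plastic Surgery", 72, 272, 1073, 1417, 76.0, 259_559, 47.4, 122_949),
    PublishedGroupRow("Anatomy and Pathological Histology and Cytodiagnostic", 13, 107, 1076, 1196, 95.7, 233_749, 31.8, 74_375),
    PublishedGroupRow("Technical unit and Clinical Engineering", 17, 336, 919, 1272, 80.0, 144_433, 33.3, 48_144),
    PublishedGroupRow("Hematology", 0, 14, 610, 624, 94.1, 124_513, 37.5, 46_692),
    PublishedGroupRow("Orthopaedics", 0, 100, 576, 676, 81.3, 115_922, 30.8, 35_668),
    PublishedGroupRow("Laboratory of Medical Physics and Expert Systems", 0, 156, 748, 904, 81.3, 102_647, 30.8, 31_584),
    PublishedGroupRow("Derma pathology", 0, 68, 343, 411, 75.0, 81_896, 33.3, 27_299),
    PublishedGroupRow("Insurance, Litigation and Deliberative Acts", 0, 2, 331, 333, 85.7, 37_811, 50.0, 18_906),
    PublishedGroupRow("Cardiology", 0, 113, 777, 890, 78.6, 188_239, 9.1, 17_113),
    PublishedGroupRow("Endocrinology", 0, 10, 370, 380, 85.7, 80_372, 16.7, 13_395),
    PublishedGroupRow("Training", 0, 72, 363, 435, 85.7, 51_267, 16.7, 8_545),
    PublishedGroupRow("Respiratory Pathophysiology", 0, 39, 419, 458, 88.9, 94_950, 0.0, 0.0),
    PublishedGroupRow("Cancer Dermatology", 0, 36, 539, 575, 90.9, 129_096, 0.0, 0.0),
    PublishedGroupRow("Digestive surgical oncology", 0, 94, 559, 653, 100.0, 129_327, 0.0, 0.0),
)

#: Public-administration case study: all 6 homogenous groups.
ADMIN_GROUP_ROWS: tuple[PublishedGroupRow, ...] = (
    PublishedGroupRow("Civil protection", 0, 291, 0, 291, 75.4, 26_003, 10.2, 2_653),
    PublishedGroupRow("Transportation", 0, 536, 356, 892, 78.5, 85_595, 8.1, 6_903),
    PublishedGroupRow("Regional agency of river basin district", 0, 378, 337, 715, 83.9, 70_531, 23.1, 16_276),
    PublishedGroupRow("Social policies", 0, 882, 349, 1231, 81.4, 131_626, 14.3, 18_804),
    PublishedGroupRow("General affairs and information society", 2, 896, 410, 1308, 83.1, 139_086, 23.7, 33_004),
    PublishedGroupRow("Forest department and environmental surveillance", 49, 13_083, 8_995, 22_127, 83.0, 1_562_635, 18.1, 282_404),
)


def hospital_salary_table() -> dict[str, JobSalaryEntry]:
    """Salary entries for the hospital workforce, day costs derived."""
    return {
        cat: JobSalaryEntry(job_category=cat, staff_cost=cost, headcount=n)
        for cat, (cost, n) in HOSPITAL_SALARY_INPUTS.items()
    }


def plastic_surgery_costing() -> tuple[float, float]:
    """Re-derive the worked example's group day cost and absence cost.

    Returns (ch_i, absence cost): the headcount-weighted day cost of the
    25-worker group and the cost of its 1417 recorded absence days.
    """
    composition = GroupComposition(
        group_id="Reconstructive Plastic Surgery",
        job_headcounts=PLASTIC_SURGERY_COMPOSITION,
    )
    ch = group_day_cost(composition, PLASTIC_SURGERY_JOB_DAY_COSTS).ch_i
    return ch, group_absence_cost(PLASTIC_SURGERY_TOTAL_ABSENCES, ch)


def _row_to_result(row: PublishedGroupRow) -> GroupResult:
    summary = GroupAbsenceSummary(
        group_id=row.group,
        days_injury=row.days_injury,
        days_sickness=row.days_sickness,
        days_other=row.days_other,
    )
    # Implied group day cost backs out of the published absence cost.
    day_cost = row.absence_cost / row.total_days if row.total_days else 0.0
    return GroupResult(
        group_id=row.group,
        absence=summary,
        response_rate=row.response_rate_pct / 100.0,
        day_cost=day_cost,
        absence_cost=row.absence_cost,
        paf=row.paf_pct / 100.0,
        stress_cost=row.stress_cost,
        included=True,
    )


def summarize_published_rows(rows: tuple[PublishedGroupRow, ...]) -> StudyResult:
    """Aggregate published per-group rows into the study totals block.

    Respondent counts per group were not published, so the result carries
    no weighted averages — only sums, the unweighted mean PAF and the
    dispersion of group stress costs are derivable.
    """
    return summarize_groups(
        [_row_to_result(r) for r in rows], respondent_weights=False
    )


def hospital_summary() -> StudyResult:
    """Totals block of the hospital case study from its published rows."""
    return summarize_published_rows(HOSPITAL_GROUP_ROWS)


def admin_summary() -> StudyResult:
    """Totals block of the public-administration case study."""
    return summarize_published_rows(ADMIN_GROUP_ROWS)
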