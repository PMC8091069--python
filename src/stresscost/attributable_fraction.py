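"""Attributable fractions for work-related stress over absence days.

The classical population attributable fraction is
PAF = (I_p - I_u) / I_p, with I_p the outcome incidence in the whole
population and I_u the incidence among the unexposed.  For a homogenous
group of workers the model adapts this to absence-day counts:

    PAF_i = (N_i - N_u_i) / N_i

where N_i is the group's total absence days among classifiable workers and
N_u_i the days among those classified unexposed.  This adapted statistic is
the share of absence days carried by exposed workers; unlike the classical
excess fraction it converges to the exposure prevalence, not to zero, when
exposure has no effect on absence (the classical form remains available via
:func:`paf_general` on day rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from stresscost.msit_exposure import ExposureLabel


class PafError(ValueError):
    """Raised for invalid attributable-fraction inputs."""


@dataclass(frozen=True)
class ExposureAbsenceCounts:
    """Absence-day and worker tallies for one homogenous group."""

    group_id: str
    N_i: float  # total absence days among exposed + unexposed workers
    N_u_i: float  # absence days among unexposed workers
    n_exposed: int = 0
    n_unexposed: int = 0
    n_unknown: int = 0

    def __post_init__(self) -> None:
        if self.N_i < 0 or self.N_u_i < 0:
            raise PafError(f"group {self.group_id}: negative absence counts")
        if self.N_u_i > self.N_i:
            raise PafError(
                f"group {self.group_id}: unexposed days ({self.N_u_i}) exceed total ({self.N_i})"
            )
        if min(self.n_exposed, self.n_unexposed, self.n_unknown) < 0:
            raise PafError(f"group {self.group_id}: negative worker counts")


@dataclass(frozen=True)
class GroupPaf:
    """Work-related-stress attributable fraction for one group, in [0, 1]."""

    group_id: str
    paf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.paf <= 1.0:
            raise PafError(f"group {self.group_id}: PAF {self.paf} outside [0, 1]")


def paf_general(incidence_population: float, incidence_unexposed: float) -> float:
    """Classical population attributable fraction (I_p - I_u) / I_p.

    A negative result (protective exposure, I_u > I_p) is returned as-is
    with a warning, not clipped.
    """
    if incidence_population <= 0:
        raise PafError(
            f"population incidence must be positive, got {incidence_population}"
        )
    if incidence_unexposed < 0:
        raise PafError(f"unexposed incidence must be non-negative, got {incidence_unexposed}")
    paf = (incidence_population - incidence_unexposed) / incidence_population
    if paf < 0:
        warnings.warn(
            f"negative attributable fraction ({paf:.4f}): unexposed incidence exceeds "
            "population incidence (protective exposure)",
            stacklevel=2,
        )
    return paf


def wrs_attributable_fraction(counts: ExposureAbsenceCounts) -> GroupPaf:
    """Adapted attributable fraction (N_i - N_u_i) / N_i for one group.

    A group with no classifiable absence days (N_i = 0) gets PAF 0: no
    absence means no attributable cost.
    """
    if counts.N_i == 0:
        return GroupPaf(group_id=counts.group_id, paf=0.0)
    return GroupPaf(group_id=counts.group_id, paf=(counts.N_i - counts.N_u_i) / counts.N_i)


def tally_group(
    group_id: str,
    absence_days: Mapping[str, float],
    labels: Iterable[ExposureLabel],
    *,
    scope: str = "respondents_only",
) -> ExposureAbsenceCounts:
    """Tally a group's absence days by exposure status.

    ``absence_days`` maps worker_id -> total absence days; ``labels`` carry
    each worker's exposure status.  Under the default respondents-only
    scope, N_i sums over workers with a known status (exposed or unexposed)
    and unknown-status workers are counted only in ``n_unknown``.  Under
    ``scope="all_workers"`` unknown workers' days enter N_i but not N_u_i,
    which treats every non-respondent's absence as exposed-attributable and
    therefore inflates the fraction; it exists for sensitivity analysis.
    """
    if scope not in ("respondents_only", "all_workers"):
        raise PafError(f"unknown tally scope: {scope!r}")
    seen: set[str] = set()
    N_i = 0.0
    N_u = 0.0
    n_exp = n_unexp = n_unk = 0
    for label in labels:
        if label.worker_id in seen:
            raise PafError(f"group {group_id}: duplicated worker id {label.worker_id!r}")
        seen.add(label.worker_id)
        days = float(absence_days.get(label.worker_id, 0.0))
        if days < 0:
            raise PafError(f"group {group_id}: negative absence days for {label.worker_id!r}")
        if label.status == "exposed":
            n_exp += 1
            N_i += days
        elif label.status == "unexposed":
            n_unexp += 1
            N_i += days
            N_u += days
        elif label.status == "unknown":
            n_unk += 1
            if scope == "all_workers":
                N_i += days
        else:
            raise PafError(f"group {group_id}: invalid status {label.status!r}")
    return ExposureAbsenceCounts(
        group_id=group_id,
        N_i=N_i,
        N_u_i=N_u,
        n_exposed=n_exp,
        n_unexposed=n_unexp,
        n_unknown=n_unk,
    )
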