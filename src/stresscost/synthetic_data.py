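"""Synthetic workforce generator for exercising the cost pipeline.

Real worker-level data behind this kind of study (absence records linked to
questionnaire responses) are rarely publishable, so the generator produces
datasets with the statistical structure the model assumes:

* homogenous groups of 20-250 workers drawn from a configurable job mix
  with distinct salary-derived day costs;
* a latent binary exposure to work-related stress risk with prevalence p;
* absence-day counts per worker and type from a negative binomial
  (Poisson-gamma) distribution — absence data are overdispersed — with
  unexposed mean mu and exposed mean RR x mu;
* 35-item questionnaire responses from a discretised latent score whose
  mean is shifted down by ``score_separation`` for exposed workers, so
  classification exercises the real scoring path;
* per-group questionnaire response rates drawn from a configurable range.

Under this generator the adapted attributable fraction has the analytic
expectation p*RR / (p*RR + 1 - p) (the share of absence days carried by
exposed workers), available as :func:`expected_paf` for parameter-recovery
checks.  A single seed drives all draws through spawned substreams, so a
given configuration is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from stresscost.cost_pipeline import StudyDataset
from stresscost.msit_exposure import N_ITEMS, ItemMap, default_item_map
from stresscost.workday_cost import JobSalaryEntry


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


#: Default job mix: share of the workforce and yearly cost per worker (EUR),
#: patterned on a public-hospital workforce (physicians, health staff,
#: managerial and support roles) so the generated day costs are realistic
#: for the Italian public sector.
DEFAULT_JOB_MIX: dict[str, tuple[float, float]] = {
    "physician": (0.30, 89_112.0),
    "health_staff": (0.44, 42_417.0),
    "management_other": (0.01, 96_616.0),
    "support_staff": (0.25, 33_516.0),
}

#: Default mean absence days per worker-year among unexposed workers, by
#: type — injuries are rare, sickness moderate, other leave dominant, as in
#: public-sector absence records.
DEFAULT_ABSENCE_MEANS: dict[str, float] = {
    "days_injury": 0.1,
    "days_sickness": 1.4,
    "days_other": 8.5,
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    n_groups:
        Number of homogenous groups.
    workers_per_group:
        Fixed count, or an inclusive (low, high) range sampled uniformly
        per group (default 20-250).
    job_mix:
        job category -> (workforce share, yearly cost per worker).
    exposure_prevalence:
        Probability p that a worker is exposed (default 0.25, matching the
        first-quartile normative cutoff).
    absence_means:
        Mean absence days per worker-year among the unexposed, by type.
    rate_ratio:
        RR >= 0; exposed workers' absence means are RR x mu.
    dispersion:
        Negative-binomial shape k > 0 (variance mu + mu^2/k); large k
        approaches Poisson.
    response_rate:
        Fixed fraction or (low, high) range per group (default 0.75-1.0).
    score_separation:
        Downward shift, in raw score units, of exposed workers' latent
        questionnaire score (default 1.0; unexposed centre 3.5, sd 0.4).
    n_normative:
        Size of the simulated normative sample of overall scores.
    seed:
        Single seed for all draws.
    """

    n_groups: int = 10
    workers_per_group: Union[int, tuple[int, int]] = (20, 250)
    job_mix: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_JOB_MIX)
    )
    exposure_prevalence: float = 0.25
    absence_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ABSENCE_MEANS)
    )
    rate_ratio: float = 1.5
    dispersion: float = 0.8
    response_rate: Union[float, tuple[float, float]] = (0.75, 1.0)
    score_separation: float = 1.0
    latent_mean: float = 3.5
    latent_sd: float = 0.4
    item_sd: float = 0.8
    n_normative: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups <= 0:
            raise SimulationError(f"n_groups must be positive, got {self.n_groups}")
        if not 0.0 <= self.exposure_prevalence <= 1.0:
            raise SimulationError(
                f"exposure prevalence {self.exposure_prevalence} outside [0, 1]"
            )
        if self.rate_ratio < 0:
            raise SimulationError(f"rate ratio must be >= 0, got {self.rate_ratio}")
        if self.dispersion <= 0:
            raise SimulationError(f"dispersion must be positive, got {self.dispersion}")
        if any(m < 0 for m in self.absence_means.values()):
            raise SimulationError("absence means must be non-negative")
        shares = [s for s, _ in self.job_mix.values()]
        if not self.job_mix or abs(sum(shares) - 1.0) > 1e-9 or any(s < 0 for s in shares):
            raise SimulationError("job mix shares must be non-negative and sum to 1")
        lo, hi = self._rate_range()
        if not 0.0 <= lo <= hi <= 1.0:
            raise SimulationError(f"response rate range ({lo}, {hi}) outside [0, 1]")
        wlo, whi = self._size_range()
        if not 0 < wlo <= whi:
            raise SimulationError(f"workers_per_group range ({wlo}, {whi}) invalid")

    def _rate_range(self) -> tuple[float, float]:
        if isinstance(self.response_rate, tuple):
            return float(self.response_rate[0]), float(self.response_rate[1])
        return float(self.response_rate), float(self.response_rate)

    def _size_range(self) -> tuple[int, int]:
        if isinstance(self.workers_per_group, tuple):
            return int(self.workers_per_group[0]), int(self.workers_per_group[1])
        return int(self.workers_per_group), int(self.workers_per_group)


@dataclass
class SyntheticStudy:
    """A generated study: pipeline-ready tables plus the ground truth."""

    dataset: StudyDataset
    salary_table: dict[str, JobSalaryEntry]
    normative_scores: np.ndarray
    ground_truth: pd.DataFrame  # worker_id, group_id, exposed
    config: SimulationConfig

    @property
    def true_paf(self) -> float:
        """Analytic expected attributable fraction under the generator."""
        return expected_paf(self.config.exposure_prevalence, self.config.rate_ratio)

    def write_csvs(self, directory: str | Path) -> dict[str, Path]:
        """Write all tables in the CSV dialects the pipeline reads."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "roster": directory / "roster.csv",
            "absences": directory / "absences.csv",
            "questionnaire": directory / "questionnaire.csv",
            "salary": directory / "salary.csv",
            "normative": directory / "normative_scores.csv",
            "ground_truth": directory / "ground_truth.csv",
        }
        self.dataset.roster.to_csv(paths["roster"], index=False)
        self.dataset.absences.to_csv(paths["absences"], index=False)
        self.dataset.questionnaire.to_csv(paths["questionnaire"], index=False)
        salary_rows = [
            {
                "job_category": e.job_category,
                "yearly_cost_per_worker": e.yearly_cost_per_worker,
                "monthly_payments": e.monthly_payments,
                "working_days_per_year": e.working_days_per_year,
            }
            for e in self.salary_table.values()
        ]
        pd.DataFrame(salary_rows).to_csv(paths["salary"], index=False)
        pd.DataFrame({"score": self.normative_scores}).to_csv(paths["normative"], index=False)
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        return paths


def expected_paf(p: float, rate_ratio: float) -> float:
    """Expected share of absence days carried by exposed workers.

    With exposure prevalence p and a mean rate ratio RR between exposed and
    unexposed workers, the expected adapted attributable fraction is
    p*RR / (p*RR + 1 - p).  At RR = 1 this equals p — the statistic's
    behaviour under a null effect.
    """
    if not 0.0 <= p <= 1.0:
        raise SimulationError(f"prevalence {p} outside [0, 1]")
    if rate_ratio < 0:
        raise SimulationError(f"rate ratio must be >= 0, got {rate_ratio}")
    denom = p * rate_ratio + (1.0 - p)
    if denom <= 0:
        raise SimulationError(f"degenerate denominator for p={p}, RR={rate_ratio}")
    return p * rate_ratio / denom


def paf_standard_error(config: SimulationConfig, n_workers: int) -> float:
    """Delta-method standard error of the pooled PAF estimate.

    For n workers with exposure ~ Bernoulli(p) and per-type negative
    binomial absence counts (shape k, unexposed means mu_t, exposed means
    RR x mu_t), the pooled estimate X/(X+Y) — exposed days over all days —
    fluctuates around :func:`expected_paf` with a variance that combines
    prevalence sampling and count overdispersion.  Writing U, V for one
    worker's exposed/unexposed day contribution, the first-order expansion
    around the means gives

        Var = (E[V]^2 Var U + E[U]^2 Var V - 2 E[U] E[V] Cov(U, V)) / (n S^4)

    with S = E[U] + E[V] and Cov(U, V) = -E[U] E[V] (the two contributions
    are mutually exclusive per worker).

    A second variance source is the normative threshold itself: the binary
    cutoff is the first-quartile of a finite normative sample whose exposed
    fraction fluctuates around p, and because the cutoff percentile equals
    the prevalence the quantile sits at the exposed cluster's edge — a
    shift of the realized normative exposed fraction f moves a matching
    slice of workers across the cutoff even when the clusters are far
    apart.  To first order the estimate moves with slope -PAF/p when f
    rises (exposed workers relabelled unexposed) and -(1-PAF)/(1-p) when f
    falls, so the threshold term averages the two squared slopes against
    Var(f) = p(1-p)/n_normative.  Both terms add in quadrature.  Used by
    recovery checks to set a 3-sigma band around the analytic expectation.
    """
    if n_workers <= 0:
        raise SimulationError(f"n_workers must be positive, got {n_workers}")
    p = config.exposure_prevalence
    rr = config.rate_ratio
    k = config.dispersion
    mus = [float(m) for m in config.absence_means.values()]
    m_u = sum(mus)
    if m_u <= 0 or not 0 < p < 1:
        raise SimulationError("standard error undefined for degenerate configuration")
    m_e = rr * m_u
    var_e = sum(rr * m + (rr * m) ** 2 / k for m in mus)
    var_u = sum(m + m**2 / k for m in mus)
    eu, ev = p * m_e, (1 - p) * m_u
    var_uu = p * (var_e + m_e**2) - eu**2
    var_vv = (1 - p) * (var_u + m_u**2) - ev**2
    cov_uv = -eu * ev
    s = eu + ev
    var_est = (ev**2 * var_uu + eu**2 * var_vv - 2 * eu * ev * cov_uv) / (n_workers * s**4)

    paf = expected_paf(p, rr)
    slope_up = paf / p
    slope_down = (1.0 - paf) / (1.0 - p)
    var_frac = p * (1.0 - p) / config.n_normative
    var_threshold = var_frac * (slope_up**2 + slope_down**2) / 2.0
    return float(np.sqrt(var_est + var_threshold))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative-binomial counts with per-element means and shape k."""
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if np.any(pos):
        m = mean[pos]
        out[pos] = rng.negative_binomial(n=k, p=k / (k + m))
    return out


def _questionnaire_items(
    rng: np.random.Generator,
    latent: np.ndarray,
    item_map: ItemMap,
    item_sd: float,
) -> np.ndarray:
    """Discretise latent scores into raw 1-5 item answers.

    Each item's higher-is-better value is the latent score plus noise,
    rounded and clamped to 1-5; reverse-coded items are stored as 6 - v so
    the scoring path has real reverse-coding work to do.
    """
    n = latent.shape[0]
    noise = rng.normal(0.0, item_sd, size=(n, N_ITEMS))
    good = np.clip(np.rint(latent[:, None] + noise), 1, 5).astype(int)
    raw = good.copy()
    rev = np.array(item_map.reverse)
    raw[:, rev] = 6 - raw[:, rev]
    return raw


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full synthetic study, reproducible from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_expo, rng_abs, rng_quest, rng_norm = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    item_map = default_item_map()

    jobs = list(config.job_mix)
    shares = np.array([config.job_mix[j][0] for j in jobs], dtype=float)
    salary_table = {
        j: JobSalaryEntry(job_category=j, yearly_cost_per_worker=config.job_mix[j][1])
        for j in jobs
    }

    wlo, whi = config._size_range()
    rlo, rhi = config._rate_range()
    sizes = rng_struct.integers(wlo, whi + 1, size=config.n_groups)
    group_rates = rng_struct.uniform(rlo, rhi, size=config.n_groups)
    n_workers = int(sizes.sum())

    worker_ids = np.array([f"w{i:05d}" for i in range(n_workers)])
    group_ids = np.repeat(
        [f"group_{g:02d}" for g in range(config.n_groups)], sizes
    )
    job_idx = rng_struct.choice(len(jobs), size=n_workers, p=shares / shares.sum())
    job_cats = np.array(jobs)[job_idx]

    exposed = rng_expo.random(n_workers) < config.exposure_prevalence

    roster = pd.DataFrame(
        {"worker_id": worker_ids, "group_id": group_ids, "job_category": job_cats}
    )

    abs_data: dict[str, np.ndarray] = {}
    for abs_type in ("days_injury", "days_sickness", "days_other"):
        mu = float(config.absence_means.get(abs_type, 0.0))
        means = np.where(exposed, config.rate_ratio * mu, mu)
        abs_data[abs_type] = _nb_counts(rng_abs, means, config.dispersion)
    absences = pd.DataFrame({"worker_id": worker_ids, **abs_data})

    latent = rng_quest.normal(
        config.latent_mean - config.score_separation * exposed.astype(float),
        config.latent_sd,
    )
    items = _questionnaire_items(rng_quest, latent, item_map, config.item_sd)
    responded = np.concatenate(
        [rng_quest.random(sz) < rate for sz, rate in zip(sizes, group_rates)]
    )
    quest = pd.DataFrame(
        items[responded], columns=[f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
    )
    quest.insert(0, "worker_id", worker_ids[responded])

    # Normative sample: overall scores of a population with the same latent
    # mixture, pushed through an analytic version of the scoring path (the
    # mean of 35 discretised items, reverse-coding cancelling out).
    norm_exposed = rng_norm.random(config.n_normative) < config.exposure_prevalence
    norm_latent = rng_norm.normal(
        config.latent_mean - config.score_separation * norm_exposed.astype(float),
        config.latent_sd,
    )
    norm_items = np.clip(
        np.rint(norm_latent[:, None] + rng_norm.normal(0, config.item_sd, (config.n_normative, N_ITEMS))),
        1,
        5,
    )
    normative_scores = norm_items.mean(axis=1)

    ground_truth = pd.DataFrame(
        {"worker_id": worker_ids, "group_id": group_ids, "exposed": exposed}
    )

    return SyntheticStudy(
        dataset=StudyDataset(roster=roster, absences=absences, questionnaire=quest),
        salary_table=salary_table,
        normative_scores=normative_scores,
        ground_truth=ground_truth,
        config=config,
    )
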