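# Methods

## Model

The package estimates the yearly cost of work-related stress to an
organization as the stress-attributable share of its absence cost, using
the human capital approach: a lost working day is valued at the gross
salary cost of that day. Per homogenous group *i*,

    Cost_i = d_i · ch_i · PAF_i

with `d_i` the group's recorded absence days (injury + sickness + other),
`ch_i` its average working-day cost, and `PAF_i` its work-related-stress
attributable fraction. The study total sums `Cost_i` over included groups.

Assumptions worth making explicit:

* Salary is a proxy for productivity; every absence day is valued at the
  full day cost for the whole absence period (human capital approach).
  Friction-cost ideas — costing only until a replacement arrives — are a
  different model and out of scope, as are presenteeism and turnover.
* The group PAF estimated from questionnaire respondents is applied to the
  group's *total* recorded absence cost, i.e. non-respondents are assumed
  exchangeable with respondents within a group. This is why a minimum
  response rate (default 75%) gates inclusion.
* Exposure is a binary construct obtained by thresholding a single overall
  questionnaire score against a normative distribution.

## Day costs

Per job category `j`: yearly cost per worker (total staff cost /
headcount, or given directly, or monthly salary × payments), divided by
the number of monthly payments, divided by the average working days in a
month (`working_days_per_year / 12`):

    cw_j = yearly_j / payments / (working_days / 12)

Defaults `payments = 14`, `working_days = 253` encode the Italian
public-sector convention; both are per-row config fields so the model
ports to other countries. The group day cost `ch_i` is the
headcount-weighted mean of its categories' `cw_j` (a convex combination,
so always within the category min/max). All currency values are carried at
full floating precision; rounding (day costs to 2 decimals, aggregates to
whole euros, PAF to 0.1 percentage point) happens only in the report
layer. Published reference tables round intermediates, which makes their
printed products drift by <0.1%; our reproductions therefore match the
printed day costs to ≤€0.05 and printed products to ≤0.1%.

## Exposure classification

The 35-item questionnaire (Management Standards layout) measures seven
psychosocial hazard dimensions. Since the instrument's item map is not
part of the published model description, the package ships the standard
layout as its default configuration — demands (8 items) and relationships
(4) negatively worded and reverse-coded `v → 6 − v`, control (6),
management support (5), colleague support (4), role (5) and change (3)
scored as answered — overridable by a YAML file.

Scoring: each dimension score is the mean of its present items (missing if
fewer than 50% of its items were answered — the completion rule is a
package choice; the source model is silent on missing items); a worker
without all seven dimension scores counts as a non-respondent. The overall
score defaults to the unweighted mean of the seven dimension means. The
combination rule for the "unique score" was genuinely open; the unweighted
dimension mean treats the seven hazard areas as equally important, and a
`method="item_mean"` alternative (weighting dimensions by item count) is
provided.

Thresholds: percentiles of a normative overall-score sample, computed by
linear interpolation between order statistics (stated because quantile
conventions differ between implementations). The binary cutoff defaults to
the 25th percentile — the first-quartile rule: scores strictly above it
are unexposed, scores at or below it exposed. The tie-at-cutoff case is
classified exposed, the conservative reading of a "strictly higher is
unexposed" rule. The 20th/50th/80th percentiles additionally define four
risk bands (high < p20 ≤ medium-high < p50 ≤ medium-low < p80 ≤ low); the
band feature and the binary rule are implemented separately, and the
binary percentile is a config knob, because the two descriptions
(quartile vs 20/50/80 bands) do not reduce to one another.

## The adapted attributable fraction

`PAF_i = (N_i − N_u_i)/N_i` with `N_i` total absence days among
classifiable workers and `N_u_i` the days among the unexposed. Stated at
the level at which it is literally true: this is the share of absence days
carried by exposed workers, **not** the classical excess fraction. When
exposure has no effect on absence it converges to the exposure prevalence
(≈25% under the first-quartile rule), not to zero — so a fraction near the
prevalence is consistent with "no detectable effect". The tests and the
acceptance script exercise exactly this null behaviour. The classical form
`(I_p − I_u)/I_p` remains available for day-rate comparisons; a negative
classical value (protective exposure) is returned with a warning, never
clipped. Degenerate groups with `N_i = 0` get PAF 0: no absence, no
attributable cost.

Tally scope: by default only workers with a known exposure status enter
`N_i` (respondents-only), and the resulting PAF is applied to the whole
group's absence cost. An `all_workers` scope (non-respondents' days enter
`N_i` but never `N_u_i`) is exposed for sensitivity analysis and off by
default, since it treats every non-respondent's absence as
exposed-attributable.

## Aggregation

The report's Total/Average PAF row is the unweighted mean of the included
groups' PAFs — with the published per-group rows this exactly reproduces
the case studies' printed 24.1% and 16.2%. Respondent-count-weighted means
of PAF and stress cost are also computed where respondent counts exist;
they are model-defined quantities (the case studies' printed weighted
values cannot be verified because per-group questionnaire counts were not
published, so the package flags its own weighted means as model-defined).
Dispersion is the sample standard deviation (ddof=1) of included groups'
stress costs; on the hospital rows this reproduces the published €33,900
and 17.1-point PAF spread.

A documented discrepancy in the source material: the worked single-group
example prints an attributable fraction of 0.68 (text: 64.8%) and a stress
cost of €177,539 for the same group that the full results table lists at
47.4% and €122,949. The two cannot be reconciled from published data; the
package's reproductions anchor on the full results table, whose column
sums and means are internally consistent with the headline totals.

## Synthetic data generator

The generator emulates the data shape the model consumes: homogenous
groups of 20–250 workers; a job mix with realistic Italian public-sector
yearly costs (defaults patterned on a hospital workforce: physicians
€89,112/year → €301.90/day, health staff €42,417, managerial €96,616,
support €33,516); binary exposure with prevalence `p` (default 0.25,
matching the first-quartile cutoff); per-type absence counts from a
negative binomial (Poisson–gamma) with unexposed means 0.1 / 1.4 / 8.5
days per worker-year for injury / sickness / other — ≈10 days/worker-year
total, the order observed in public-sector absence records — dispersion
`k = 0.8` (absence data are strongly overdispersed; Poisson is recovered
as `k → ∞`), and exposed means `RR · μ`; questionnaire items discretised
from a worker-level latent score (unexposed centre 3.5, sd 0.4, item noise
sd 0.8, clamped to 1–5), with exposed workers' latent centre shifted down
by `score_separation`; per-group response rates uniform on 0.75–1.0. A
single seed drives everything through spawned substreams; a fixed
configuration is byte-reproducible.

Under this generator the expected adapted fraction is

    E[PAF] = p·RR / (p·RR + 1 − p)

What the generator does **not** emulate: longitudinal/seasonal absence
structure, within-group correlation of exposure, item-level factor
structure beyond a single latent, and any fit to the case studies'
unpublished worker-level marginals. Passing recovery tests therefore show
the pipeline is a consistent estimator of the generator's fraction, not
that real absence data satisfy the model's assumptions.

## Numerical and statistical choices

* Percentile estimator: linear interpolation (`numpy.percentile`,
  `method="linear"`); thresholds require ≥20 finite normative scores.
* Recovery checks compare the pooled estimate at n = 2000 workers against
  the analytic expectation within 3 standard errors. The standard error
  (`paf_standard_error`) combines two delta-method terms in quadrature:
  the count-draw term (Bernoulli exposure × negative-binomial days) and a
  threshold term. The threshold term exists because the cutoff percentile
  equals the prevalence, so the normative first quartile sits at the
  exposed score cluster's edge: a fluctuation of the realized normative
  exposed fraction `f` moves a matching slice of workers across the
  cutoff, with first-order slopes `−PAF/p` (f above p) and `−(1−PAF)/(1−p)`
  (f below p), averaged as squared slopes against
  `Var(f) = p(1−p)/n_normative`. The formula was validated against the
  spread of independent full-pipeline replicates.
* Problem sizes: unit and property tests run on groups of 20–60 workers;
  statistical checks use one group of 2000 workers and normative samples
  of 1000–5000 scores, at which the whole suite completes in seconds.
* Degenerate inputs: empty rosters, groups missing from the salary table,
  duplicate worker ids, respondents exceeding members, and all-zero
  weights raise typed errors naming the offending entity.

## Known limitations

* The attributable fraction is a share measure (see above); comparisons
  with classical excess-fraction PAFs must account for its non-zero null.
* No confidence intervals on group PAFs or costs (point estimates only,
  matching the model as published); no currency discounting or inflation
  adjustment; no presenteeism or turnover components.
* The normative thresholds of the deployed national instrument derive from
  a 66k-questionnaire database that is not public; users must supply their
  own normative sample or threshold file.
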