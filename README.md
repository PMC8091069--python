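# stresscost

Absence-based cost estimation of work-related stress for organizations.

Occupational health teams and HR analysts routinely hold three kinds of
data: absence records (injury, sickness and other leave days), salary costs
by job category, and psychosocial risk-assessment questionnaires. This
package turns those into an estimate of what work-related stress costs an
organization per year, at the level of *homogenous groups* — units of
workers sharing work-related risk factors and organizational aspects.

## The model

For each homogenous group *i* the stress-attributable cost is

```
Cost_i = d_i · ch_i · PAF_i
```

* **d_i** — the group's absence days (injury + sickness + other).
* **ch_i** — the human-capital cost of one working day, the
  headcount-weighted mean of the job categories' day costs
  `cw_j = (yearly cost per worker / monthly payments) / (working days per year / 12)`
  (Italian convention: 14 payments, 253 working days, both configurable).
* **PAF_i** — a work-related-stress attributable fraction adapted from the
  classical population attributable fraction `(I_p − I_u)/I_p`:
  `PAF_i = (N_i − N_u_i)/N_i`, where `N_i` is the group's absence days and
  `N_u_i` the days among workers classified **unexposed** to psychosocial
  risk. Exposure comes from the 35-item Management Standards Indicator
  Tool (seven dimensions: demands, control, management support, colleague
  support, role, relationships, change; higher = better conditions):
  workers whose overall score is at or below the first-quartile cutoff of
  a normative score distribution are exposed, those above it unexposed.

Groups whose questionnaire response rate is below 75% (configurable) are
excluded from the aggregates. Note that `(N − N_u)/N` is the *share of
absence days carried by exposed workers*; under a null effect it converges
to the exposure prevalence, not to zero — see `docs/methods.md`.

## Worked example

The package bundles the published inputs of the two case studies the model
was evaluated on (a 14-group public hospital, N=1014, and a 6-group public
administration unit, N=534):

```python
from stresscost import case_studies as cs

table = cs.hospital_salary_table()
print(round(table["management_physicians"].day_cost, 2))  # 301.9
print(round(table["health_staff"].day_cost, 2))           # 143.7

ch, absence_cost = cs.plastic_surgery_costing()
print(round(ch, 2), round(absence_cost))                  # 183.16 259543

hospital = cs.hospital_summary()
print(round(100 * hospital.mean_paf, 1))                  # 24.1
print(round(hospital.total_stress_cost))                  # 444670
admin = cs.admin_summary()
print(round(100 * admin.mean_paf, 1))                     # 16.2
print(round(admin.total_stress_cost))                     # 360044
```

A hospital physician's working day costs €301.90; the 25-worker
reconstructive-plastic-surgery group averages €183.16/day, so its 1417
absence days cost ≈€259.5k, of which 47.4% (its PAF) is attributed to
work-related stress. Across the hospital's 14 groups, stress-attributable
absence sums to ≈€445k (24.1% average PAF); across the administration
unit's 6 groups, ≈€360k (16.2%).

For your own data, run the pipeline end to end from the shell:

```
stresscost simulate demo/ --seed 1            # or bring your own CSVs
stresscost thresholds demo/normative_scores.csv --out thresholds.yaml
stresscost estimate --roster demo/roster.csv --absences demo/absences.csv \
    --questionnaire demo/questionnaire.csv --salary demo/salary.csv \
    --thresholds thresholds.yaml --out report.csv
```

`report.csv` mirrors the study tables: one row per group (absence days by
type, response rate, absence cost, PAF, stress cost) plus a Total/Average
block.

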