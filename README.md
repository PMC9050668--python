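# dogyears

Cohort life tables, bootstrap confidence intervals and longevity metrics for
companion-animal mortality registries.

Primary-care veterinary records are the richest source of death information
for companion dogs, but they arrive as free text and messy CSVs, and the
standard longevity summary — a single mean age at death — hides how life
expectancy changes with age. `dogyears` implements the full pipeline from
raw registry rows to published-style life tables:

* **screening** — flag candidate death cases in free-text clinical-note and
  treatment fields with a small search grammar (bare tokens, `prefix*`
  wildcards, `"quoted phrases"`, `"proximity terms" ~ k`, and
  `["conjunctive" and "terms"]`);
* **cleaning** — apply a deceased-only case definition: death inside an
  observation window, valid non-negative lifespan, recorded sex, with a
  reconciling exclusion log;
* **life tables** — complete (1-year-interval) cohort life tables with an
  open final interval, per stratum (sex, neuter status, Kennel Club breed
  group, breed), published only when every interval meets a minimum-count
  eligibility rule;
* **confidence intervals** — empirical bootstrap over individual animals,
  with eligibility-gated acceptance of iterations;
* **metrics** — threshold ages (when does life expectancy drop below 1.5
  years?), cross-stratum comparisons, demography summaries;
* **simulation** — a synthetic registry generator driven by parametric
  age-specific hazards (Gompertz–Makeham by default), with an observation
  window and a configurable birth-cohort growth trend that reproduces the
  *popularity bias* of deceased-only cohorts for fast-growing breeds.

## The model

For a fully observed cohort with exact ages at death, deaths are binned into
one-year intervals [x, x+1) and each interval carries

| symbol | meaning | definition |
|---|---|---|
| dₓ | deaths in the interval | count |
| lₓ | alive at exact age x | Σᵢ≥ₓ dᵢ |
| q̂ₓ | probability of dying in the interval | dₓ / lₓ |
| âₓ | mean fraction of the last year lived | mean(t − x) over deaths in the interval |
| Lₓ | animal-years lived in the interval | (lₓ − dₓ) + âₓ·dₓ |
| Tₓ | animal-years lived beyond x | Σᵢ≥ₓ Lᵢ |
| êₓ | life expectancy at x | Tₓ / lₓ |

The final interval [n, ∞) is open: q̂ₙ = 1 and êₙ = âₙ. A telescoping
identity makes êₓ exactly the mean residual lifespan of survivors to x, so
ê₀ is the cohort mean age at death. A stratum is published only if every
closed interval holds ≥ 3 deaths and the open interval ≥ 11 (configurable).
95% CIs come from resampling animals with replacement, rebuilding the table
per iteration, and keeping only iterations that satisfy the same rule.

## Worked example

The package ships the aggregate columns (dₓ and âₓ per interval) of a
published overall life table for UK companion dogs; everything else is
rederived from those two columns:

```python
>>> import dogyears as dy
>>> table = dy.load_reference_aggregates()
>>> round(table.e(0), 2), round(table.e(10), 2)
(11.23, 3.28)
>>> r = table.rows[0]
>>> r.d, r.l, round(r.q_hat, 3), r.a_hat
(514, 30563, 0.017, 0.42)
>>> dy.age_when_e_below(table, 1.5).label()
'14–15'
```

A newborn dog in this cohort can expect 11.23 years of life; a ten-year-old
another 3.28 years; life expectancy first drops below 1.5 years in the
14–15 age interval. The same numbers flow through the command line, here on
a simulated registry:

```sh
$ dogyears simulate -o records.csv --n 8000 --seed 42
wrote 1764 in-window records to records.csv
$ dogyears bootstrap records.csv -o overall_ci.csv --iterations 2000 --seed 42
accepted 2000/2000 iterations; e0 = 11.08 (10.95-11.22) -> overall_ci.csv
$ dogyears report overall_ci.csv --threshold 1.5
overall_ci: e0 = 11.08, e < 1.5 first in interval 12–13
```

Only 1,764 of the 8,000 simulated animals die inside the 2016–2020
observation window — the deceased-only case definition at work. The
bootstrap interval (10.95–11.22) brackets the generator's true life
expectancy at birth (≈ 11.0 for the default hazard).

`dogyears build records.csv -o out --schemes overall,sex,breed` writes one
full-precision CSV and one print-rounded "report" CSV per eligible stratum,
plus the exclusion log and a demography summary.

## Layout

```
src/dogyears/     records.py  screening.py  cohort.py  lifetable.py
                  bootstrap.py  metrics.py  synthetic.py  cli.py
                  data/         packaged aggregate fixture + breed lookup
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   modelling notes: estimators, conventions, limitations
```
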