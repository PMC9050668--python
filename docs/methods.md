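# Methods notes

These notes record the estimators, conventions and design choices behind
`dogyears`, in the spirit of a model-documentation page: what is computed,
under what assumptions, and where the genuinely open choices were made.

## Cohort life table estimator

The estimator operates on a *deceased-only* cohort: every analysis unit is
an animal with an exact (fractional) age at death. Nothing is censored —
animals alive at the end of the observation window simply never enter the
dataset. This is a hypothetical-cohort design: the table describes the
mortality experience of the animals that died in the window, as if they
were a birth cohort followed to extinction.

Deaths are binned into one-year intervals `[x, x+1)` (half-open, so an
exact integer lifespan falls at the start of its interval with fraction 0).
Per interval: deaths `d_x`; survivors to exact age x, `l_x = Σ_{i≥x} d_i`;
conditional death probability `q_x = d_x/l_x`; mean fraction of the last
year lived `a_x = mean(t − x)`; animal-years `L_x = (l_x − d_x) + a_x d_x`;
cumulative years `T_x = Σ_{i≥x} L_i`; life expectancy `e_x = T_x/l_x`. The
final interval `[n, ∞)` pools all deaths at ages ≥ n, so `l_n = d_n`,
`q_n = 1`, `a_n = mean(t − n)` (possibly > 1 year), `L_n = a_n d_n` and
`e_n = a_n`.

Two identities are exact and are asserted in tests to machine precision:
`T_x` telescopes to `Σ (t − x)` over lifespans ≥ x, so `e_x` is the mean
residual lifespan of survivors to x, and `e_0` is the cohort mean age at
death. A decreasing `e_x` profile is *not* a mathematical law; it is a
plausibility property expected under age-increasing hazards and is asserted
only on synthetic cohorts generated under such hazards.

**Closed intervals with no deaths.** `a_x` is undefined when `d_x = 0`;
the row records it as absent and `L_x = l_x` (everyone lives the whole
year). Published, eligibility-passing tables never contain such rows, but
the builder must not crash on arbitrary cohorts.

**Lifespan convention.** Lifespan = day count between birth and death
÷ 365.25. The day-count convention is not standardised in registry studies;
365.25 is the leap-safe epidemiological default and avoids locale-dependent
date arithmetic entirely.

## Final interval and eligibility

The start of the open interval is chosen by a tail-sum rule: `n` is the
*largest* age whose pooled tail `Σ_{i≥n} d_i` still holds at least
`min_last_interval` deaths (default 11). A stratum is *eligible* when,
additionally, every closed interval `0..n−1` holds at least
`min_per_interval` deaths (default 3, ensuring the `a_x` average has a
denominator above 1). Published practice states the two floors but not the
selection procedure for `n`; the tail-sum rule is this package's precise
formulation — it is well defined for every input and reproduces the
published tables' final intervals. No interval merging is attempted to
rescue ineligible strata; there is no published merging rule to follow.

Ineligible cohorts still yield a table, flagged `eligible=False`, rather
than raising: the bootstrap must evaluate eligibility once per resample and
exceptions-as-control-flow would be both slow and unclear. The CLI refuses
to publish ineligible strata and lists them instead.

## Bootstrap confidence intervals

The resampling unit is the individual animal: each iteration draws `n`
animals with replacement, rebuilds the complete table (including its own
final-interval choice), and is accepted only if the rebuilt table is
eligible. Accepted iterations' `e_x` values form the empirical distribution
from which per-age bounds are taken.

* **Interval type.** Percentile bounds (linear interpolation between order
  statistics) are the default; the basic/pivotal interval is available via
  `method="basic"`. With 10,000 iterations and cohorts in the tens of
  thousands the two nearly coincide.
* **Rejected iterations** are discarded, not replaced, so the accepted
  count can fall below the requested count; `topup=True` redraws until the
  requested number of accepted iterations is reached (capped at 10× to
  guarantee termination). Replacement behaviour is not standardised in the
  source workflow; discarding is the literal reading and is the default.
* **Gating presumes an eligible stratum.** When the cohort's own point
  table is ineligible (e.g. ad-hoc cohorts with empty young intervals), the
  rule is evidently not in force for it, and gating would reject every
  replicate; such cohorts are bootstrapped ungated, with a log note.
* **Short replicate tables.** A replicate's table can end below the point
  table's last age. Ages present in fewer than 50% of accepted replicates
  get no bounds (logged): a quantile over a vanishing support says more
  about the support than about uncertainty. The 50% floor is this package's
  choice; the per-interval count floors exist precisely to keep the tail
  stable, so the rule rarely triggers on eligible strata.
* **Implementation.** Because the table depends on the resample only
  through the multiset of lifespans, individual resampling is implemented
  as a multinomial draw over distinct lifespan values; per-interval death
  counts and lifespan sums then come from two matrix products. This is an
  exact reformulation, not an approximation, and makes 10,000 iterations on
  a 30k pseudo-cohort run in well under a second. Results are
  bit-reproducible for a fixed seed.

## Screening grammar

Free-text screening mirrors common clinical-search-engine semantics: bare
terms match whole tokens case-insensitively; a trailing `*` makes a prefix
match; quoted multiword terms match consecutive tokens; `~k` proximity is
treated as *unordered* with up to k intervening tokens; bracketed `and`
requires all sub-terms anywhere in the field. Tokenisation is case-folding
with punctuation/whitespace as separators. Whether production search
engines match bare terms as tokens or substrings varies by vendor; token
matching is the default (avoiding false hits inside longer words, e.g.
`doa` inside other words), with a `substring=True` switch on the matcher.
Note terms apply to the clinical note, treatment terms to the treatment
field; the default lists (15 and 6 terms) ship as configuration. The
compiled matcher is property-tested against an exhaustive brute-force
token-window scanner.

## Cleaning and stratification

Exclusions apply in a fixed order — outside window, negative lifespan,
missing birth/death, missing sex — and each record is counted once under
the first applicable reason, making logs reproducible; the log always
reconciles (`included + excluded = input`). The observation-window check
runs first and only needs the death date, so a record dead outside the
window is logged as such even if other fields are also missing. Records
with a death date but no birth date are excluded at cleaning (reason
`missing_birth_or_death`); there is no imputation of dates or sex.

Breed classification is two-level and purely configuration-driven: a
recognised-breed set defines purebred vs crossbred (empty breed →
unrecorded), and a breed→group map assigns Kennel Club groups; recognised
breeds without a group are "non-KC recognised". Neuter status is taken as
recorded at death (a single dichotomy) — animals neutered late in life
carry the same label as those neutered young, a known interpretive caveat
of such data, not a modelling choice this package can repair.

Demography percentages use per-scheme denominators: sex/neuter percentages
are among animals with the attribute recorded, KC-group percentages among
animals of KC-grouped breeds, while "unrecorded" breed is itself a reported
category within breed purity. This matches how registry demography tables
are conventionally presented.

## Synthetic registry generator

The generator exists so the entire pipeline — screening included — runs and
validates with no external data. Each animal gets a birth date from a
uniform or exponentially growing (`rate g` per year) birth process over a
configurable span, a lifespan drawn from a parametric hazard, a death date
= birth + lifespan, and is *emitted only if the death falls inside the
observation window*, emulating the deceased-only case definition. Clinical
notes and treatment lines carry phrases from the screening-term families so
the screen has true positives; configurable fractions get missing sex or a
missing birth date.

Hazard forms: constant (exponential lifespans), Gompertz–Makeham
(`λ + a·e^{bt}`), and piecewise interval probabilities (uniform within the
interval). Gompertz–Makeham sampling inverts the cumulative hazard exactly
via the Lambert W function, evaluated through an asymptotic-plus-Newton
path in log space where the argument overflows — no grid discretisation.
`true_life_expectancy` provides the analytic oracle: closed form for the
constant hazard, interval summation for piecewise, adaptive quadrature
(absolute tolerance 1e-8) for Gompertz–Makeham.

The default demonstration schedule (λ = 0.01, a = 5e-4, b = 0.55) yields
ê₀ ≈ 11.0 years with a death-probability profile that is flat and low
before age ~5 and rises steeply after ~6 — the shape seen in companion-dog
registries. It is a demonstration configuration, chosen once for realism;
it is not fitted to any dataset and no breed-specific calibrations are
shipped.

**What the generator does not emulate:** registration gaps (puppy deaths
before first registration), emigration/loss to follow-up, duplicate or
transferred records, breed-string misspellings, and seasonality. Passing
tests on synthetic registries therefore validate the *estimators and
plumbing*, not the representativeness of any real registry.

**Popularity bias.** With `g > 0` the birth process grows, in-window deaths
over-represent young animals, and the fitted ê₀ falls below the hazard's
true value — the mechanism that depresses apparent life expectancy for
rapidly popularised breeds in deceased-only cohorts. The package asserts
the direction of this effect, not its magnitude, which depends on `g`, the
window and the hazard jointly.

## Problem sizes in the test suite

Oracle-equivalence and round-trip properties run on cohorts up to n = 500;
parameter recovery uses one cohort of n = 100,000 (within 3 Monte-Carlo
SEs of the analytic values at ages 0, 5, 10); interval coverage uses 200
cohorts of n = 2,000 with 500 bootstrap iterations each, judged against a
3σ binomial band around 95%; the aggregate-reconstruction checks are exact
or 2-dp comparisons on the packaged 30,563-animal table. These sizes were
chosen so each check's Monte-Carlo error is small relative to the tolerance
it is judged against while the whole suite stays quick to run.

## Numerical conventions

* Quantiles: linear interpolation between order statistics, everywhere.
* Printed ("report") renderings round probabilities to 3 dp and years to
  2 dp; data renderings keep full precision; round-tripping the data
  rendering is lossless.
* Aggregate tables are rebuilt from `d` and `a` alone; any derived columns
  present in the file are cross-checked within a stated tolerance and
  mismatches are logged, not fatal — published tables print rounded values,
  and the packaged fixture's `a` column is itself a 2-dp transcription
  (contributing < 0.005 yr to each rebuilt `e_x`).
* Dates are ISO-8601 only in the canonical dialect; other formats require
  an explicit dialect mapping. Unparseable dates become absent values with
  a warning at read time and an exclusion at cleaning time.

## Known limitations

* Deceased-only cohorts answer "how long did dogs that died live?", which
  approximates population life expectancy only under demographic
  stationarity; the popularity-bias simulation quantifies the failure mode.
* Life expectancy from euthanased animals blends clinical and owner
  decisions; the `death_mechanism` field is carried through but not
  modelled.
* No abridged (multi-year) intervals, no analytic (Chiang-style) variances,
  no BCa/studentised bootstrap intervals, and no statistical tests of
  between-stratum differences — comparisons are presented as intervals.
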