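# Methods

## Setting and measures

The package implements the new-user (washout) design for nationwide
pharmacy dispensing registries. Dispensings of blood glucose-lowering
drugs (ATC A10; A10A insulins, A10B oral antidiabetics, "OAD") serve as a
proxy for drug-treated diabetes. Three outcome classes are tabulated per
person and calendar year: any A10, OAD, and "insulins only", the last a
proxy for Type 1 diabetes.

Window conventions, chosen once and applied everywhere:

* "m months before/after" a date is a calendar-month shift of that date,
  same day of month clamped to month end (e.g. 31 Jan + 1 month = 28/29
  Feb) — exactly reproducible and matching the month-denominated way such
  windows are specified, rather than a fixed day count.
* The incidence washout is `[t₀ − w, t₀)`: the anchor fill itself never
  disqualifies. The insulins-only OAD exclusion window is closed at both
  ends, `[t₀ − w, t₀ + l]` for prevalence and `[t₀, t₀ + l]` on the
  lookforward side for incidence. In particular an OAD fill on the anchor
  date makes the person *not* insulins-only in both measures: same-day
  insulin + OAD dispensing signals combination therapy, and the convention
  also preserves the invariant that an incident insulins-only user is a
  prevalent insulins-only user of the same year.
* Re-incidence is allowed: a person whose fills resume after a gap longer
  than the washout is incident again. The definition is a property of the
  year, not of the person's lifetime.
* The incident-OAD washout is anchored at the first **OAD** fill of the
  year (not the first A10 fill), and any A10 fill inside it — including
  insulin — disqualifies, a literal reading of "no blood glucose-lowering
  drug in the previous w months".
* Age for stratification is the age attained in the calendar year
  (year − birth year), in 10-year bands 0–9 … 80+.

**Observability.** A (year, measure) pair is reportable only when every
possible anchor window in that year lies inside registry coverage; the
check is done at year level, so a whole column is either reportable or
explicitly marked unobservable (flags stay unset and tables carry an
`observable = False` marker — never a silent zero). With coverage
2004–2011 and 24/12-month windows this yields incidence 2006–2011 and
insulins-only measures 2006–2010; the leading years act as a run-in and
the final year lacks lookforward for insulins-only.

**Follow-up metrics.** Persistence is the share of incident users with a
second fill of the defining class within 12 months of the anchor.
Discontinuation ("stopped treatment") is not given a canonical definition
in registry practice; here a user has stopped within a 24-month horizon
when the final 12 months of that horizon contain no insulin fill. This
separates transient users cleanly from persistent ones under any refill
interval up to a year, and is the package's own operationalisation.

## Estimation

Person-years for year *y* and stratum *s* are the arithmetic mean of the
January-1 populations of *y* and *y + 1* restricted to *s* (the usual
mean-population approximation for a fully covered registry; the same age
filter is applied at both dates). Incidence per 100 000 person-years
carries a Wald interval on the rate scale, `rate · (1 ± z/√count)`, with
`z = 1.96` at the default α = 0.05; a log-scale Wald variant is available
behind a flag and rounds identically on all published cells checked. A
zero count uses the rule of three for the upper bound. The engine stores
full precision; reports round half away from zero.

The trend model is Poisson log-linear with log person-year offset: linear
calendar year (centred at the midpoint of the fitted years — pure
conditioning, the IRR per year is invariant to centring), categorical age
band (reference: youngest band present), categorical sex (reference:
female), optional year×age interaction. It is fitted by IRLS with the
canonical log link; a step is halved until the log-likelihood is
non-decreasing, convergence is declared when the relative log-likelihood
change or the score norm falls below 1e-10 (default), and the covariance
is the inverse information at the MLE. Age bands with zero events in
every cell are dropped before fitting, since their dummy coefficients are
not identified (the MLE diverges). Stratum-specific trends are obtained
by fitting within the stratum with a linear year term rather than by
reading interaction contrasts. Overdispersion is not modelled; a Pearson
dispersion statistic is attached to each fit as a diagnostic only.
Nested models are compared by likelihood ratio against the χ² upper tail.

## Synthetic registry

The simulator generates the study conditions end to end so every stage of
the pipeline has ground truth:

* **Population**: a closed cohort (default 50 000 persons, roughly 1/100
  of a small national population, so the full pipeline runs in seconds),
  sexes equiprobable, ages 0–89 with a pyramid flat to age 50 and
  exponentially declining thereafter (scale 15 years). January-1 counts
  are emitted for every denominator year. No births, deaths or migration.
* **Onset**: exponential waiting times with piecewise-constant yearly
  hazards by age band and sex (defaults rising from 5 to ~800 per 100 000
  person-years, women slightly higher before age 40, men after),
  multiplied by a calendar trend `annual_irr^(year − start)`. Onsets are
  drawn from 10 years before coverage so baseline prevalent users enter
  with left-truncated fill streams and exercise the run-in logic.
* **Modality**: OAD only / OAD-then-insulin / insulins only with default
  mix 0.73 / 0.17 / 0.10, approximating the observed national split of
  incident users across the three classes; switchers move to insulin
  after an exponential delay (mean 4 years).
* **Fills**: gamma-distributed refill intervals (mean 90 days, CV 0.3)
  from onset until attrition (exponential, 1%/year), discontinuation or
  coverage end; ATC codes are drawn per person from small insulin and OAD
  code pools. Records are truncated to coverage.
* **Gestational diabetes**: a configurable share (default 0.6, the
  magnitude reported for young women in national data) of female insulin
  starters aged 20–44 stop after a uniform 4–9 months; their true stop
  date is recorded even when it falls past coverage.
* **PCOS**: women 18–45 accrue metformin-only episodes (50 per 100 000
  person-years, mean duration 2 years) with no diabetes truth record,
  planting the known off-label misclassification artefact.

All draws flow from a single seeded generator, so identical configs give
byte-identical output. With gestational, PCOS and attrition switched off
the classifier's incident counts equal the truth table exactly on
observable years (every onset produces an immediate first fill and refill
gaps cannot reach the washout length) — asserted in the tests.

What the simulator does **not** emulate: real demography (births, deaths,
migration), seasonality of dispensing, stockpiling and variable package
sizes, institutional (nursing-home) supply recorded without person
identity, regional variation, and any correlation between adherence and
age or severity. Passing tests therefore demonstrate correctness of the
classification and estimation machinery under the stated generating
process, not calibration to any real population.

## Validation studies

`glucotrend.studies` packages the calibration experiments (also run by
`scripts/acceptance.py`): each takes a master seed and spawns one child
seed per replicate.

* **Washout monotonicity** — extending the washout 24 → 72 months never
  increases incident or prevalent insulins-only counts, over 100 random
  registries of 150 persons; planted OAD→insulin switchers (fills 5 years
  before their insulin anchor) produce strict decreases.
* **IRR recovery** — 50 registries of 20 000 persons with a planted IRR
  of 0.95/year; the 95% Wald interval from the year + age + sex model
  covers the truth in ≈ 95% of replicates. The artefact mechanisms are
  switched off here: PCOS episodes carry no calendar trend and would
  dilute the planted IRR toward 1, turning the experiment into a
  robustness study rather than a recovery study.
* **LR test size/power** — counts drawn from a fixed no-interaction
  model at national-table scale (12 × 6 cells, person-years 2 × 10⁵);
  rejection at α = 0.05 stays near nominal over 200 replicates, and a
  planted year×age tilt of 0.04 per band step is detected essentially
  always.
* **Wald interval coverage** — 500 Poisson draws at expected count 900:
  coverage within 93–97%.
* **Gestational recovery** — onsets confined to women under 40 with
  insulins-only modality and a planted 60% transient share; the
  discontinuation metric recovers it to within binomial error.

## Numerical and degenerate-input choices

* Ties on a day: multiple same-day fills are handled by closed/half-open
  interval arithmetic on sorted timestamp arrays; record input order
  never affects results.
* Empty inputs: an empty registry classifies to an empty status table;
  empty strata make the follow-up fractions `None` rather than 0.
* Rank-deficient trend designs raise an error naming the suspect columns;
  non-convergence returns the fit flagged `converged = False` and the IRR
  accessor refuses it.
* Zero person-years cells are dropped from model tables; zero population
  denominators raise.
* Rounding for display is half-away-from-zero; published tables mix
  rounding and truncation, so exact-reproduction checks are limited to
  the cells where the Wald recomputation matches the print (37 of 51),
  with the rest verified to within one unit.

## Limitations

Type 1 / Type 2 classification beyond the insulins-only proxy, linkage to
diagnoses, dose (DDD) volumes, institutional supply shares, migration and
mortality adjustment, and age standardisation are out of scope. The Wald
rate interval is slightly anticonservative at very small counts; the
rule-of-three bound covers only the zero-count case.
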