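# Methods

This note documents the statistical models implemented in `pharmepi`, the
assumptions behind them, the simulation conditions used for validation, and
the choices made where the design was genuinely open.

## Spontaneous-report arm

### Data model and preprocessing

A spontaneous reporting system collects voluntary reports, each listing
free-text drug names, event terms, and sparse demographics. Reports lack
denominators and timelines, so all inference is *disproportionality*: does
the event appear more often than expected among reports mentioning the
drug?

Preprocessing contracts (`report_store`):

* **Name normalisation** maps raw strings (trade names, salts,
  abbreviations) to generic names via a supplied two-column map,
  case-insensitively; synonyms collapse to a single set element. Unmapped
  names are kept verbatim by default — silently dropping them would shrink
  denominators in a drug-dependent way — and are listed in a normalisation
  report. A `drop` policy is available.
* **Deduplication** keeps one record per case id: the highest version, ties
  broken by lexicographically greatest report id. Real systems use richer
  heuristics (field-matching across manufacturers); the strategy here is
  deterministic and swappable, and the downstream statistics depend only on
  the one-record-per-case invariant.
* **Event queries** are explicit term sets matched exactly after trimming
  and case-folding — a stand-in for a narrow-scope standardised MedDRA
  query. No ontology traversal is attempted; the term list is the query.

### Reporting odds ratio

For the 2×2 table (a = drug & event, b = drug only, c = event only,
d = neither):

    ROR = ad / bc
    SE  = sqrt(1/a + 1/b + 1/c + 1/d)        (on the log scale)
    CI  = exp(ln ROR ± z_{0.975} · SE)
    Z   = ln ROR / SE

The **Haldane–Anscombe correction** adds 0.5 to all four cells before any
arithmetic, unconditionally — not only when a cell is zero — so that every
drug, however rare, yields a finite estimate and the statistic is a smooth
function of the counts. Requesting uncorrected statistics on a zero-cell
table raises an explicit error rather than returning an infinity.

Screens default to a minimum of 3 pre-correction cases (the conventional
pharmacovigilance floor; configurable) and report unadjusted Z scores, with
an optional Benjamini–Hochberg adjustment off the main path. Significance
is the Wald criterion |Z| ≥ 1.96, equivalent to the 95% CI excluding 1
because both use the same SE.

### Concomitant screening and cross-database enrichment

The interaction screen restricts the report set to users of a base drug
class (any member present) and runs the identical 2×2 machinery per
co-reported drug. "Concomitant" means co-listed on the same report;
spontaneous reports carry no dosing timeline, so no temporal overlap can be
required. A drug "significantly decreases" the event's ROR when its
corrected upper CI bound at level α falls below 1 (Z ≤ −1.96 at α = 0.05).

Cross-database enrichment intersects the direction-consistent significant
sets of ≥ 2 independently collected databases. Only the significance
criterion is intersected — no additional effect-size floor — and results
are ordered by mean ln ROR across databases. The intersection is monotone:
tightening α or adding databases can only shrink the result.

## Claims arm

### Cohort construction

Time is integer days from an arbitrary epoch; every interval is half-open
`[start, end)` **except** the concomitant-use window, which is inclusive at
both ends (−7 to +30 days around the index prescription, matching the
clinical definition "from 7 days before to 30 days after").

* **Run-in (wash-out):** 180 days. Patients with an outcome diagnosis, an
  exposure prescription, or a concomitant-drug prescription during
  `[enroll_start, enroll_start + 180)` are excluded, as are patients
  enrolled for less than 180 days. Route is ignored here: any prior use
  disqualifies a "new user". The 180-day default operationalises exclusion
  of first-events clustered in months 0–5 of enrollment, with incidence
  stabilising from month 6; it is configurable.
* **Index dating (drug-induced design, `"fq"`):** index = day of the first
  *systemic* exposure-code prescription after run-in. A prescription is
  systemic unless its route is in a configurable topical-route list
  (default: topical, ophthalmic, otic); patients whose exposure
  prescriptions are all topical never enter. The exposed arm has a systemic
  concomitant-code prescription within the −7/+30 window. Repeat
  prescriptions after index are ignored (first-episode new-user design).
* **Index dating (age-restricted design, `"older"`):** the concomitant drug
  is itself the exposure. Exposed patients index at their first systemic
  prescription after run-in. How the comparator clock should start is
  genuinely open; the choice here is **comparator index = end of run-in**,
  which gives both arms the same eligibility history and is configurable in
  one place. An age floor (`min_age`) restricts the population.
* **Survival records:** time = min(first outcome on/after index,
  disenrollment, index + follow-up) − index, event = 1 iff the minimum is
  an outcome day (ties resolve to the event). An outcome on the index day
  is kept as time 0, event 1. Follow-up is 60 days in the drug-induced
  design (double the 30-day risk period) and 180 days in the age-restricted
  design.
* **Covariates** are assembled strictly pre-index, over
  `[index − 180, index)`: a diagnosis on the index day itself is outcome
  territory, not baseline. The lookback mirrors the run-in length.

The crude "total incidence proportion" is events/patients per arm with an
exact Clopper–Pearson interval; it deliberately ignores censoring and is
reported alongside, never instead of, the survival estimates.

### Propensity matching

Exposure is modelled by unpenalised logistic regression on the baseline
covariates (a convex fit, hence deterministic); perfect or quasi-separation
raises an error advising covariate reduction rather than returning a
degenerate model. Matching is greedy 1:1 nearest-neighbor without
replacement, visiting exposed patients in seeded-random order; a pair forms
only within the caliper. The default caliper is **0.2 × SD of the logit
propensity score** — the conventional reading of "a 0.2 caliper width" —
with an absolute probability-scale caliper behind a flag, since the scale
is often left unstated in applied reports. An optional exact-match
constraint (e.g. on the exposure drug subtype) restricts candidate pairs.
Optimal (non-greedy) matching is out of scope.

Balance is reported as standardized mean differences (difference in means
over the pooled SD) before and after matching, with χ² tests for binary
covariates and Wilcoxon rank-sum (default) or Welch t-tests for continuous
ones on the matched sample. Zero-variance covariates report SMD 0 with a
degeneracy flag.

### Survival analysis

Kaplan–Meier estimation, the two-group log-rank test, and Cox regression
are delegated to `lifelines`; the module adds the daily number-at-risk
table (subjects with time ≥ t for each day, the risk table printed under
clinical incidence plots) and a one-parameter Breslow partial-likelihood
Newton solver of its own. The Breslow solver exists because the two-group
log-rank statistic is algebraically the Cox score test at β = 0 under
Breslow tie handling; the test suite asserts this identity numerically on
tie-free data, pitting the two independent implementations against each
other. Efron is the default ties method for fitting (more accurate with
ties); the Breslow variant is provided for the group-only model. Monotone
likelihoods (an arm without events) raise an explicit error. Follow-up
truncation happens once, in the cohort builder — survival operations never
re-censor.

## Synthetic-data generator

The generator exists so every stage can be validated against known truth;
it is a first-class, tested module, not a fixture.

**Reports.** Each report draws catalog drugs independently (per-drug
prevalence), plus a Poisson number of background co-medications. The
outcome indicator is logistic: baseline odds are multiplied by the OR of
every present drug and every present interacting pair. The
odds-multiplicative form makes an injected OR the exact estimand of the
downstream ROR tabulation, so recovery tests compare like with like.
Duplicates are injected as same-case-id copies with fresh report ids,
exactly the structure deduplication removes. Drug names are emitted
already-generic (name normalisation is tested on handcrafted fixtures
instead).

**Claims.** Per patient: an enrollment span inside a 900-day window (start
in the first tenth, length uniform down to 60 days, giving enrollment
churn), normal age, independent binary/continuous covariates, and a
logistic exposure model whose covariate log-odds create confounding
whenever the same covariates carry outcome log-hazards. Binary covariates
are materialised as recurring chronic-condition diagnosis codes (every 90
days) so the cohort builder genuinely reconstructs them from the lookback
window. The outcome is a **recurrent event process** with
piecewise-constant intensity: `baseline_hazard · exp(covariate effects)`
before a systemic exposure day and additionally
`· exp(exposure_log_hr [+ comod_log_hr when concomitant])` after it. Two
properties follow: the process is memoryless, so the hazard of the *first
event after any index date* equals the current intensity and the Cox
estimand from index equals the injected HR; and recurrence avoids the
immortal-cohort artifact a single-latent-event design would create for
patients whose only event falls between run-in end and index. Censoring
arises only from disenrollment or analysis-imposed follow-up; there are no
competing risks, matching the single-endpoint design.

Both simulators are pure functions of (config, seed).

**What the generator does not emulate:** real MedDRA/ICD ontologies,
correlated co-prescription structure (drugs are independent given the
Poisson polypharmacy count), seasonal or calendar effects, reporting biases
(stimulated reporting, notoriety), coding errors, and time-varying
covariates. Passing recovery tests therefore demonstrates correctness of
the *methods* under their stated assumptions, not robustness to the messiness
of real FAERS or MarketScan extracts.

## Validation conditions

The reference scenarios (`pharmepi.scenarios`) fix one documented set of
study conditions:

* *Null calibration:* 30 drugs at 8% prevalence, 10% baseline event rate,
  4,000 reports × 10 replicates (expected a-cell ≈ 32, large enough for the
  Wald Z to be near-normal). The fraction of |Z| ≥ 1.96 flags is compared
  to 5% at a three-standard-deviation binomial tolerance. The correction
  makes the screen slightly conservative at small counts — expected, and
  visible in rates just under 5%.
* *Interaction recovery:* base drug OR 3.0 at 15% prevalence, protective
  interaction OR 0.3 with a 15%-prevalence concomitant, eight null
  co-medications, 20,000 reports per database, three databases per
  replicate.
* *Confounded claims:* three binary comorbidities (prevalence 0.25–0.30)
  each raising exposure odds (log-odds 0.8–1.2) and outcome hazard (log HR
  0.7–0.9); baseline hazard 4 × 10⁻⁴/day; true exposure HR 0.6. At 8,000
  patients per replicate the crude HR is biased to ≈ 1.0 while matching
  recovers ≈ 0.6.
* *End-to-end:* the same population at 20,000 patients, full pipeline.

Replicate counts (10–50) and population sizes were chosen so each check has
clear power while the whole validation runs in minutes on one core.

## Numerical notes and limitations

* The normal 97.5% quantile is used at full precision (1.95996…), not 1.96.
* Matching sorts comparator scores once and scans only the caliper window,
  so large cohorts match in O(n log n) plus the window width.
* Propensity scores are clipped to (1e−12, 1 − 1e−12) before the logit
  transform; coefficients above 30 in absolute value are treated as
  quasi-separation.
* The Cox HR is non-collapsible: with heterogeneous covariate hazards, the
  *marginal* matched-cohort HR is attenuated toward 1 relative to the
  covariate-conditional HR the generator injects (≈ 0.66–0.69 when the
  conditional truth is 0.6 under the reference conditions). Validation
  therefore asserts CI coverage and bias *reduction* relative to the crude
  estimate, not exact equality.
* Greedy matching is order-dependent; the seeded-random order makes runs
  reproducible, and the caliper bound holds for every order.
* The deduplication tie-break (report id) is lexicographic, which is only
  meaningful when report ids sort consistently within a case — true for
  all supported inputs and the simulator.
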