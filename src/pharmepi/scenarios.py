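"""Reference simulation scenarios used for validation and demonstration.

Each function returns a configuration describing one canonical study
condition: a null report set for calibration, a report set with one strongly
protective drug–drug interaction, a claims population with confounded
protective exposure, and so on.  Validation code and the worked examples use
these so that the package is always exercised under one documented set of
conditions.
"""

from __future__ import annotations

import math

from .cohort_builder import CohortSpec
from .interaction_screen import DrugClass
from .report_store import EventQuery
from .synthetic_data import ClaimsSimConfig, CovariateSpec, SRSimConfig

OUTCOME_TERM = "tendon disorder"
OUTCOME_CODE = "M76.9"

TENDON_QUERY = EventQuery(name="tendinopathy", terms=frozenset([OUTCOME_TERM]))
FQ_CLASS = DrugClass(name="fluoroquinolones",
                     members=frozenset(["levofloxacin", "ciprofloxacin"]))


def null_reports(seed: int, n_reports: int = 4_000) -> SRSimConfig:
    """All drug–event odds ratios 1: a calibration set for the signal screen.

    30 drugs at 8% exposure prevalence each, 10% baseline event rate; with
    ~4,000 reports the expected a-cell is ~32, large enough for the Wald Z
    to be approximately standard normal under the null.
    """
    return SRSimConfig(
        n_reports=n_reports,
        drug_catalog={f"drug_{i:02d}": 0.08 for i in range(30)},
        baseline_event_prob=0.10,
        polypharmacy_rate=0.0,
        outcome_term=OUTCOME_TERM,
        seed=seed,
    )


def interaction_reports(seed: int, n_reports: int = 20_000,
                        protective_or: float = 0.3) -> SRSimConfig:
    """One protective base-drug x concomitant interaction among null drugs.

    The base drug (levofloxacin) triples the outcome odds; co-reported
    dexamethasone multiplies them by ``protective_or``.  Eight null
    co-medications at similar prevalence provide the false-positive pool.
    """
    catalog = {"levofloxacin": 0.15, "dexamethasone": 0.15}
    catalog.update({f"null_{i:02d}": 0.12 for i in range(8)})
    return SRSimConfig(
        n_reports=n_reports,
        drug_catalog=catalog,
        polypharmacy_rate=0.5,
        baseline_event_prob=0.10,
        drug_event_or={"levofloxacin": 3.0},
        interaction_or={("levofloxacin", "dexamethasone"): protective_or},
        outcome_term=OUTCOME_TERM,
        seed=seed,
    )


def confounded_claims(seed: int, n_patients: int = 8_000,
                      true_hr: float = 0.6) -> ClaimsSimConfig:
    """Protective exposure confounded by three comorbidities.

    Each comorbidity raises both the probability of exposure (log-odds 0.8
    to 1.2) and the outcome hazard (log HR 0.7 to 0.9), so the crude hazard
    ratio is biased far toward the null while the true effect is
    ``true_hr``.  Baseline hazard 4e-4/day gives a ~7% 180-day incidence in
    an unexposed average patient.
    """
    return ClaimsSimConfig(
        n_patients=n_patients,
        covariate_spec=(
            CovariateSpec("cancer", "binary", prevalence=0.30, exposure_log_odds=1.2),
            CovariateSpec("ckd", "binary", prevalence=0.25, exposure_log_odds=1.0),
            CovariateSpec("diabetes", "binary", prevalence=0.30, exposure_log_odds=0.8),
        ),
        covariate_log_hr={"cancer": 0.9, "ckd": 0.8, "diabetes": 0.7},
        exposure_intercept=-2.0,
        baseline_hazard=4e-4,
        exposure_log_hr=math.log(true_hr),
        outcome_code=OUTCOME_CODE,
        seed=seed,
    )


def claims_cohort_spec(cfg: ClaimsSimConfig, follow_up_days: int = 180) -> CohortSpec:
    """Cohort design treating the simulated exposure as the drug of interest.

    Uses the age-restricted-style design in which the study drug defines the
    exposed arm's index date and comparators index at the end of run-in.
    """
    return CohortSpec(
        outcome_codes=frozenset({cfg.outcome_code}),
        exposure_codes=frozenset(),
        comod_codes=frozenset(cfg.exposure_codes),
        follow_up_days=follow_up_days,
    )


CLAIMS_COMORBIDITY_CODES = {
    "cancer": frozenset({"DX_CANCER"}),
    "ckd": frozenset({"DX_CKD"}),
    "diabetes": frozenset({"DX_DIABETES"}),
}
CLAIMS_FEATURES = ["dx_cancer", "dx_ckd", "dx_diabetes"]


def mixed_claims(seed: int, n_patients: int = 500) -> ClaimsSimConfig:
    """A small heterogeneous store exercising every cohort-builder rule:

    topical prescriptions, concomitant co-prescriptions at assorted offsets,
    comorbidity diagnoses, early disenrollment, and a harmful exposure.
    """
    return ClaimsSimConfig(
        n_patients=n_patients,
        exposure_intercept=-0.5,
        route_topical_fraction=0.15,
        comod_prob=0.5,
        baseline_hazard=5e-4,
        exposure_log_hr=0.5,
        covariate_spec=(CovariateSpec("diabetes", "binary", prevalence=0.2),),
        outcome_code=OUTCOME_CODE,
        seed=seed,
    )
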