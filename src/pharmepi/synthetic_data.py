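"""Synthetic spontaneous reports and claims with known ground-truth effects.

Real spontaneous-report databases (FAERS, JADER, CVARD) and claims databases
(MarketScan) are proprietary; this module generates stand-ins whose causal
structure is known exactly, so every downstream stage — disproportionality,
interaction screening, cohort building, matching, survival — can be tested
for effect recovery and null calibration.

Report model
    Each report carries an independent draw of catalog drugs (per-drug
    exposure probability), plus a Poisson number of background co-medications.
    The outcome indicator is logistic: baseline odds are multiplied by the
    odds ratio of every present drug and of every present interacting drug
    pair.  Because the model is odds-multiplicative, an injected OR is the
    exact estimand of the downstream reporting odds ratio (at low outcome
    and exposure prevalence the 2x2 collapse is unconfounded in expectation).
    Duplicate records are injected as same-case-id copies with a fresh
    report id, matching the deduplication contract.

Claims model
    Per patient: an enrollment span inside a configurable window, a normal
    age, independent binary/continuous covariates, a possibly confounded
    exposure prescription (logistic in the covariates; topical route with a
    configurable fraction), an optional concomitant prescription near the
    exposure day, and a recurrent outcome process whose intensity is
    ``baseline_hazard * exp(covariate effects)`` before exposure and
    additionally ``* exp(exposure_log_hr [+ comod_log_hr])`` from the day of
    a systemic exposure prescription onward.  Because the process is
    memoryless with piecewise-constant intensity, the hazard of the first
    outcome after any index date equals the current intensity, so the Cox
    estimand from the index date equals the injected hazard ratio.  Events
    after disenrollment are unobserved.  Censoring arises only from
    disenrollment or analysis-imposed follow-up.

Everything is a pure function of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_builder import ClaimsStore
from .report_store import ReportRecord, ReportSet

NOISE_EVENTS = ("nausea", "headache", "rash", "dizziness", "pyrexia")


class ConfigurationError(ValueError):
    """An invalid simulator parameter, with the offending field named."""


def _require(ok: bool, message: str) -> None:
    if not ok:
        raise ConfigurationError(message)


@dataclass(frozen=True)
class SRSimConfig:
    """Parameters of the spontaneous-report simulator.

    ``drug_catalog`` maps generic name -> per-report exposure probability;
    ``drug_event_or`` and ``interaction_or`` inject marginal and pairwise
    odds ratios on the outcome (absent drugs default to OR 1);
    ``polypharmacy_rate`` is the Poisson mean of extra background
    co-medications per report; ``duplicate_rate`` injects that fraction of
    same-case duplicate records.
    """

    n_reports: int = 10_000
    drug_catalog: dict[str, float] = field(
        default_factory=lambda: {f"drug_{i:02d}": 0.05 for i in range(20)}
    )
    polypharmacy_rate: float = 1.0
    baseline_event_prob: float = 0.02
    drug_event_or: dict[str, float] = field(default_factory=dict)
    interaction_or: dict[tuple[str, str], float] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    n_background_drugs: int = 30
    outcome_term: str = "tendon disorder"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_reports > 0, "n_reports must be positive")
        _require(
            0.0 < self.baseline_event_prob < 1.0,
            "baseline_event_prob must lie in (0,1)",
        )
        _require(self.polypharmacy_rate >= 0, "polypharmacy_rate must be >= 0")
        _require(
            0.0 <= self.duplicate_rate < 1.0, "duplicate_rate must lie in [0,1)"
        )
        for name, p in self.drug_catalog.items():
            _require(0.0 < p < 1.0, f"drug_catalog[{name!r}] probability must lie in (0,1)")
        for name, o in self.drug_event_or.items():
            _require(o > 0, f"drug_event_or[{name!r}] must be > 0")
        for pair, o in self.interaction_or.items():
            _require(o > 0, f"interaction_or[{pair!r}] must be > 0")


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline covariate: distribution plus its pull on exposure.

    ``kind="binary"`` uses ``prevalence``; ``kind="continuous"`` uses
    ``mean``/``sd``.  ``exposure_log_odds`` enters the logistic exposure
    model (confounding arises when the same covariate also has a log hazard
    ratio in the outcome model).  Binary covariates are materialised in the
    claims as recurring diagnosis records with code ``dx_code`` so the
    cohort builder can reconstruct them from the lookback window.
    """

    name: str
    kind: str = "binary"
    prevalence: float = 0.2
    mean: float = 0.0
    sd: float = 1.0
    exposure_log_odds: float = 0.0

    @property
    def dx_code(self) -> str:
        return f"DX_{self.name.upper()}"

    def __post_init__(self) -> None:
        _require(self.kind in ("binary", "continuous"),
                 f"covariate {self.name!r}: kind must be binary or continuous")
        if self.kind == "binary":
            _require(0.0 < self.prevalence < 1.0,
                     f"covariate {self.name!r}: prevalence must lie in (0,1)")
        else:
            _require(self.sd > 0, f"covariate {self.name!r}: sd must be > 0")


@dataclass(frozen=True)
class ClaimsSimConfig:
    """Parameters of the longitudinal-claims simulator.

    Time is integer days from the enrollment-window start.  Hazards are per
    patient-day; effects are on the log scale.  ``exposure_intercept`` plus
    the covariates' ``exposure_log_odds`` form the logistic model for
    receiving an exposure prescription; exposed patients get it at a uniform
    day inside ``exposure_day_range`` (skipped when that day falls outside
    their enrollment).  A concomitant prescription is co-issued with
    probability ``comod_prob`` at ``exposure day + U(comod_day_range)``.
    """

    n_patients: int = 5_000
    enrollment_window: tuple[int, int] = (0, 900)
    min_enrollment_days: int = 60
    age_distribution: tuple[float, float] = (55.0, 15.0)
    covariate_spec: tuple[CovariateSpec, ...] = ()
    exposure_codes: tuple[str, ...] = ("J01MA12",)
    exposure_intercept: float = -1.0
    exposure_day_range: tuple[int, int] = (190, 420)
    route_topical_fraction: float = 0.0
    comod_codes: tuple[str, ...] = ("H02AB02",)
    comod_prob: float = 0.0
    comod_day_range: tuple[int, int] = (-10, 40)
    baseline_hazard: float = 1e-4
    exposure_log_hr: float = 0.0
    comod_log_hr: float = 0.0
    covariate_log_hr: dict[str, float] = field(default_factory=dict)
    outcome_code: str = "M76.9"
    dx_repeat_days: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_patients > 0, "n_patients must be positive")
        _require(self.baseline_hazard >= 0, "baseline_hazard must be >= 0")
        _require(0.0 <= self.route_topical_fraction <= 1.0,
                 "route_topical_fraction must lie in [0,1]")
        _require(0.0 <= self.comod_prob <= 1.0, "comod_prob must lie in [0,1]")
        w0, w1 = self.enrollment_window
        _require(w1 > w0, "enrollment_window must be a non-empty (start, end)")
        _require(self.min_enrollment_days > 0, "min_enrollment_days must be positive")
        if isinstance(self.covariate_spec, list):
            object.__setattr__(self, "covariate_spec", tuple(self.covariate_spec))


@dataclass(frozen=True)
class GroundTruth:
    """The injected effects (and latent state) behind one simulated dataset."""

    drug_event_or: dict[str, float] = field(default_factory=dict)
    interaction_or: dict[tuple[str, str], float] = field(default_factory=dict)
    exposure_hr: float | None = None
    comod_hr: float | None = None
    covariate_hr: dict[str, float] = field(default_factory=dict)
    latent: pd.DataFrame | None = field(default=None, compare=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "drug_event_or": self.drug_event_or,
            "interaction_or": {f"{a}|{b}": v for (a, b), v in self.interaction_or.items()},
            "exposure_hr": self.exposure_hr,
            "comod_hr": self.comod_hr,
            "covariate_hr": self.covariate_hr,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def generate_reports(config: SRSimConfig) -> tuple[ReportSet, GroundTruth]:
    """Simulate a spontaneous-report set with injected drug–event effects.

    Produces exactly ``n_reports`` primary reports plus
    ``floor(duplicate_rate * n_reports)`` duplicate records (same case id,
    fresh report id).  Drug names are emitted already in generic form, so
    the returned set is flagged normalised but not deduplicated.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    catalog = list(config.drug_catalog)
    present = {
        name: rng.random(n) < p for name, p in config.drug_catalog.items()
    }
    background = [f"comed_{i:02d}" for i in range(config.n_background_drugs)]
    n_extra = (
        np.minimum(rng.poisson(config.polypharmacy_rate, size=n), len(background))
        if config.polypharmacy_rate > 0 and background
        else np.zeros(n, dtype=int)
    )

    log_odds = np.full(n, math.log(config.baseline_event_prob / (1 - config.baseline_event_prob)))
    for name, o in config.drug_event_or.items():
        if name in present:
            log_odds += np.where(present[name], math.log(o), 0.0)
    for (a, b), o in config.interaction_or.items():
        if a in present and b in present:
            log_odds += np.where(present[a] & present[b], math.log(o), 0.0)
    event = rng.random(n) < 1.0 / (1.0 + np.exp(-log_odds))
    noise_idx = rng.integers(0, len(NOISE_EVENTS), size=n)
    ages = np.round(rng.normal(55, 18, size=n), 0).clip(0, 100)
    sexes = np.where(rng.random(n) < 0.5, "F", "M")

    records: list[ReportRecord] = []
    for i in range(n):
        drugs = {name for name in catalog if present[name][i]}
        if n_extra[i]:
            drugs.update(rng.choice(background, size=n_extra[i], replace=False))
        events = {NOISE_EVENTS[noise_idx[i]]}
        if event[i]:
            events.add(config.outcome_term)
        raw = tuple(sorted(drugs))
        records.append(
            ReportRecord(
                report_id=f"R{i:08d}",
                case_id=f"C{i:08d}",
                version=1,
                drugs_raw=raw,
                drugs=frozenset(raw),
                events=frozenset(events),
                age=float(ages[i]),
                sex=str(sexes[i]),
            )
        )
    n_dup = int(math.floor(config.duplicate_rate * n))
    if n_dup:
        dup_of = rng.choice(n, size=n_dup, replace=False)
        for j, i in enumerate(sorted(int(v) for v in dup_of)):
            src = records[i]
            records.append(dataclasses.replace(src, report_id=f"R{n + j:08d}"))

    truth = GroundTruth(
        drug_event_or={d: config.drug_event_or.get(d, 1.0) for d in catalog},
        interaction_or=dict(config.interaction_or),
    )
    rs = ReportSet(
        records=tuple(records),
        provenance=f"synthetic-srs-seed{config.seed}",
        deduplicated=False,
        normalized=True,
    )
    return rs, truth


def generate_claims(config: ClaimsSimConfig) -> tuple[ClaimsStore, GroundTruth]:
    """Simulate a longitudinal claims store with a known exposure hazard ratio.

    See the module docstring for the generative model.  The returned
    :class:`GroundTruth` carries per-patient latent state (exposure day,
    latent event day, covariates) alongside the injected effects.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    w0, w1 = config.enrollment_window

    start = rng.integers(w0, w0 + max(1, (w1 - w0) // 10), size=n)
    max_len = w1 - start
    length = np.array(
        [rng.integers(config.min_enrollment_days, m + 1) if m > config.min_enrollment_days
         else int(m) for m in max_len]
    )
    end = start + length

    age = rng.normal(*config.age_distribution, size=n).clip(18, 100).round(0)
    sex = np.where(rng.random(n) < 0.5, "F", "M")

    cov_values: dict[str, np.ndarray] = {}
    for cs in config.covariate_spec:
        if cs.kind == "binary":
            cov_values[cs.name] = (rng.random(n) < cs.prevalence).astype(float)
        else:
            cov_values[cs.name] = rng.normal(cs.mean, cs.sd, size=n)

    # confounded exposure assignment
    expo_logit = np.full(n, config.exposure_intercept, dtype=float)
    for cs in config.covariate_spec:
        expo_logit += cs.exposure_log_odds * cov_values[cs.name]
    wants_exposure = rng.random(n) < 1.0 / (1.0 + np.exp(-expo_logit))
    lo, hi = config.exposure_day_range
    expo_day_draw = rng.integers(lo, hi + 1, size=n)
    topical = rng.random(n) < config.route_topical_fraction
    wants_comod = rng.random(n) < config.comod_prob
    comod_offset = rng.integers(config.comod_day_range[0], config.comod_day_range[1] + 1, size=n)

    # outcome hazards
    log_hr_cov = np.zeros(n)
    for name, b in config.covariate_log_hr.items():
        log_hr_cov += b * cov_values[name]
    h_pre = config.baseline_hazard * np.exp(log_hr_cov)

    patients = []
    rx_rows = []
    dx_rows = []
    latent_rows = []
    for i in range(n):
        pid = f"P{i:06d}"
        s, e = int(start[i]), int(end[i])
        patients.append(
            {"patient_id": pid, "age": float(age[i]), "sex": str(sex[i]),
             "enroll_start": s, "enroll_end": e}
        )
        # recurring comorbidity diagnoses, chronic-condition style
        for cs in config.covariate_spec:
            if cs.kind == "binary" and cov_values[cs.name][i] == 1.0:
                day = s + int(rng.integers(0, min(60, max(1, e - s))))
                while day < e:
                    dx_rows.append({"patient_id": pid, "day": day, "code": cs.dx_code})
                    day += config.dx_repeat_days

        expo_day: int | None = None
        route = "topical" if topical[i] else "oral"
        if wants_exposure[i] and s + expo_day_draw[i] < e:
            expo_day = s + int(expo_day_draw[i])
            rx_rows.append(
                {"patient_id": pid, "day": expo_day,
                 "code": config.exposure_codes[int(rng.integers(0, len(config.exposure_codes)))],
                 "route": route, "days_supply": int(rng.integers(5, 15))}
            )
        comod_day: int | None = None
        if expo_day is not None and wants_comod[i]:
            cd = expo_day + int(comod_offset[i])
            if s <= cd < e:
                comod_day = cd
                rx_rows.append(
                    {"patient_id": pid, "day": comod_day,
                     "code": config.comod_codes[int(rng.integers(0, len(config.comod_codes)))],
                     "route": "oral", "days_supply": int(rng.integers(3, 13))}
                )

        # recurrent outcome process with piecewise-constant intensity: h_pre
        # before a systemic exposure day, h_post after (memoryless restart at
        # the boundary).  Recurrence mirrors real claims, where a diagnosis
        # can recur; downstream designs take the first occurrence after index.
        systemic_expo = expo_day is not None and route != "topical"
        comod_concomitant = (
            comod_day is not None
            and expo_day is not None
            and expo_day - 7 <= comod_day <= expo_day + 30
        )
        h_post = h_pre[i] * math.exp(
            config.exposure_log_hr
            + (config.comod_log_hr if comod_concomitant else 0.0)
        )
        event_days: list[int] = []
        if config.baseline_hazard > 0:
            t = float(s)
            while t < e:
                in_pre = not systemic_expo or t < expo_day
                gap = rng.exponential(1.0 / (h_pre[i] if in_pre else h_post))
                if in_pre and systemic_expo and t + gap > expo_day:
                    t = float(expo_day)  # hazard changes; redraw from boundary
                    continue
                t += gap
                if t < e:
                    event_days.append(int(math.floor(t)))
        for day in sorted(set(event_days)):
            dx_rows.append({"patient_id": pid, "day": day, "code": config.outcome_code})
        event_day = event_days[0] if event_days else None
        latent_rows.append(
            {"patient_id": pid, "exposure_day": expo_day, "route": route,
             "comod_day": comod_day, "event_day": event_day,
             **{f"cov_{k}": cov_values[k][i] for k in cov_values}}
        )

    store = ClaimsStore(
        patients=pd.DataFrame(patients),
        prescriptions=pd.DataFrame(
            rx_rows, columns=["patient_id", "day", "code", "route", "days_supply"]
        ),
        diagnoses=pd.DataFrame(dx_rows, columns=["patient_id", "day", "code"]),
    )
    truth = GroundTruth(
        exposure_hr=math.exp(config.exposure_log_hr),
        comod_hr=math.exp(config.comod_log_hr),
        covariate_hr={k: math.exp(v) for k, v in config.covariate_log_hr.items()},
        latent=pd.DataFrame(latent_rows),
    )
    return store, truth
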