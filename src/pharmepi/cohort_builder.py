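"""Turn longitudinal claims into analyzable new-user cohorts.

The claims model is the usual administrative-database triple: per-patient
enrollment spans, dated prescription records (drug code + route), and dated
diagnosis records (ICD-10-style codes).  Time is integer days from an
arbitrary epoch; all intervals are half-open ``[start, end)`` except the
concomitant-use window, which is inclusive at both ends to match the
"from 7 days before to 30 days after" phrasing of the design.

Two new-user designs are supported:

* ``"fq"`` — index at the first systemic exposure-code prescription (e.g. a
  fluoroquinolone) after the run-in period; the exposed arm has a systemic
  concomitant-code prescription (e.g. dexamethasone) within
  [index - window_before, index + window_after]; patients whose only
  exposure prescriptions are topical never index.

* ``"older"`` — an age-restricted cohort in which the concomitant drug is
  itself the exposure: exposed patients index at their first systemic
  concomitant-code prescription after run-in, comparators at the end of the
  run-in period.

The run-in (wash-out) excludes prevalent cases and prior users so that
observed outcomes are incident and exposures are new.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

PATIENT_COLUMNS = ["patient_id", "age", "sex", "enroll_start", "enroll_end"]
RX_COLUMNS = ["patient_id", "day", "code", "route", "days_supply"]
DX_COLUMNS = ["patient_id", "day", "code"]

DEFAULT_TOPICAL_ROUTES = ("topical", "ophthalmic", "otic")


@dataclass(frozen=True)
class ClaimsStore:
    """Patients, prescriptions and diagnoses as three aligned DataFrames."""

    patients: pd.DataFrame  # patient_id, age, sex, enroll_start, enroll_end
    prescriptions: pd.DataFrame  # patient_id, day, code, route, days_supply
    diagnoses: pd.DataFrame  # patient_id, day, code

    def __post_init__(self) -> None:
        for df, cols, name in (
            (self.patients, PATIENT_COLUMNS, "patients"),
            (self.prescriptions, RX_COLUMNS, "prescriptions"),
            (self.diagnoses, DX_COLUMNS, "diagnoses"),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} table is missing columns {missing}")

    def validate_containment(self) -> None:
        """Assert every dated record falls inside its patient's enrollment span."""
        spans = self.patients.set_index("patient_id")[["enroll_start", "enroll_end"]]
        for df, name in ((self.prescriptions, "prescription"), (self.diagnoses, "diagnosis")):
            if df.empty:
                continue
            joined = df.join(spans, on="patient_id")
            bad = (joined["day"] < joined["enroll_start"]) | (joined["day"] >= joined["enroll_end"])
            if bad.any():
                raise ValueError(f"{int(bad.sum())} {name} records fall outside enrollment")


@dataclass(frozen=True)
class CohortSpec:
    """All design parameters of the cohort build.

    Defaults encode the tendinopathy design: a 180-day run-in
    (operationalising exclusion of events in the first 0–5 enrollment months,
    with incidence stabilising after month 6), a concomitant-use window of
    7 days before to 30 days after the index prescription, a 30-day risk
    period and 60-day follow-up for the drug-induced design (180 days for the
    age-related design), and systemic-route-only exposure.
    """

    outcome_codes: frozenset[str]
    exposure_codes: frozenset[str]
    comod_codes: frozenset[str] = frozenset()
    run_in_days: int = 180
    window_before: int = 7
    window_after: int = 30
    risk_period_days: int = 30
    follow_up_days: int = 60
    min_age: int | None = None
    systemic_only: bool = True
    topical_routes: tuple[str, ...] = DEFAULT_TOPICAL_ROUTES
    lookback_days: int = 180

    def __post_init__(self) -> None:
        for name in ("run_in_days", "window_before", "window_after",
                     "risk_period_days", "follow_up_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.follow_up_days < self.risk_period_days:
            raise ValueError("follow_up_days must cover the risk period")
        object.__setattr__(self, "outcome_codes", frozenset(self.outcome_codes))
        object.__setattr__(self, "exposure_codes", frozenset(self.exposure_codes))
        object.__setattr__(self, "comod_codes", frozenset(self.comod_codes))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "topical_routes" in raw:
            raw["topical_routes"] = tuple(raw["topical_routes"])
        return cls(**raw)


def load_claims(directory: str | Path, sep: str = "\t") -> ClaimsStore:
    """Read ``patients.tsv``, ``prescriptions.tsv``, ``diagnoses.tsv`` from a directory."""
    directory = Path(directory)
    pat = pd.read_csv(directory / "patients.tsv", sep=sep)
    rx = pd.read_csv(directory / "prescriptions.tsv", sep=sep)
    dx = pd.read_csv(directory / "diagnoses.tsv", sep=sep)
    for df in (rx, dx):
        df["day"] = df["day"].astype(int)
    return ClaimsStore(patients=pat, prescriptions=rx, diagnoses=dx)


def write_claims(cs: ClaimsStore, directory: str | Path, sep: str = "\t") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cs.patients.to_csv(directory / "patients.tsv", sep=sep, index=False)
    cs.prescriptions.to_csv(directory / "prescriptions.tsv", sep=sep, index=False)
    cs.diagnoses.to_csv(directory / "diagnoses.tsv", sep=sep, index=False)


def _is_systemic(route: pd.Series, spec: CohortSpec) -> pd.Series:
    if not spec.systemic_only:
        return pd.Series(True, index=route.index)
    return ~route.astype(str).str.strip().str.casefold().isin(
        [r.casefold() for r in spec.topical_routes]
    )


def apply_run_in(cs: ClaimsStore, spec: CohortSpec) -> frozenset:
    """Eligible patient ids after run-in (wash-out) exclusion.

    Excluded: enrollment shorter than ``run_in_days``, or any outcome
    diagnosis, exposure prescription or concomitant-drug prescription during
    ``[enroll_start, enroll_start + run_in_days)``.  Route is ignored here —
    any use during run-in disqualifies a "new user".
    """
    pat = cs.patients
    eligible = set(
        pat.loc[pat["enroll_end"] - pat["enroll_start"] >= spec.run_in_days, "patient_id"]
    )
    starts = pat.set_index("patient_id")["enroll_start"]

    dx = cs.diagnoses
    if not dx.empty:
        d = dx[dx["code"].isin(spec.outcome_codes)].copy()
        if not d.empty:
            d = d.join(starts, on="patient_id")
            bad = d.loc[d["day"] < d["enroll_start"] + spec.run_in_days, "patient_id"]
            eligible -= set(bad)

    rx = cs.prescriptions
    if not rx.empty:
        drug_codes = spec.exposure_codes | spec.comod_codes
        r = rx[rx["code"].isin(drug_codes)].copy()
        if not r.empty:
            r = r.join(starts, on="patient_id")
            bad = r.loc[r["day"] < r["enroll_start"] + spec.run_in_days, "patient_id"]
            eligible -= set(bad)
    return frozenset(eligible)


def assign_index(
    cs: ClaimsStore,
    spec: CohortSpec,
    eligible: frozenset,
    design: str = "fq",
) -> pd.DataFrame:
    """Index date and arm assignment per eligible patient.

    Returns a DataFrame ``patient_id, index_day, exposed`` (exposed is the
    concomitant/treated arm flag).  Patients that never index under the
    design (e.g. no systemic exposure prescription) are absent.
    """
    if design not in ("fq", "older"):
        raise ValueError("design must be 'fq' or 'older'")
    pat = cs.patients
    rx = cs.prescriptions
    systemic = rx[_is_systemic(rx["route"], spec)] if not rx.empty else rx

    if design == "fq":
        starts = pat.set_index("patient_id")["enroll_start"]
        expo = systemic[
            systemic["code"].isin(spec.exposure_codes)
            & systemic["patient_id"].isin(eligible)
        ].copy()
        if expo.empty:
            return pd.DataFrame(columns=["patient_id", "index_day", "exposed"])
        expo = expo.join(starts, on="patient_id")
        expo = expo[expo["day"] >= expo["enroll_start"] + spec.run_in_days]
        if expo.empty:
            return pd.DataFrame(columns=["patient_id", "index_day", "exposed"])
        index_day = expo.groupby("patient_id")["day"].min()

        comod = systemic[
            systemic["code"].isin(spec.comod_codes)
            & systemic["patient_id"].isin(index_day.index)
        ]
        exposed_ids: set = set()
        if not comod.empty:
            joined = comod.join(index_day.rename("index_day"), on="patient_id")
            # window inclusive at both ends: -window_before .. +window_after
            hit = (
                (joined["day"] >= joined["index_day"] - spec.window_before)
                & (joined["day"] <= joined["index_day"] + spec.window_after)
            )
            exposed_ids = set(joined.loc[hit, "patient_id"])
        out = index_day.reset_index().rename(columns={"day": "index_day"})
        out["exposed"] = out["patient_id"].isin(exposed_ids)
        return out.sort_values("patient_id").reset_index(drop=True)

    # older-adult design: concomitant drug is the exposure of interest
    p = pat[pat["patient_id"].isin(eligible)].copy()
    if spec.min_age is not None:
        p = p[p["age"] >= spec.min_age]
    if p.empty:
        return pd.DataFrame(columns=["patient_id", "index_day", "exposed"])
    starts = p.set_index("patient_id")["enroll_start"]
    comod = systemic[
        systemic["code"].isin(spec.comod_codes)
        & systemic["patient_id"].isin(set(p["patient_id"]))
    ].copy()
    first_comod = pd.Series(dtype=float)
    if not comod.empty:
        comod = comod.join(starts, on="patient_id")
        comod = comod[comod["day"] >= comod["enroll_start"] + spec.run_in_days]
        if not comod.empty:
            first_comod = comod.groupby("patient_id")["day"].min()
    rows = []
    for pid, start in starts.items():
        if pid in first_comod.index:
            rows.append({"patient_id": pid, "index_day": int(first_comod[pid]), "exposed": True})
        else:
            rows.append({"patient_id": pid, "index_day": int(start + spec.run_in_days), "exposed": False})
    return pd.DataFrame(rows).sort_values("patient_id").reset_index(drop=True)


def build_survival(
    cs: ClaimsStore, spec: CohortSpec, index_map: pd.DataFrame
) -> pd.DataFrame:
    """Per-patient (time, event) from index to outcome / disenrollment / follow-up end.

    ``time = min(first outcome day >= index, enroll_end, index + follow_up) - index``
    and ``event = 1`` iff the minimum is an outcome day.  An outcome on the
    index day itself yields time 0 with event 1 and is kept.  Disenrollment
    censors at ``enroll_end - index`` because enrollment is half-open (the
    patient is last observable on day ``enroll_end - 1``; an outcome on
    ``enroll_end`` is unobserved).
    """
    if index_map.empty:
        return pd.DataFrame(columns=["patient_id", "group", "time", "event", "index_day"])
    ends = cs.patients.set_index("patient_id")["enroll_end"]
    dx = cs.diagnoses
    outcome = dx[dx["code"].isin(spec.outcome_codes)] if not dx.empty else dx
    first_outcome: dict = {}
    if not outcome.empty:
        idx = index_map.set_index("patient_id")["index_day"]
        o = outcome[outcome["patient_id"].isin(idx.index)].copy()
        o = o.join(idx, on="patient_id")
        o = o[o["day"] >= o["index_day"]]
        if not o.empty:
            first_outcome = o.groupby("patient_id")["day"].min().to_dict()
    rows = []
    for row in index_map.itertuples(index=False):
        pid, index_day, exposed = row.patient_id, int(row.index_day), bool(row.exposed)
        t_admin = index_day + spec.follow_up_days
        t_censor = min(int(ends[pid]), t_admin)
        t_out = first_outcome.get(pid)
        if t_out is not None and t_out <= t_censor and t_out <= t_admin:
            time, event = t_out - index_day, 1
        else:
            time, event = t_censor - index_day, 0
        rows.append(
            {
                "patient_id": pid,
                "group": "exposed" if exposed else "comparator",
                "time": int(time),
                "event": int(event),
                "index_day": index_day,
            }
        )
    return pd.DataFrame(rows)


def build_covariates(
    cs: ClaimsStore,
    index_map: pd.DataFrame,
    lookback_days: int = 180,
    comorbidity_codes: dict[str, frozenset] | None = None,
    medication_codes: dict[str, frozenset] | None = None,
    hospitalization_codes: frozenset | None = None,
) -> pd.DataFrame:
    """Baseline covariate vectors from strictly pre-index records.

    Flags are computed over the half-open window
    ``[index - lookback_days, index)``: a record on the index day itself is
    *not* baseline.  ``comorbidity_codes`` / ``medication_codes`` map flag
    name -> diagnosis / drug code set; ``hospitalization_codes`` are
    diagnosis codes marking an inpatient stay.  Age and sex are copied from
    the patient table.
    """
    comorbidity_codes = comorbidity_codes or {}
    medication_codes = medication_codes or {}
    pat = cs.patients.set_index("patient_id")
    out = index_map[["patient_id", "index_day"]].copy()
    out["age"] = out["patient_id"].map(pat["age"])
    out["sex_male"] = (out["patient_id"].map(pat["sex"]).astype(str).str.upper() == "M").astype(int)

    def window_hits(df: pd.DataFrame, codes: frozenset) -> set:
        if df.empty:
            return set()
        sub = df[df["code"].isin(codes) & df["patient_id"].isin(set(out["patient_id"]))]
        if sub.empty:
            return set()
        sub = sub.join(index_map.set_index("patient_id")["index_day"], on="patient_id")
        hit = (sub["day"] >= sub["index_day"] - lookback_days) & (sub["day"] < sub["index_day"])
        return set(sub.loc[hit, "patient_id"])

    for name, codes in comorbidity_codes.items():
        out[f"dx_{name}"] = out["patient_id"].isin(window_hits(cs.diagnoses, frozenset(codes))).astype(int)
    for name, codes in medication_codes.items():
        out[f"rx_{name}"] = out["patient_id"].isin(window_hits(cs.prescriptions, frozenset(codes))).astype(int)
    if hospitalization_codes is not None:
        out["hospitalized"] = out["patient_id"].isin(
            window_hits(cs.diagnoses, frozenset(hospitalization_codes))
        ).astype(int)
    return out.drop(columns=["index_day"])


def cumulative_incidence(records: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Crude incidence proportion per group with exact Clopper–Pearson CI.

    The proportion is events / patients over the whole follow-up (the
    "total incidence proportion"), not a time-to-event estimate.
    """
    if records.empty:
        raise ValueError("cumulative_incidence requires a non-empty record table")
    alpha = 1.0 - level
    rows = []
    for group, sub in records.groupby("group"):
        n = len(sub)
        k = int(sub["event"].sum())
        lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
        rows.append(
            {"group": group, "n": n, "events": k, "proportion": k / n,
             "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)
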