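"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately reimplement pipeline logic as
straight-line per-patient / per-report scans, without reusing any package
internals, so that tests compare two independent routes to the same answer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pharmepi.report_store import EventQuery, ReportRecord, ReportSet


def make_report(
    report_id: str,
    case_id: str | None = None,
    version: int = 1,
    drugs: tuple[str, ...] = (),
    events: tuple[str, ...] = (),
    age: float | None = None,
    sex: str | None = None,
) -> ReportRecord:
    return ReportRecord(
        report_id=report_id,
        case_id=case_id or report_id,
        version=version,
        drugs_raw=tuple(drugs),
        drugs=frozenset(drugs),
        events=frozenset(events),
        age=age,
        sex=sex,
    )


def make_report_set(records, **kwargs) -> ReportSet:
    kwargs.setdefault("deduplicated", True)
    kwargs.setdefault("normalized", True)
    return ReportSet(records=tuple(records), **kwargs)


@pytest.fixture
def tendon_query() -> EventQuery:
    return EventQuery(name="tendinopathy", terms=frozenset(["tendon disorder", "tendon rupture"]))


def random_report_set(rng: np.random.Generator, n: int, n_drugs: int = 8,
                      event_prob: float = 0.3) -> ReportSet:
    """Unstructured random reports for oracle-equivalence tests."""
    drugs = [f"d{i}" for i in range(n_drugs)]
    records = []
    for i in range(n):
        present = tuple(d for d in drugs if rng.random() < 0.25)
        events = ("tendon disorder",) if rng.random() < event_prob else ("nausea",)
        records.append(make_report(f"R{i:05d}", drugs=present, events=events))
    return make_report_set(records)


# ---------------------------------------------------------------------------
# brute-force claims-pipeline oracle


def brute_force_eligible(store, spec) -> set:
    """Per-patient straight-line run-in scan."""
    out = set()
    rx = store.prescriptions
    dx = store.diagnoses
    drug_codes = set(spec.exposure_codes) | set(spec.comod_codes)
    for p in store.patients.itertuples(index=False):
        if p.enroll_end - p.enroll_start < spec.run_in_days:
            continue
        cutoff = p.enroll_start + spec.run_in_days
        bad = False
        for d in dx[dx["patient_id"] == p.patient_id].itertuples(index=False):
            if d.code in spec.outcome_codes and d.day < cutoff:
                bad = True
        for r in rx[rx["patient_id"] == p.patient_id].itertuples(index=False):
            if r.code in drug_codes and r.day < cutoff:
                bad = True
        if not bad:
            out.add(p.patient_id)
    return out


def _systemic(route: str, spec) -> bool:
    if not spec.systemic_only:
        return True
    return str(route).strip().casefold() not in {r.casefold() for r in spec.topical_routes}


def brute_force_index(store, spec, eligible, design="fq") -> dict:
    """Per-patient index day and arm flag; returns {pid: (index_day, exposed)}."""
    rx = store.prescriptions
    out = {}
    for p in store.patients.itertuples(index=False):
        pid = p.patient_id
        if pid not in eligible:
            continue
        mine = rx[rx["patient_id"] == pid]
        if design == "fq":
            expo_days = sorted(
                r.day for r in mine.itertuples(index=False)
                if r.code in spec.exposure_codes and _systemic(r.route, spec)
                and r.day >= p.enroll_start + spec.run_in_days
            )
            if not expo_days:
                continue
            index_day = expo_days[0]
            exposed = any(
                r.code in spec.comod_codes and _systemic(r.route, spec)
                and index_day - spec.window_before <= r.day <= index_day + spec.window_after
                for r in mine.itertuples(index=False)
            )
            out[pid] = (index_day, exposed)
        else:
            if spec.min_age is not None and p.age < spec.min_age:
                continue
            comod_days = sorted(
                r.day for r in mine.itertuples(index=False)
                if r.code in spec.comod_codes and _systemic(r.route, spec)
                and r.day >= p.enroll_start + spec.run_in_days
            )
            if comod_days:
                out[pid] = (comod_days[0], True)
            else:
                out[pid] = (p.enroll_start + spec.run_in_days, False)
    return out


def brute_force_survival(store, spec, index: dict) -> dict:
    """Per-patient (time, event) via an independent minimum computation."""
    dx = store.diagnoses
    ends = store.patients.set_index("patient_id")["enroll_end"]
    out = {}
    for pid, (index_day, exposed) in index.items():
        outcome_days = sorted(
            d.day for d in dx[dx["patient_id"] == pid].itertuples(index=False)
            if d.code in spec.outcome_codes and d.day >= index_day
        )
        stop = min(int(ends[pid]), index_day + spec.follow_up_days)
        if outcome_days and outcome_days[0] <= stop:
            out[pid] = (outcome_days[0] - index_day, 1)
        else:
            out[pid] = (stop - index_day, 0)
    return out
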