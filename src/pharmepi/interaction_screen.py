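"""Concomitant-drug confounder screening within a base-drug cohort.

Restricting the report set to users of a base drug class (e.g. the
fluoroquinolones) and cross-tabulating each concomitant drug against the
event yields, per pair, the same ROR/CI/Z machinery as the single-drug
screen.  A concomitant drug whose corrected upper CI bound falls below 1
"significantly decreases" the event's ROR among base-drug users — a
candidate mitigating co-medication (or confounder).  Intersecting the
significant set across independently collected databases (FAERS, JADER,
CVARD) filters database-specific artefacts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .disproportionality import (
    DEFAULT_MIN_CASES,
    ContingencyTable,
    ror_statistics,
)
from .report_store import EventQuery, ReportSet, has_event

PAIR_COLUMNS = [
    "base_class", "concomitant", "database", "a", "b", "c", "d",
    "ror", "ci_low", "ci_high", "z", "p", "n_exposed", "n_exposed_event",
    "log10_ror", "abs_z", "significant_increase", "significant_decrease",
]


@dataclass(frozen=True)
class DrugClass:
    """A named set of generic drug names (e.g. ATC J01MA fluoroquinolones)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("DrugClass requires at least one member")
        object.__setattr__(
            self, "members", frozenset(m.strip().casefold() for m in self.members)
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Drugs significant in the same direction in every screened database."""

    direction: str  # "decrease" or "increase"
    alpha: float
    drugs: tuple[str, ...]  # ordered by mean ln ROR across databases
    evidence: pd.DataFrame  # the per-database PairSignal rows for those drugs
    n_databases: int


def _base_cohort(rs: ReportSet, base: DrugClass) -> list:
    return [r for r in rs if r.drugs & base.members]


def stratified_contingency(
    rs: ReportSet, base: DrugClass, concomitant: str, query: EventQuery
) -> ContingencyTable:
    """2x2 table for one concomitant drug among base-class users only.

    Cells always sum to the base-cohort size.  Asking about a drug that is
    itself a member of the base class is a usage error.
    """
    concomitant = concomitant.strip().casefold()
    if concomitant in base.members:
        raise ValueError(
            f"{concomitant!r} is a member of base class {base.name!r}; "
            "a concomitant drug must lie outside the base class"
        )
    a = b = c = d = 0
    for r in _base_cohort(rs, base):
        with_con = concomitant in r.drugs
        event = has_event(r, query)
        if with_con and event:
            a += 1
        elif with_con:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def screen_concomitants(
    rs: ReportSet,
    base: DrugClass,
    query: EventQuery,
    min_cases: int = DEFAULT_MIN_CASES,
    database: str | None = None,
) -> pd.DataFrame:
    """Corrected ROR signal for every concomitant drug in the base cohort.

    ``min_cases`` applies to the pre-correction a cell (concomitant + event
    reports), mirroring the single-drug screen.  Drugs seen only outside the
    base cohort never appear.  Returns the pair-signal table sorted by
    \\|Z\\| descending.
    """
    cohort = _base_cohort(rs, base)
    n_total = len(cohort)
    with_event: Counter[str] = Counter()
    present: Counter[str] = Counter()
    n_event = 0
    for r in cohort:
        ev = has_event(r, query)
        n_event += ev
        for drug in r.drugs - base.members:
            present[drug] += 1
            if ev:
                with_event[drug] += 1
    label = database if database is not None else rs.provenance
    rows = []
    for drug in sorted(present):
        a = with_event[drug]
        if a < min_cases:
            continue
        b = present[drug] - a
        c = n_event - a
        d = n_total - a - b - c
        s = ror_statistics(ContingencyTable(a, b, c, d), drug=drug)
        rows.append(
            {
                "base_class": base.name, "concomitant": drug, "database": label,
                "a": a, "b": b, "c": c, "d": d,
                "ror": s.ror, "ci_low": s.ci_low, "ci_high": s.ci_high,
                "z": s.z, "p": s.p,
                "n_exposed": a + b, "n_exposed_event": a,
                "log10_ror": math.log10(s.ror), "abs_z": abs(s.z),
                "significant_increase": s.significant_increase,
                "significant_decrease": s.significant_decrease,
            }
        )
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if not out.empty:
        out = out.sort_values("abs_z", ascending=False, kind="mergesort").reset_index(drop=True)
    return out


def cross_database_enrichment(
    tables: list[pd.DataFrame],
    direction: str = "decrease",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Intersect direction-consistent significant concomitant signals.

    A drug qualifies when, in *every* supplied pair-signal table, its
    corrected CI at level ``alpha`` excludes 1 on the stated side
    (``decrease``: upper bound < 1; ``increase``: lower bound > 1).
    Results are ordered by mean ln ROR across databases (most protective
    first for ``decrease``, strongest first for ``increase``).
    """
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    if len(tables) < 2:
        raise ValueError("cross-database enrichment needs at least two tables")
    labels = [t["database"].iloc[0] if not t.empty else f"table{i}" for i, t in enumerate(tables)]
    if len(set(labels)) != len(labels):
        raise ValueError("pair-signal tables must carry distinct database labels")

    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    sig_sets = []
    for t in tables:
        if t.empty:
            sig_sets.append(set())
            continue
        log_ror = pd.Series([math.log(v) for v in t["ror"]], index=t.index)
        se = (log_ror / t["z"].replace(0, float("nan"))).abs()
        if direction == "decrease":
            sig = t.loc[(log_ror + zq * se) < 0, "concomitant"]
        else:
            sig = t.loc[(log_ror - zq * se) > 0, "concomitant"]
        sig_sets.append(set(sig))
    shared = set.intersection(*sig_sets) if sig_sets else set()

    if shared:
        evidence = pd.concat(
            [t[t["concomitant"].isin(shared)] for t in tables], ignore_index=True
        )
        mean_log = (
            evidence.assign(log_ror=[math.log(v) for v in evidence["ror"]])
            .groupby("concomitant")["log_ror"].mean()
        )
        ordered = tuple(
            mean_log.sort_values(ascending=(direction == "decrease")).index
        )
    else:
        evidence = pd.DataFrame(columns=PAIR_COLUMNS)
        ordered = ()
    return EnrichmentResult(
        direction=direction,
        alpha=alpha,
        drugs=ordered,
        evidence=evidence,
        n_databases=len(tables),
    )
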