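"""Spontaneous adverse-event report ingestion, normalisation and deduplication.

Spontaneous reporting systems (FAERS, JADER, CVARD) collect voluntary
adverse-event reports.  Each report lists free-text drug names and event
terms; the same clinical case may appear several times (follow-up versions,
duplicate submissions).  Before any disproportionality statistic is computed
the reports must be (1) mapped from arbitrary trade names/abbreviations to
unified generic names, (2) deduplicated to one record per case, and
(3) screened against an event-term query emulating a narrow-scope
standardised MedDRA query.

All operations are pure: they return new objects and never mutate inputs.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["report_id", "case_id", "version", "drugs", "events", "age", "sex"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class TableDialect:
    """How report tables are laid out on disk.

    ``sep`` separates columns; ``field_sep`` separates the multiple values
    packed inside the drugs / events columns.
    """

    sep: str = "\t"
    field_sep: str = ";"


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous adverse-event report.

    ``drugs_raw`` holds the verbatim drug strings from the source table;
    ``drugs`` is empty until :func:`normalize_drugs` has run and then holds
    the mapped generic names.  Demographics may be missing (``None``).
    """

    report_id: str
    case_id: str
    version: int
    drugs_raw: tuple[str, ...]
    drugs: frozenset[str]
    events: frozenset[str]
    age: float | None = None
    sex: str | None = None


@dataclass(frozen=True)
class NormalizationReport:
    """What :func:`normalize_drugs` did: counts and the unmapped names seen."""

    n_reports: int
    n_raw_names: int
    unmapped: frozenset[str]
    policy: str


@dataclass(frozen=True)
class ReportSet:
    """An immutable collection of :class:`ReportRecord`.

    ``provenance`` labels the source database (e.g. ``"FAERS"``);
    ``deduplicated`` / ``normalized`` track pipeline state.
    """

    records: tuple[ReportRecord, ...]
    provenance: str = ""
    deduplicated: bool = False
    normalized: bool = False
    normalization: NormalizationReport | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReportRecord]:
        return iter(self.records)

    def drug_universe(self) -> frozenset[str]:
        """All generic drug names appearing in the set (post-normalisation)."""
        out: set[str] = set()
        for r in self.records:
            out.update(r.drugs)
        return frozenset(out)

    def to_frame(self, dialect: TableDialect = TableDialect()) -> pd.DataFrame:
        """Flatten to the on-disk column layout (sets joined with field_sep)."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "report_id": r.report_id,
                    "case_id": r.case_id,
                    "version": r.version,
                    "drugs": dialect.field_sep.join(
                        sorted(r.drugs) if r.drugs else r.drugs_raw
                    ),
                    "events": dialect.field_sep.join(sorted(r.events)),
                    "age": r.age,
                    "sex": r.sex,
                }
            )
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)


@dataclass(frozen=True)
class DrugMap:
    """Raw drug name -> generic name mapping with an unmapped-name policy.

    Lookup is case-insensitive and whitespace-trimmed.  ``unmapped_policy``
    is ``"keep"`` (retain the raw name, case-folded, as its own generic —
    the default, so denominators are not silently biased) or ``"drop"``.
    """

    entries: Mapping[str, str]
    unmapped_policy: str = "keep"

    def __post_init__(self) -> None:
        if self.unmapped_policy not in ("keep", "drop"):
            raise ValueError(
                f"unmapped_policy must be 'keep' or 'drop', got {self.unmapped_policy!r}"
            )
        folded = {_fold(k): v for k, v in self.entries.items()}
        object.__setattr__(self, "entries", folded)

    def lookup(self, raw: str) -> str | None:
        """Generic name for ``raw``, or None if unmapped under the drop policy."""
        key = _fold(raw)
        if key in self.entries:
            return self.entries[key]
        if self.unmapped_policy == "keep":
            return key
        return None


@dataclass(frozen=True)
class EventQuery:
    """A named set of event terms defining the outcome of interest.

    Stands in for a narrow-scope standardised MedDRA query: membership is
    exact string match on trimmed, case-folded terms, no ontology traversal.
    """

    name: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("EventQuery requires a non-empty term set")
        object.__setattr__(self, "terms", frozenset(_fold(t) for t in self.terms))


def _fold(s: str) -> str:
    return s.strip().casefold()


def _split_multi(value: object, field_sep: str) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    text = str(value)
    return tuple(p.strip() for p in text.split(field_sep) if p.strip())


def load_reports(
    path: str | Path,
    dialect: TableDialect = TableDialect(),
    provenance: str = "",
) -> ReportSet:
    """Read a delimited report table into a :class:`ReportSet`.

    The table must carry the columns ``report_id, case_id, version, drugs,
    events, age, sex``; drugs/events are intra-field lists split on
    ``dialect.field_sep``.  Raises :class:`SchemaError` naming the first
    missing column; an empty file yields an empty set with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"report table {path} is missing required column {col!r}")
    if df.empty:
        warnings.warn(f"report table {path} is empty", stacklevel=2)
        return ReportSet(records=(), provenance=provenance)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ReportRecord(
                report_id=str(row.report_id),
                case_id=str(row.case_id),
                version=int(row.version) if str(row.version).strip() else 0,
                drugs_raw=_split_multi(row.drugs, dialect.field_sep),
                drugs=frozenset(),
                events=frozenset(_fold(e) for e in _split_multi(row.events, dialect.field_sep)),
                age=float(row.age) if str(row.age).strip() else None,
                sex=str(row.sex) if str(row.sex).strip() else None,
            )
        )
    return ReportSet(records=tuple(records), provenance=provenance)


def write_reports(
    rs: ReportSet, path: str | Path, dialect: TableDialect = TableDialect()
) -> None:
    """Write a ReportSet back to the delimited layout read by :func:`load_reports`."""
    rs.to_frame(dialect).to_csv(path, sep=dialect.sep, index=False)


def load_drug_map(
    path: str | Path, sep: str = "\t", unmapped_policy: str = "keep"
) -> DrugMap:
    """Read a two-column (raw name, generic name) table into a :class:`DrugMap`."""
    entries: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=sep):
            if len(row) >= 2 and row[0].strip():
                entries[row[0]] = _fold(row[1])
    return DrugMap(entries=entries, unmapped_policy=unmapped_policy)


def load_event_query(path: str | Path, name: str | None = None) -> EventQuery:
    """Read a one-term-per-line file into an :class:`EventQuery`."""
    path = Path(path)
    terms = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return EventQuery(name=name or path.stem, terms=frozenset(terms))


def normalize_drugs(rs: ReportSet, drug_map: DrugMap) -> ReportSet:
    """Map raw drug strings to generic names; collapse synonyms to one entry.

    Two trade names of the same generic become a single set element.
    Unmapped names follow the map's policy (keep-as-is or drop) and are
    listed in the attached :class:`NormalizationReport`.  Idempotent:
    re-applying with the same map changes nothing.
    """
    unmapped: set[str] = set()
    n_raw = 0
    records = []
    for r in rs.records:
        raw_names = r.drugs_raw if not rs.normalized else tuple(sorted(r.drugs))
        mapped: set[str] = set()
        for raw in raw_names:
            n_raw += 1
            generic = drug_map.lookup(raw)
            key = _fold(raw)
            if key not in drug_map.entries:
                unmapped.add(key)
            if generic is not None:
                mapped.add(generic)
        records.append(replace(r, drugs=frozenset(mapped)))
    report = NormalizationReport(
        n_reports=len(rs),
        n_raw_names=n_raw,
        unmapped=frozenset(unmapped),
        policy=drug_map.unmapped_policy,
    )
    if unmapped:
        logger.info("normalize_drugs: %d unmapped raw names (%s policy)",
                    len(unmapped), drug_map.unmapped_policy)
    return ReportSet(
        records=tuple(records),
        provenance=rs.provenance,
        deduplicated=rs.deduplicated,
        normalized=True,
        normalization=report,
    )


def deduplicate(rs: ReportSet) -> ReportSet:
    """Keep one report per case: highest version, ties by greatest report_id.

    Spontaneous reporting systems accumulate follow-up versions and outright
    duplicates of a case; all disproportionality denominators assume one
    record per case.  The strategy here (max version, then lexicographically
    greatest report_id) is deterministic and swappable.
    """
    best: dict[str, ReportRecord] = {}
    for r in rs.records:
        cur = best.get(r.case_id)
        if cur is None or (r.version, r.report_id) > (cur.version, cur.report_id):
            best[r.case_id] = r
    kept = tuple(sorted(best.values(), key=lambda r: r.report_id))
    removed = len(rs) - len(kept)
    if removed:
        logger.info("deduplicate: removed %d duplicate reports", removed)
    return ReportSet(
        records=kept,
        provenance=rs.provenance,
        deduplicated=True,
        normalized=rs.normalized,
        normalization=rs.normalization,
    )


def has_event(record: ReportRecord, query: EventQuery) -> bool:
    """True iff the report lists at least one term of the event query."""
    return bool(record.events & query.terms)
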