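"""Reporting odds ratio (ROR) disproportionality analysis.

For a drug D and an event query E over a deduplicated report set, the 2x2
contingency table is

              event   no event
    drug        a        b
    no drug     c        d

and the reporting odds ratio is ROR = (a/b) / (c/d) = ad/bc.  On the log
scale the Wald standard error is SE = sqrt(1/a + 1/b + 1/c + 1/d), giving

    95% CI  = exp(ln ROR +/- 1.96 * SE)
    Z       = ln ROR / SE

The Haldane–Anscombe correction adds 0.5 to every cell before computation so
that estimates stay finite when a cell is zero; it is applied unconditionally
to all four cells, not only in the zero-cell case.  Because spontaneous
reports lack denominators, the ROR is a signal metric, not an incidence
measure.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .report_store import EventQuery, ReportSet, has_event

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

DEFAULT_MIN_CASES = 3  # conventional pharmacovigilance case floor


class UndefinedRORError(ZeroDivisionError):
    """Raised when an uncorrected table with a zero cell makes the ROR undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 cell counts underlying one ROR computation.

    Cells are stored uncorrected; ``corrected()`` returns the
    Haldane–Anscombe-shifted copy.
    """

    a: float  # exposed, event
    b: float  # exposed, no event
    c: float  # unexposed, event
    d: float  # unexposed, no event
    corrected_flag: bool = False
    correction_value: float = 0.5

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> "ContingencyTable":
        """Return the table with 0.5 added to every cell."""
        k = self.correction_value
        return ContingencyTable(
            self.a + k, self.b + k, self.c + k, self.d + k,
            corrected_flag=True, correction_value=k,
        )

    def transposed(self) -> "ContingencyTable":
        """Swap the roles of drug and event (exchange b and c)."""
        return ContingencyTable(self.a, self.c, self.b, self.d,
                                self.corrected_flag, self.correction_value)


@dataclass(frozen=True)
class SignalResult:
    """One volcano-plot row: ROR, 95% CI, Z, and the pre-correction case count."""

    drug: str
    ror: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    n_exposed_event: float
    n_exposed: float = float("nan")

    @property
    def significant_increase(self) -> bool:
        return self.ci_low > 1.0

    @property
    def significant_decrease(self) -> bool:
        return self.ci_high < 1.0


def contingency(rs: ReportSet, drug: str, query: EventQuery) -> ContingencyTable:
    """Cross-tabulate drug presence against event-query membership.

    The report set should already be deduplicated and name-normalised so
    that one record is one case and ``drug`` is a generic name.
    """
    a = b = c = d = 0
    for r in rs:
        exposed = drug in r.drugs
        event = has_event(r, query)
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def ror_statistics(
    table: ContingencyTable,
    drug: str = "",
    apply_correction: bool = True,
) -> SignalResult:
    """ROR, Wald 95% CI, Z score and two-sided p from a 2x2 table.

    With ``apply_correction`` every cell gets +0.5 before any arithmetic, so
    all outputs are finite even with zero cells.  Without correction a zero
    cell raises :class:`UndefinedRORError` rather than silently producing an
    infinity.
    """
    raw = table
    t = table if table.corrected_flag else (table.corrected() if apply_correction else table)
    if not t.corrected_flag and min(t.a, t.b, t.c, t.d) == 0:
        raise UndefinedRORError(
            f"uncorrected table {(t.a, t.b, t.c, t.d)} has a zero cell; "
            "enable the Haldane–Anscombe correction for a finite estimate"
        )
    log_ror = math.log(t.a) - math.log(t.b) - math.log(t.c) + math.log(t.d)
    se = math.sqrt(1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d)
    z = log_ror / se
    return SignalResult(
        drug=drug,
        ror=math.exp(log_ror),
        ci_low=math.exp(log_ror - Z_95 * se),
        ci_high=math.exp(log_ror + Z_95 * se),
        z=z,
        p=2.0 * stats.norm.sf(abs(z)),
        n_exposed_event=raw.a if not raw.corrected_flag else raw.a - raw.correction_value,
        n_exposed=(raw.a + raw.b) if not raw.corrected_flag else raw.a + raw.b - 2 * raw.correction_value,
    )


def screen_all_drugs(
    rs: ReportSet,
    query: EventQuery,
    min_cases: int = DEFAULT_MIN_CASES,
    apply_correction: bool = True,
) -> pd.DataFrame:
    """One corrected ROR signal per drug with at least ``min_cases`` event reports.

    Returns a DataFrame sorted by \\|Z\\| descending with columns
    ``drug, a, b, c, d, ror, ci_low, ci_high, z, p, n_exposed,
    n_exposed_event, log10_ror, abs_z`` — the volcano-plot table (x =
    log10 ROR, y = \\|Z\\|, marker size = n_exposed).
    """
    n_total = len(rs)
    with_event: Counter[str] = Counter()
    exposed: Counter[str] = Counter()
    n_event = 0
    for r in rs:
        ev = has_event(r, query)
        n_event += ev
        for drug in r.drugs:
            exposed[drug] += 1
            if ev:
                with_event[drug] += 1
    rows = []
    for drug in sorted(exposed):
        a = with_event[drug]
        if a < min_cases:
            continue
        b = exposed[drug] - a
        c = n_event - a
        d = n_total - a - b - c
        table = ContingencyTable(a, b, c, d)
        s = ror_statistics(table, drug=drug, apply_correction=apply_correction)
        rows.append(
            {
                "drug": drug, "a": a, "b": b, "c": c, "d": d,
                "ror": s.ror, "ci_low": s.ci_low, "ci_high": s.ci_high,
                "z": s.z, "p": s.p,
                "n_exposed": a + b, "n_exposed_event": a,
                "log10_ror": math.log10(s.ror), "abs_z": abs(s.z),
                "significant_increase": s.significant_increase,
                "significant_decrease": s.significant_decrease,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "drug", "a", "b", "c", "d", "ror", "ci_low", "ci_high", "z", "p",
            "n_exposed", "n_exposed_event", "log10_ror", "abs_z",
            "significant_increase", "significant_decrease",
        ],
    )
    if not out.empty:
        out = out.sort_values("abs_z", ascending=False, kind="mergesort").reset_index(drop=True)
    return out


def adjust_bh(signals: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Append Benjamini–Hochberg adjusted p-values across the screened drugs.

    Off the main path: the default screen reports unadjusted Z scores.
    """
    from statsmodels.stats.multitest import multipletests

    out = signals.copy()
    if out.empty:
        out["p_bh"] = []
        out["significant_bh"] = []
        return out
    rej, p_adj, _, _ = multipletests(out["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    out["p_bh"] = p_adj
    out["significant_bh"] = rej
    return out
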