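"""Kaplan–Meier estimation, log-rank testing and Cox hazard ratios.

Operates on the survival-record table produced by the cohort builder
(columns ``patient_id, group, time, event`` with group in
{"exposed", "comparator"}).  Follow-up truncation happens in the cohort
builder; nothing here re-censors.

The Kaplan–Meier output includes a per-day number-at-risk table — the count
of patients still under observation and event-free on each follow-up day —
matching the risk tables printed under clinical cumulative-incidence plots.
Cox models use the Efron ties approximation by default; a Breslow variant
of the group-only model is provided because the two-group log-rank statistic
is exactly the Cox score test at beta = 0 under Breslow tie handling, a
relationship asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

GROUPS = ("exposed", "comparator")


class MonotoneLikelihoodError(RuntimeError):
    """No events in one arm: the group hazard ratio diverges."""


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimates per group plus a daily number-at-risk table."""

    curves: dict[str, pd.DataFrame]  # per group: time, n_risk, n_event, survival, cum_incidence
    at_risk_daily: pd.DataFrame  # day x group counts over [0, horizon]
    horizon: int

    def survival_at(self, group: str, t: float) -> float:
        """S(t) by step-function lookup (right-continuous)."""
        df = self.curves[group]
        past = df[df["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # chi-square, 1 df for two groups
    p: float
    observed: dict[str, float]
    expected: dict[str, float]


@dataclass(frozen=True)
class CoxResult:
    log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    se: float
    p: float  # Wald
    ties: str
    n: int
    n_events: int


def _check_records(records: pd.DataFrame) -> None:
    if records.empty:
        raise ValueError("empty survival-record table")
    missing = [c for c in ("group", "time", "event") if c not in records.columns]
    if missing:
        raise ValueError(f"survival records missing columns {missing}")


def km(records: pd.DataFrame, horizon: int | None = None) -> KMEstimate:
    """Kaplan–Meier estimate per group with daily at-risk counts.

    At each distinct event time t the estimate multiplies by
    (1 - d_t / n_t); subjects censored at t remain at risk for events at t
    and leave the risk set afterwards.  ``horizon`` defaults to the largest
    observed time; the at-risk table counts, for each day in [0, horizon],
    subjects with ``time >= day``.
    """
    _check_records(records)
    if horizon is None:
        horizon = int(records["time"].max())
    curves: dict[str, pd.DataFrame] = {}
    risk_cols: dict[str, np.ndarray] = {}
    days = np.arange(horizon + 1)
    for group, sub in records.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        ev = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        df = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "n_risk": ev["at_risk"].to_numpy(dtype=int),
                "n_event": ev["observed"].to_numpy(dtype=int),
                "n_censored": ev["censored"].to_numpy(dtype=int),
                "survival": surv.to_numpy(dtype=float),
            }
        )
        df["cum_incidence"] = 1.0 - df["survival"]
        curves[str(group)] = df.reset_index(drop=True)
        t = sub["time"].to_numpy()
        risk_cols[str(group)] = np.array([(t >= d).sum() for d in days], dtype=int)
    at_risk = pd.DataFrame({"day": days, **risk_cols})
    return KMEstimate(curves=curves, at_risk_daily=at_risk, horizon=int(horizon))


def _two_group_arrays(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    groups = sorted(records["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    order = [g for g in GROUPS if g in groups] + [g for g in groups if g not in GROUPS]
    x = (records["group"] == order[0]).to_numpy(dtype=float)  # 1 = exposed arm
    return records["time"].to_numpy(dtype=float), records["event"].to_numpy(dtype=int), x


def log_rank(records: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test (observed minus expected, hypergeometric variance)."""
    _check_records(records)
    time, event, x = _two_group_arrays(records)
    if event.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(time[x == 1], time[x == 0], event[x == 1], event[x == 0])
    obs, exp = _observed_expected(time, event, x)
    return LogRankResult(
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        observed={"group1": obs[0], "group0": obs[1]},
        expected={"group1": exp[0], "group0": exp[1]},
    )


def _observed_expected(
    time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> tuple[tuple[float, float], tuple[float, float]]:
    o1 = float(event[x == 1].sum())
    o0 = float(event[x == 0].sum())
    e1 = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (x == 1)).sum()
        d = float(event[(time == t)].sum())
        e1 += d * n1 / n
    return (o1, o0), (e1, o1 + o0 - e1)


def cox_score_test(records: pd.DataFrame) -> tuple[float, float]:
    """Score chi-square for the group effect at beta = 0 (Breslow risk sets).

    For two groups this is algebraically the log-rank statistic: the score
    is the summed observed-minus-expected and its variance the summed
    hypergeometric variance over event times.
    """
    _check_records(records)
    time, event, x = _two_group_arrays(records)
    u = 0.0
    v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = float(at_risk.sum())
        n1 = float((at_risk & (x == 1)).sum())
        d = float(event[time == t].sum())
        d1 = float(event[(time == t) & (x == 1)].sum())
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = u * u / v
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _cox_breslow_group(time: np.ndarray, event: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Newton solve of the one-parameter Breslow partial likelihood (binary x)."""
    event_times = np.unique(time[event == 1])
    # per event time: deaths in each arm and risk-set counts per arm
    rows = []
    for t in event_times:
        at_risk = time >= t
        rows.append(
            (
                float(event[(time == t) & (x == 1)].sum()),
                float(event[time == t].sum()),
                float((at_risk & (x == 1)).sum()),
                float((at_risk & (x == 0)).sum()),
            )
        )
    beta = 0.0
    for _ in range(60):
        u = 0.0
        info = 0.0
        for d1, d, n1, n0 in rows:
            w = n1 * np.exp(beta)
            denom = w + n0
            mu = w / denom
            u += d1 - d * mu
            info += d * mu * (1 - mu)
        if info <= 0:
            raise MonotoneLikelihoodError(
                "monotone partial likelihood: one arm has no events at risk; "
                "the group hazard ratio is not identifiable"
            )
        step = u / info
        beta += np.clip(step, -5, 5)
        if abs(step) < 1e-12:
            break
    if abs(beta) > 25:
        raise MonotoneLikelihoodError(
            "group log hazard ratio diverged; check that both arms have events"
        )
    return beta, float(np.sqrt(1.0 / info))


def cox(
    records: pd.DataFrame,
    covariate_cols: list[str] | None = None,
    ties: str = "efron",
    level: float = 0.95,
) -> CoxResult:
    """Cox proportional-hazards fit for the group effect.

    The default model contains only the group indicator (1 = exposed arm);
    ``covariate_cols`` adds adjustment covariates from the record table.
    ``ties="efron"`` uses the Efron approximation (via lifelines);
    ``ties="breslow"`` is available for the group-only model.  Raises
    :class:`MonotoneLikelihoodError` when an arm has no events.
    """
    _check_records(records)
    time, event, x = _two_group_arrays(records)
    if event[x == 1].sum() == 0 or event[x == 0].sum() == 0:
        raise MonotoneLikelihoodError(
            "no events in one arm: the partial likelihood is monotone in the "
            "group effect; enlarge the cohort or lengthen follow-up"
        )
    zq = stats.norm.ppf(0.5 + level / 2.0)
    if ties == "breslow":
        if covariate_cols:
            raise ValueError("breslow ties are provided for the group-only model")
        beta, se = _cox_breslow_group(time, event, x)
    elif ties == "efron":
        cols = {"time": time, "event": event, "group_exposed": x}
        for c in covariate_cols or []:
            cols[c] = records[c].to_numpy(dtype=float)
        df = pd.DataFrame(cols)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        beta = float(cph.params_["group_exposed"])
        se = float(cph.standard_errors_["group_exposed"])
    else:
        raise ValueError("ties must be 'efron' or 'breslow'")
    z = beta / se
    return CoxResult(
        log_hr=beta,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zq * se)),
        ci_high=float(np.exp(beta + zq * se)),
        se=se,
        p=float(2 * stats.norm.sf(abs(z))),
        ties=ties,
        n=len(records),
        n_events=int(event.sum()),
    )
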