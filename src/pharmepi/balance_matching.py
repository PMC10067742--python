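"""Propensity-score estimation, 1:1 caliper matching, and balance diagnostics.

The propensity score is the modeled probability of being in the exposed arm
given baseline covariates, fit by plain (unpenalised) logistic regression.
Matching is greedy 1:1 nearest-neighbor without replacement: exposed
patients are visited in seeded-random order and each takes its closest
still-unmatched comparator, provided the score distance is within the
caliper.  The default caliper is 0.2 standard deviations of the logit
propensity score — the conventional reading of "a 0.2 caliper width" — with
a raw-probability-scale caliper available by flag.

Balance is reported as pre/post standardized mean differences (mean
difference over pooled SD), a chi-square test for binary covariates, and a
Wilcoxon rank-sum or Welch t-test for continuous ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class SeparationError(RuntimeError):
    """Perfect separation: the covariates predict exposure exactly."""


@dataclass(frozen=True)
class PropensityModel:
    """A fitted logistic exposure model and its per-patient scores."""

    feature_names: tuple[str, ...]
    coefficients: pd.Series  # includes "const"
    stderr: pd.Series  # Wald standard errors, aligned with coefficients
    scores: pd.Series  # P(exposed | x), strictly in (0,1), indexed like input
    exposed: pd.Series  # the exposure labels, aligned with scores

    @property
    def logit_scores(self) -> pd.Series:
        return np.log(self.scores / (1.0 - self.scores))


@dataclass(frozen=True)
class MatchedCohort:
    """1:1 matched pairs with the caliper actually used."""

    pairs: pd.DataFrame  # exposed_id, comparator_id, distance
    caliper: float  # on the matching scale
    caliper_scale: str  # "logit_sd" or "raw"
    n_exposed_unmatched: int
    n_comparator_unmatched: int

    def matched_ids(self) -> pd.Index:
        return pd.Index(
            list(self.pairs["exposed_id"]) + list(self.pairs["comparator_id"])
        )


def fit_propensity(
    covariates: pd.DataFrame,
    exposed: pd.Series,
    feature_cols: list[str] | None = None,
) -> PropensityModel:
    """Fit an additive logistic model of exposure on the covariates.

    ``covariates`` is the table from the cohort builder (may include a
    patient_id column, ignored as a feature); ``exposed`` is a boolean
    series aligned by position or index.  The fit is convex, hence
    deterministic given the data.  Perfect separation raises
    :class:`SeparationError` advising covariate reduction.
    """
    if feature_cols is None:
        feature_cols = [c for c in covariates.columns if c != "patient_id"]
    y = np.asarray(exposed, dtype=float)
    if y.min() == y.max():
        raise ValueError("exposure label is constant; propensity model is undefined")
    n_arm = min(int(y.sum()), int(len(y) - y.sum()))
    if n_arm < 2:
        raise ValueError("need at least 2 patients per arm to fit a propensity model")
    X = sm.add_constant(covariates[feature_cols].astype(float), has_constant="add")
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise SeparationError(
            "propensity fit failed (perfect separation or singular design); "
            "reduce or recode the covariates"
        ) from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 30:
        raise SeparationError(
            "propensity coefficients diverged, indicating (quasi-)separation; "
            "reduce or recode the covariates"
        )
    scores = pd.Series(np.clip(res.predict(X), 1e-12, 1 - 1e-12),
                       index=covariates.index)
    return PropensityModel(
        feature_names=tuple(feature_cols),
        coefficients=pd.Series(params, index=X.columns),
        stderr=pd.Series(np.asarray(res.bse, dtype=float), index=X.columns),
        scores=scores,
        exposed=pd.Series(y.astype(bool), index=covariates.index),
    )


def match(
    model: PropensityModel,
    caliper: float = 0.2,
    caliper_scale: str = "logit_sd",
    seed: int = 0,
    exact_cols: pd.DataFrame | None = None,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    ``caliper_scale="logit_sd"`` interprets ``caliper`` as a multiple of the
    pooled SD of the logit score and matches on the logit scale;
    ``"raw"`` matches on the probability scale with an absolute caliper.
    ``exact_cols`` (a DataFrame aligned with the scores, e.g. the exposure
    drug subtype) restricts pairs to identical values in every listed
    column.  Deterministic given ``seed``.
    """
    if caliper_scale not in ("logit_sd", "raw"):
        raise ValueError("caliper_scale must be 'logit_sd' or 'raw'")
    exp_mask = model.exposed.to_numpy()
    if exp_mask.all() or not exp_mask.any():
        raise ValueError("matching requires both an exposed and a comparator arm")
    if caliper_scale == "logit_sd":
        score = model.logit_scores
        width = caliper * float(score.std(ddof=1))
    else:
        score = model.scores
        width = caliper

    rng = np.random.default_rng(seed)
    exp_idx = score.index[exp_mask]
    cmp_idx = score.index[~exp_mask]
    order = rng.permutation(len(exp_idx))

    cmp_scores = score.loc[cmp_idx].to_numpy()
    sort_order = np.argsort(cmp_scores, kind="stable")
    cmp_sorted = cmp_scores[sort_order]
    cmp_ids_sorted = np.asarray(cmp_idx)[sort_order]
    available = np.ones(len(cmp_idx), dtype=bool)
    exact = None
    if exact_cols is not None:
        exact = exact_cols.astype(str).agg("|".join, axis=1)
        exact_sorted = exact.loc[cmp_idx].to_numpy()[sort_order]

    pairs = []
    for k in order:
        eid = exp_idx[k]
        s = float(score.loc[eid])
        lo = np.searchsorted(cmp_sorted, s - width, side="left")
        hi = np.searchsorted(cmp_sorted, s + width, side="right")
        best_j, best_d = -1, np.inf
        for j in range(lo, hi):
            if not available[j]:
                continue
            if exact is not None and exact_sorted[j] != exact.loc[eid]:
                continue
            d = abs(cmp_sorted[j] - s)
            if d < best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            available[best_j] = False
            pairs.append(
                {"exposed_id": eid, "comparator_id": cmp_ids_sorted[best_j],
                 "distance": best_d}
            )
    pairs_df = pd.DataFrame(pairs, columns=["exposed_id", "comparator_id", "distance"])
    return MatchedCohort(
        pairs=pairs_df,
        caliper=width,
        caliper_scale=caliper_scale,
        n_exposed_unmatched=int(exp_mask.sum()) - len(pairs_df),
        n_comparator_unmatched=int((~exp_mask).sum()) - len(pairs_df),
    )


def _smd(x1: np.ndarray, x0: np.ndarray) -> tuple[float, bool]:
    """Standardized mean difference with a zero-variance flag."""
    v1, v0 = np.var(x1, ddof=1) if len(x1) > 1 else 0.0, np.var(x0, ddof=1) if len(x0) > 1 else 0.0
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0.0:
        return 0.0, True
    return float((np.mean(x1) - np.mean(x0)) / pooled), False


def balance(
    matched: MatchedCohort,
    covariates: pd.DataFrame,
    exposed: pd.Series,
    feature_cols: list[str] | None = None,
    continuous_test: str = "wilcoxon",
) -> pd.DataFrame:
    """Pre/post-match SMD plus hypothesis tests per covariate.

    Binary covariates get a chi-square test on the post-match 2x2 table;
    continuous covariates a Wilcoxon rank-sum (default) or Welch t-test.
    Post-match statistics use matched patients only.  Zero-variance
    covariates report SMD 0 with ``degenerate=True``.
    """
    if matched.pairs.empty:
        raise ValueError("balance requires at least one matched pair")
    if feature_cols is None:
        feature_cols = [c for c in covariates.columns if c != "patient_id"]
    if continuous_test not in ("wilcoxon", "welch"):
        raise ValueError("continuous_test must be 'wilcoxon' or 'welch'")
    exp_mask = np.asarray(exposed, dtype=bool)
    m_exp = covariates.loc[matched.pairs["exposed_id"]]
    m_cmp = covariates.loc[matched.pairs["comparator_id"]]
    rows = []
    for col in feature_cols:
        pre1 = covariates.loc[exp_mask, col].to_numpy(dtype=float)
        pre0 = covariates.loc[~exp_mask, col].to_numpy(dtype=float)
        post1 = m_exp[col].to_numpy(dtype=float)
        post0 = m_cmp[col].to_numpy(dtype=float)
        smd_pre, deg_pre = _smd(pre1, pre0)
        smd_post, deg_post = _smd(post1, post0)
        binary = set(np.unique(np.concatenate([pre1, pre0]))) <= {0.0, 1.0}
        if binary:
            table = np.array(
                [[post1.sum(), len(post1) - post1.sum()],
                 [post0.sum(), len(post0) - post0.sum()]]
            )
            if table[:, 0].sum() in (0, table.sum()) or deg_post:
                p = 1.0
                test = "chi2 (degenerate)"
            else:
                p = float(stats.chi2_contingency(table, correction=True)[1])
                test = "chi2"
        elif continuous_test == "wilcoxon":
            p = float(stats.ranksums(post1, post0).pvalue)
            test = "wilcoxon"
        else:
            p = float(stats.ttest_ind(post1, post0, equal_var=False).pvalue)
            test = "welch"
        rows.append(
            {"covariate": col, "smd_pre": smd_pre, "smd_post": smd_post,
             "test": test, "p_post": p, "degenerate": deg_pre or deg_post}
        )
    return pd.DataFrame(rows)
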