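"""Propensity model fitting, greedy caliper matching, and balance reporting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pharmepi.balance_matching import (
    MatchedCohort,
    SeparationError,
    balance,
    fit_propensity,
    match,
)


def confounded_sample(rng: np.random.Generator, n: int = 2000,
                      beta: float = 1.5) -> tuple[pd.DataFrame, pd.Series]:
    x1 = (rng.random(n) < 0.3).astype(float)
    x2 = rng.normal(0, 1, n)
    logit = -1.0 + beta * x1 + 0.8 * x2
    exposed = rng.random(n) < 1 / (1 + np.exp(-logit))
    cov = pd.DataFrame({"x1": x1, "x2": x2},
                       index=[f"P{i}" for i in range(n)])
    return cov, pd.Series(exposed, index=cov.index)


class TestFitPropensity:
    def test_null_coefficients_near_zero(self):
        rng = np.random.default_rng(1)
        cov, _ = confounded_sample(rng, n=4000)
        exposed = pd.Series(rng.random(4000) < 0.4, index=cov.index)
        m = fit_propensity(cov, exposed)
        for name in ("x1", "x2"):
            assert abs(m.coefficients[name]) < 3 * m.stderr[name]

    def test_confounder_sign_recovered(self):
        cov, exposed = confounded_sample(np.random.default_rng(2))
        m = fit_propensity(cov, exposed)
        assert m.coefficients["x1"] > 0 and m.coefficients["x2"] > 0

    def test_scores_strictly_inside_unit_interval(self):
        cov, exposed = confounded_sample(np.random.default_rng(3), n=500)
        m = fit_propensity(cov, exposed)
        assert ((m.scores > 0) & (m.scores < 1)).all()

    def test_perfect_separation_raises(self):
        x = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        exposed = pd.Series([False] * 20 + [True] * 20)
        with pytest.raises(SeparationError):
            fit_propensity(x, exposed)

    def test_constant_label_rejected(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            fit_propensity(x, pd.Series([True] * 10))


def model_from_scores(scores: dict, exposed_ids: set):
    """Bypass the logistic fit: construct a model with given raw scores."""
    from pharmepi.balance_matching import PropensityModel

    s = pd.Series(scores)
    return PropensityModel(
        feature_names=("x",),
        coefficients=pd.Series({"const": 0.0, "x": 0.0}),
        stderr=pd.Series({"const": 1.0, "x": 1.0}),
        scores=s,
        exposed=pd.Series({k: k in exposed_ids for k in scores}),
    )


def greedy_oracle(scores: dict, exposed_ids: set, width: float, order: tuple):
    """Straight-line greedy matcher for a given visit order (raw scale)."""
    taken = set()
    pairs = []
    for eid in order:
        best, bd = None, None
        for cid, sc in scores.items():
            if cid in exposed_ids or cid in taken:
                continue
            d = abs(sc - scores[eid])
            if d <= width and (bd is None or d < bd):
                best, bd = cid, d
        if best is not None:
            taken.add(best)
            pairs.append((eid, best, bd))
    return pairs


class TestMatch:
    def test_identical_distributions_large_caliper_matches_all_exposed(self):
        scores = {f"E{i}": 0.3 + 0.01 * i for i in range(5)}
        scores.update({f"C{i}": 0.3 + 0.01 * i for i in range(10)})
        m = model_from_scores(scores, {f"E{i}" for i in range(5)})
        res = match(m, caliper=0.5, caliper_scale="raw", seed=0)
        assert len(res.pairs) == 5
        assert res.n_exposed_unmatched == 0

    def test_nearest_comparator_beyond_caliper_gives_no_pair(self):
        m = model_from_scores({"E0": 0.9, "C0": 0.1}, {"E0"})
        res = match(m, caliper=0.2, caliper_scale="raw", seed=0)
        assert res.pairs.empty
        assert res.n_exposed_unmatched == 1

    def test_matches_exhaustive_greedy_oracle_all_orders(self):
        rng = np.random.default_rng(8)
        exposed_ids = {f"E{i}" for i in range(5)}
        scores = {f"E{i}": float(rng.random()) for i in range(5)}
        scores.update({f"C{i}": float(rng.random()) for i in range(12)})
        width = 0.15
        m = model_from_scores(scores, exposed_ids)
        res = match(m, caliper=width, caliper_scale="raw", seed=3)
        counts = set()
        for order in itertools.permutations(sorted(exposed_ids)):
            counts.add(len(greedy_oracle(scores, exposed_ids, width, order)))
        assert len(res.pairs) in counts
        assert (res.pairs["distance"] <= width + 1e-12).all()
        # replay our own visit order through the oracle: must agree exactly
        replay = greedy_oracle(scores, exposed_ids, width,
                               tuple(res.pairs["exposed_id"]))
        got = {(e, c) for e, c, _ in replay}
        assert got == set(zip(res.pairs["exposed_id"], res.pairs["comparator_id"]))

    def test_without_replacement_and_pair_bound(self):
        rng = np.random.default_rng(4)
        cov, exposed = confounded_sample(rng, n=600)
        from pharmepi.balance_matching import fit_propensity

        m = fit_propensity(cov, exposed)
        res = match(m, seed=7)
        ids = list(res.pairs["exposed_id"]) + list(res.pairs["comparator_id"])
        assert len(ids) == len(set(ids))
        assert len(res.pairs) <= min(int(exposed.sum()), int((~exposed).sum()))
        assert (res.pairs["distance"] <= res.caliper + 1e-12).all()

    def test_deterministic_given_seed(self):
        cov, exposed = confounded_sample(np.random.default_rng(5), n=400)
        m = fit_propensity(cov, exposed)
        a = match(m, seed=11).pairs
        b = match(m, seed=11).pairs
        pd.testing.assert_frame_equal(a, b)

    def test_exact_constraint_restricts_pairs(self):
        scores = {"E0": 0.5, "C0": 0.5, "C1": 0.52}
        m = model_from_scores(scores, {"E0"})
        subtype = pd.DataFrame({"fq": {"E0": "levo", "C0": "cipro", "C1": "levo"}})
        res = match(m, caliper=0.5, caliper_scale="raw", seed=0, exact_cols=subtype)
        assert list(res.pairs["comparator_id"]) == ["C1"]

    def test_empty_arm_rejected(self):
        m = model_from_scores({"E0": 0.5, "E1": 0.6}, {"E0", "E1"})
        with pytest.raises(ValueError, match="arm"):
            match(m)


class TestBalance:
    def _matched(self, pairs):
        return MatchedCohort(
            pairs=pd.DataFrame(pairs, columns=["exposed_id", "comparator_id", "distance"]),
            caliper=1.0, caliper_scale="raw",
            n_exposed_unmatched=0, n_comparator_unmatched=0,
        )

    def test_identical_arms_zero_smd(self):
        cov = pd.DataFrame(
            {"x": [1.0, 2.0, 1.0, 2.0], "b": [0, 1, 0, 1]},
            index=["E0", "E1", "C0", "C1"],
        )
        exposed = pd.Series([True, True, False, False], index=cov.index)
        rep = balance(self._matched([("E0", "C0", 0.0), ("E1", "C1", 0.0)]), cov, exposed)
        assert (rep["smd_post"] == 0).all()

    def test_six_pair_smd_hand_arithmetic(self):
        e = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        c = [2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
        cov = pd.DataFrame({"x": e + c},
                           index=[f"E{i}" for i in range(6)] + [f"C{i}" for i in range(6)])
        exposed = pd.Series([True] * 6 + [False] * 6, index=cov.index)
        rep = balance(
            self._matched([(f"E{i}", f"C{i}", 0.0) for i in range(6)]), cov, exposed
        )
        pooled = np.sqrt((np.var(e, ddof=1) + np.var(c, ddof=1)) / 2)
        assert rep.iloc[0]["smd_pre"] == pytest.approx((np.mean(e) - np.mean(c)) / pooled)
        assert rep.iloc[0]["smd_post"] == rep.iloc[0]["smd_pre"]  # same individuals

    def test_zero_variance_covariate_flagged(self):
        cov = pd.DataFrame({"x": [1.0] * 4}, index=["E0", "E1", "C0", "C1"])
        exposed = pd.Series([True, True, False, False], index=cov.index)
        rep = balance(self._matched([("E0", "C0", 0.0), ("E1", "C1", 0.0)]), cov, exposed)
        assert rep.iloc[0]["smd_post"] == 0 and bool(rep.iloc[0]["degenerate"])

    def test_confounded_simulation_post_smd_below_pre(self):
        cov, exposed = confounded_sample(np.random.default_rng(17), n=4000)
        m = fit_propensity(cov, exposed)
        res = match(m, seed=1)
        rep = balance(res, cov, exposed)
        assert (rep["smd_post"].abs() < rep["smd_pre"].abs()).all()
        # chi2 for binary, wilcoxon for continuous
        assert set(rep["test"]) == {"chi2", "wilcoxon"}

    def test_welch_option(self):
        cov, exposed = confounded_sample(np.random.default_rng(19), n=1000)
        m = fit_propensity(cov, exposed)
        res = match(m, seed=1)
        rep = balance(res, cov, exposed, continuous_test="welch")
        assert "welch" in set(rep["test"])
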