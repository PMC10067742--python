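"""Run-in exclusion, index/concomitant assignment, survival-record construction."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_eligible, brute_force_index, brute_force_survival
from pharmepi.cohort_builder import (
    ClaimsStore,
    CohortSpec,
    apply_run_in,
    assign_index,
    build_covariates,
    build_survival,
    cumulative_incidence,
    load_claims,
    write_claims,
)
from pharmepi.synthetic_data import ClaimsSimConfig, CovariateSpec, generate_claims

SPEC = CohortSpec(
    outcome_codes=frozenset({"M76.9"}),
    exposure_codes=frozenset({"J01MA12"}),
    comod_codes=frozenset({"H02AB02"}),
)


def tiny_store(patients, rx=(), dx=()):
    return ClaimsStore(
        patients=pd.DataFrame(patients, columns=["patient_id", "age", "sex",
                                                 "enroll_start", "enroll_end"]),
        prescriptions=pd.DataFrame(rx, columns=["patient_id", "day", "code",
                                                "route", "days_supply"]),
        diagnoses=pd.DataFrame(dx, columns=["patient_id", "day", "code"]),
    )


def simulated_store(seed=0, n=300, **overrides):
    cfg = ClaimsSimConfig(
        n_patients=n,
        exposure_intercept=-0.5,
        route_topical_fraction=0.15,
        comod_prob=0.5,
        baseline_hazard=5e-4,
        exposure_log_hr=0.5,
        covariate_spec=(CovariateSpec("diabetes", "binary", prevalence=0.2),),
        seed=seed,
        **overrides,
    )
    return generate_claims(cfg)[0]


class TestApplyRunIn:
    def test_outcome_during_run_in_excluded(self):
        store = tiny_store(
            [("P1", 50, "F", 0, 400)], dx=[("P1", 10, "M76.9")]
        )
        assert apply_run_in(store, SPEC) == frozenset()

    def test_clean_run_in_with_later_exposure_eligible(self):
        store = tiny_store(
            [("P1", 50, "F", 0, 400)], rx=[("P1", 200, "J01MA12", "oral", 7)]
        )
        assert apply_run_in(store, SPEC) == frozenset({"P1"})

    def test_short_enrollment_excluded(self):
        store = tiny_store([("P1", 50, "F", 0, 100)])
        assert apply_run_in(store, SPEC) == frozenset()

    def test_comod_during_run_in_excluded_even_topical(self):
        # run-in disqualifies any prior use, irrespective of route
        store = tiny_store(
            [("P1", 50, "F", 0, 400)], rx=[("P1", 50, "H02AB02", "topical", 7)]
        )
        assert apply_run_in(store, SPEC) == frozenset()

    def test_matches_brute_force_on_simulated_store(self):
        store = simulated_store(seed=21)
        assert apply_run_in(store, SPEC) == frozenset(brute_force_eligible(store, SPEC))


class TestAssignIndex:
    def _one_patient(self, rx):
        store = tiny_store([("P1", 50, "F", 0, 600)], rx=rx)
        eligible = frozenset({"P1"})
        return assign_index(store, SPEC, eligible, design="fq")

    def test_comod_five_days_before_index_is_concomitant(self):
        out = self._one_patient(
            [("P1", 300, "J01MA12", "oral", 7), ("P1", 295, "H02AB02", "oral", 5)]
        )
        assert out.iloc[0]["index_day"] == 300 and bool(out.iloc[0]["exposed"])

    @pytest.mark.parametrize(
        "offset,expected",
        [(-7, True), (-8, False), (30, True), (31, False), (0, True)],
    )
    def test_window_boundaries_inclusive(self, offset, expected):
        out = self._one_patient(
            [("P1", 300, "J01MA12", "oral", 7),
             ("P1", 300 + offset, "H02AB02", "oral", 5)]
        )
        assert bool(out.iloc[0]["exposed"]) is expected

    def test_topical_exposure_never_indexes(self):
        out = self._one_patient([("P1", 300, "J01MA12", "topical", 7)])
        assert out.empty

    def test_topical_comod_not_concomitant(self):
        out = self._one_patient(
            [("P1", 300, "J01MA12", "oral", 7), ("P1", 301, "H02AB02", "topical", 5)]
        )
        assert not bool(out.iloc[0]["exposed"])

    def test_first_systemic_prescription_defines_index(self):
        out = self._one_patient(
            [("P1", 350, "J01MA12", "oral", 7), ("P1", 250, "J01MA12", "topical", 7),
             ("P1", 300, "J01MA12", "oral", 7)]
        )
        assert out.iloc[0]["index_day"] == 300

    def test_older_design_comparator_clock_starts_at_run_in_end(self):
        spec = CohortSpec(
            outcome_codes=frozenset({"M76.9"}), exposure_codes=frozenset(),
            comod_codes=frozenset({"H02AB02"}), min_age=65, follow_up_days=180,
        )
        store = tiny_store(
            [("P1", 70, "F", 10, 600), ("P2", 70, "M", 0, 600), ("P3", 50, "F", 0, 600)],
            rx=[("P1", 400, "H02AB02", "oral", 5)],
        )
        out = assign_index(store, spec, frozenset({"P1", "P2", "P3"}), design="older")
        by_id = out.set_index("patient_id")
        assert by_id.loc["P1", "index_day"] == 400 and bool(by_id.loc["P1", "exposed"])
        assert by_id.loc["P2", "index_day"] == 180 and not bool(by_id.loc["P2", "exposed"])
        assert "P3" not in by_id.index  # under min_age

    @pytest.mark.parametrize("design", ["fq", "older"])
    def test_matches_brute_force_on_simulated_store(self, design):
        store = simulated_store(seed=33)
        spec = SPEC if design == "fq" else CohortSpec(
            outcome_codes=frozenset({"M76.9"}), exposure_codes=frozenset(),
            comod_codes=frozenset({"J01MA12"}), follow_up_days=180,
        )
        eligible = apply_run_in(store, spec)
        got = assign_index(store, spec, eligible, design=design)
        expected = brute_force_index(store, spec, set(eligible), design=design)
        got_map = {r.patient_id: (r.index_day, bool(r.exposed))
                   for r in got.itertuples(index=False)}
        assert got_map == expected


class TestBuildSurvival:
    def test_administrative_censoring(self):
        store = tiny_store([("P1", 50, "F", 0, 600)])
        idx = pd.DataFrame([{"patient_id": "P1", "index_day": 200, "exposed": True}])
        rec = build_survival(store, SPEC, idx).iloc[0]
        assert (rec["time"], rec["event"]) == (SPEC.follow_up_days, 0)
        assert rec["group"] == "exposed"

    def test_event_during_follow_up(self):
        store = tiny_store([("P1", 50, "F", 0, 600)], dx=[("P1", 210, "M76.9")])
        idx = pd.DataFrame([{"patient_id": "P1", "index_day": 200, "exposed": False}])
        rec = build_survival(store, SPEC, idx).iloc[0]
        assert (rec["time"], rec["event"]) == (10, 1)

    def test_outcome_on_index_day_kept_as_time_zero_event(self):
        store = tiny_store([("P1", 50, "F", 0, 600)], dx=[("P1", 200, "M76.9")])
        idx = pd.DataFrame([{"patient_id": "P1", "index_day": 200, "exposed": False}])
        rec = build_survival(store, SPEC, idx).iloc[0]
        assert (rec["time"], rec["event"]) == (0, 1)

    def test_disenrollment_censors_before_follow_up_end(self):
        store = tiny_store([("P1", 50, "F", 0, 230)], dx=[("P1", 228, "M76.9")])
        idx = pd.DataFrame([{"patient_id": "P1", "index_day": 200, "exposed": False}])
        rec = build_survival(store, SPEC, idx).iloc[0]
        assert (rec["time"], rec["event"]) == (28, 1)

    def test_matches_brute_force_on_simulated_store(self):
        store = simulated_store(seed=55)
        eligible = apply_run_in(store, SPEC)
        idx = assign_index(store, SPEC, eligible, design="fq")
        got = build_survival(store, SPEC, idx)
        index_map = {r.patient_id: (int(r.index_day), bool(r.exposed))
                     for r in idx.itertuples(index=False)}
        expected = brute_force_survival(store, SPEC, index_map)
        got_map = {r.patient_id: (r.time, r.event) for r in got.itertuples(index=False)}
        assert got_map == expected
        assert ((got["time"] >= 0) & (got["time"] <= SPEC.follow_up_days)).all()


class TestBuildCovariates:
    def _store(self):
        return tiny_store(
            [("P1", 70, "M", 0, 600)],
            rx=[("P1", 150, "H02AB02", "oral", 5)],
            dx=[("P1", 100, "E11"), ("P1", 200, "I10")],
        )

    def test_lookback_flags(self):
        idx = pd.DataFrame([{"patient_id": "P1", "index_day": 200, "exposed": True}])
        cov = build_covariates(
            self._store(), idx,
            comorbidity_codes={"diabetes": frozenset({"E11"}),
                               "hypertension": frozenset({"I10"})},
            medication_codes={"steroid": frozenset({"H02AB02"})},
        ).iloc[0]
        assert cov["dx_diabetes"] == 1
        assert cov["dx_hypertension"] == 0  # on index day itself: strictly pre-index
        assert cov["rx_steroid"] == 1
        assert cov["age"] == 70 and cov["sex_male"] == 1

    def test_empty_history_all_zero(self):
        store = tiny_store([("P1", 70, "F", 0, 600)])
        idx = pd.DataFrame([{"patient_id": "P1", "index_day": 200, "exposed": False}])
        cov = build_covariates(
            store, idx, comorbidity_codes={"diabetes": frozenset({"E11"})}
        ).iloc[0]
        assert cov["dx_diabetes"] == 0

    def test_record_before_lookback_window_ignored(self):
        idx = pd.DataFrame([{"patient_id": "P1", "index_day": 500, "exposed": True}])
        cov = build_covariates(
            self._store(), idx, lookback_days=180,
            comorbidity_codes={"diabetes": frozenset({"E11"})},
        ).iloc[0]
        assert cov["dx_diabetes"] == 0  # day 100 < 500 - 180

    def test_matches_brute_force_window_scan(self):
        store = simulated_store(seed=77)
        eligible = apply_run_in(store, SPEC)
        idx = assign_index(store, SPEC, eligible, design="fq")
        cov = build_covariates(
            store, idx, comorbidity_codes={"diabetes": frozenset({"DX_DIABETES"})}
        ).set_index("patient_id")
        dx = store.diagnoses
        for r in idx.itertuples(index=False):
            mine = dx[(dx["patient_id"] == r.patient_id) & (dx["code"] == "DX_DIABETES")]
            expected = int(any(
                r.index_day - 180 <= day < r.index_day for day in mine["day"]
            ))
            assert cov.loc[r.patient_id, "dx_diabetes"] == expected


class TestCumulativeIncidence:
    def test_two_percent(self):
        rec = pd.DataFrame(
            {"group": ["exposed"] * 100, "time": [30] * 100,
             "event": [1, 1] + [0] * 98}
        )
        out = cumulative_incidence(rec)
        assert out.iloc[0]["proportion"] == pytest.approx(0.02)

    def test_zero_events_ci_lower_bound_zero(self):
        rec = pd.DataFrame({"group": ["a"] * 50, "time": [30] * 50, "event": [0] * 50})
        out = cumulative_incidence(rec)
        assert out.iloc[0]["proportion"] == 0.0
        assert out.iloc[0]["ci_low"] == 0.0

    def test_hand_tally_20_records(self):
        rec = pd.DataFrame(
            {
                "group": ["exposed"] * 8 + ["comparator"] * 12,
                "time": list(range(20)),
                "event": [1, 0, 1, 0, 0, 0, 0, 0] + [1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
            }
        )
        out = cumulative_incidence(rec).set_index("group")
        assert out.loc["exposed", "proportion"] == pytest.approx(2 / 8)
        assert out.loc["comparator", "proportion"] == pytest.approx(3 / 12)
        assert out.loc["exposed", "ci_low"] < 2 / 8 < out.loc["exposed", "ci_high"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cumulative_incidence(pd.DataFrame(columns=["group", "time", "event"]))


def test_claims_round_trip_and_containment(tmp_path):
    store = simulated_store(seed=91, n=100)
    store.validate_containment()
    write_claims(store, tmp_path)
    back = load_claims(tmp_path)
    pd.testing.assert_frame_equal(store.patients, back.patients)
    pd.testing.assert_frame_equal(
        store.prescriptions.reset_index(drop=True), back.prescriptions
    )
    pd.testing.assert_frame_equal(
        store.diagnoses.reset_index(drop=True), back.diagnoses
    )
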