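import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from helmet.data_model import (
    PatientRecord,
    ScanRecord,
    StaticProfile,
    TimedValue,
    TreatmentEvent,
)
from helmet.observation_builder import (
    FFILL_SUFFIX,
    PRIOR_MLS_FEATURE,
    RMAX_SUFFIX,
    FeatureSchema,
    ImputerStats,
    build_hourly_grid,
    build_observations,
    forward_fill,
    rolling_max_24h,
)


def _patient(admission=2.0, end=10.0, treatments=(), scans=()):
    return PatientRecord(
        static=StaticProfile("g", admission_hour=admission, features={}),
        treatments=list(treatments),
        scans=list(scans),
        end_hour=end,
    )


class TestHourlyGrid:
    def test_simple_admission_to_discharge(self):
        assert build_hourly_grid(_patient(2.0, 10.0)) == list(range(2, 11))

    def test_hemicraniectomy_truncates_grid(self):
        rec = _patient(2.0, 80.0, treatments=[TreatmentEvent(50.0, "hemicraniectomy")])
        grid = build_hourly_grid(rec)
        assert grid[0] == 2 and grid[-1] < 50

    def test_seven_day_cap_from_admission(self):
        grid = build_hourly_grid(_patient(2.0, 400.0))
        assert grid[-1] == 2 + 168

    def test_fractional_admission_rounds_up(self):
        assert build_hourly_grid(_patient(2.4, 5.0))[0] == 3


class TestTransforms:
    def test_forward_fill_takes_most_recent(self):
        s = [TimedValue("x", 3.0, 5.0), TimedValue("x", 9.0, 7.0)]
        out = forward_fill(s, [2, 5, 9, 10])
        assert np.isnan(out[0])           # before any measurement
        assert out[1] == 5.0
        assert out[2] == 7.0              # most recent wins at its own hour
        assert out[3] == 7.0

    def test_rolling_max_window_is_24h_half_open(self):
        s = [TimedValue("x", 1.0, 4.0), TimedValue("x", 10.0, 9.0)]
        out = rolling_max_24h(s, [12, 25, 30, 34])
        assert out[0] == 9.0
        assert out[1] == 9.0              # hour 1 left the window, 10 still in
        assert out[2] == 9.0
        assert np.isnan(out[3])           # everything older than 24 h

    def test_single_value_is_its_own_max(self):
        s = [TimedValue("x", 5.0, 2.5)]
        assert rolling_max_24h(s, [5])[0] == 2.5

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_forward_fill_is_idempotent(self, pairs):
        series = sorted(
            (TimedValue("x", h, v) for h, v in pairs), key=lambda t: t.hour
        )
        grid = list(range(0, 101))
        once = forward_fill(series, grid)
        refilled = [
            TimedValue("x", float(h), float(v))
            for h, v in zip(grid, once)
            if not np.isnan(v)
        ]
        twice = forward_fill(refilled, grid)
        assert np.array_equal(once, twice, equal_nan=True)

    def test_rolling_max_dominates_forward_fill(self, small_obs, schema):
        for var in ("glucose", "wbc"):
            f = small_obs[var + FFILL_SUFFIX]
            m = small_obs[var + RMAX_SUFFIX]
            both = f.notna() & m.notna()
            assert (m[both] >= f[both] - 1e-12).all()


class TestFeatureSchema:
    def test_reference_feature_counts(self, schema):
        assert len(schema.static) == 33
        assert len(schema.dynamic_features()) == 2 * 16
        assert len(schema.radiographic_features()) == 2 * 36 + 1
        assert len(schema.text_features()) == 12
        assert len(schema.feature_names()) == 33 + 32 + 73 + 12

    def test_feature_count_identity_generalizes(self):
        custom = FeatureSchema(static=["a"], dynamic=["b", "c"], radiographic=["mls_mm"])
        assert len(custom.feature_names()) == 1 + 2 * 2 + (2 * 1 + 1) + 12
        no_text = FeatureSchema(
            static=["a"], dynamic=["b"], radiographic=["mls_mm"], include_text=False
        )
        assert len(no_text.feature_names()) == 1 + 2 + 3

    def test_every_feature_has_one_category(self, schema):
        cats = schema.categories()
        assert set(cats) == set(schema.feature_names())
        assert set(cats.values()) <= {"llm_text", "human_radiographic", "dynamic_ehr", "static"}


class TestBuildObservations:
    def test_no_observation_precedes_first_scan(self, small_cohort, schema, small_obs):
        first_scan = {r.patient_id: r.scans[0].hour for r in small_cohort if r.scans}
        hours = small_obs["hour"].to_numpy()
        firsts = small_obs["patient_id"].map(first_scan).to_numpy()
        assert (hours >= firsts).all()

    def test_prior_mls_missing_until_second_scan(self):
        rec = _patient(2.0, 30.0, scans=[ScanRecord(hour=3.0, mls_mm=1.0)])
        obs = build_observations(rec, FeatureSchema(include_text=False))
        assert obs[PRIOR_MLS_FEATURE].isna().all()

    def test_current_class_tracks_most_recent_scan(self):
        rec = _patient(
            2.0, 30.0,
            scans=[ScanRecord(hour=3.0, mls_mm=1.0), ScanRecord(hour=10.0, mls_mm=6.0)],
        )
        obs = build_observations(rec, FeatureSchema(include_text=False))
        assert (obs.loc[obs.hour < 10, "current_class"] == 1).all()
        assert (obs.loc[obs.hour >= 10, "current_class"] == 2).all()


class TestImputer:
    def test_static_means_computed_over_patients(self, schema):
        # three patients: ages 60, 80, missing -> mean 70
        rows = []
        for pid, age in (("a", 60.0), ("b", 80.0), ("c", np.nan)):
            row = {c: 0.0 for c in schema.feature_names()}
            row.update(patient_id=pid, hour=5, current_class=0, age=age)
            rows.append(row)
            rows.append({**row, "hour": 6})  # repeated hours must not bias the mean
        obs = pd.DataFrame(rows)
        stats = ImputerStats.fit(obs, schema)
        assert stats.means["age"] == pytest.approx(70.0)
        out = stats.transform(obs)
        assert (out.loc[out.patient_id == "c", "age"] == 70.0).all()

    def test_fit_on_split_a_applied_to_split_b(self, small_obs, schema):
        pids = small_obs["patient_id"].unique()
        a, b = set(pids[:10]), set(pids[10:])
        stats = ImputerStats.fit(small_obs, schema, sorted(a))
        expected = small_obs[small_obs.patient_id.isin(a)].groupby("patient_id").first()["age"].mean()
        assert stats.means["age"] == pytest.approx(expected)
        out = stats.transform(small_obs[small_obs.patient_id.isin(b)])
        assert not out[schema.feature_names()].isna().any().any()

    def test_entirely_missing_feature_is_an_error(self, schema):
        row = {c: 0.0 for c in schema.feature_names()}
        row.update(patient_id="a", hour=1, current_class=0, age=np.nan)
        obs = pd.DataFrame([row])
        with pytest.raises(ValueError, match="age"):
            ImputerStats.fit(obs, schema)
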