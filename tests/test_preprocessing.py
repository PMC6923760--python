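import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnoclust.errors import SchemaError, ValidationError
from somnoclust.features import ALL_FEATURES, RETAINED_FEATURES
from somnoclust.preprocessing import (
    DailyRecord,
    FeaturePanel,
    build_panel,
    compliance_filter,
    load_daily_logs,
    minmax_normalize,
    preprocess,
    screen_features,
)
from somnoclust.synthetic import CohortSpec, default_regimes, generate_cohort, inject_noncompliance


def _make_records(subject_days: dict[str, list[int]], feat_fn=None):
    out = []
    for sid, days in subject_days.items():
        for d in days:
            feats = {f: float(d + 1) for f in ALL_FEATURES}
            feats["sleep_efficiency"] = 0.8
            feats["active_ratio"] = 0.3
            if feat_fn:
                feats = feat_fn(sid, d, feats)
            out.append(DailyRecord(sid, d, feats))
    return out


class TestLoadDailyLogs:
    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        path = tmp_path / "logs.csv"
        path.write_text(",".join(["subject_id", "day_index", *ALL_FEATURES]) + "\n")
        assert load_daily_logs(path) == []

    def test_round_trip_of_toy_table(self, tmp_path):
        rows = []
        for i in range(3):
            rows.append({"subject_id": f"S{i}", "day_index": i,
                         **{f: i + 0.5 for f in ALL_FEATURES},
                         "sleep_efficiency": 0.9, "active_ratio": 0.2})
        pd.DataFrame(rows).to_csv(tmp_path / "t.csv", index=False)
        recs = load_daily_logs(tmp_path / "t.csv")
        assert len(recs) == 3
        assert recs[1].features["sleep_min"] == pytest.approx(1.5)

    def test_generated_cohort_loads_with_expected_count(self, tmp_path, cohort_10x42):
        _, logs, _ = cohort_10x42
        logs.to_csv(tmp_path / "c.csv", index=False)
        assert len(load_daily_logs(tmp_path / "c.csv")) == 420

    def test_missing_column_raises_schema_error(self, tmp_path):
        pd.DataFrame({"subject_id": ["a"], "day_index": [0]}).to_csv(
            tmp_path / "bad.csv", index=False)
        with pytest.raises(SchemaError):
            load_daily_logs(tmp_path / "bad.csv")

    def test_non_numeric_cell_names_offending_row(self, tmp_path):
        row = {"subject_id": "a", "day_index": 0,
               **{f: 1.0 for f in ALL_FEATURES}}
        row["sleep_min"] = "oops"
        row["sleep_efficiency"] = 0.5
        row["active_ratio"] = 0.5
        pd.DataFrame([row]).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SchemaError, match="sleep_min"):
            load_daily_logs(tmp_path / "bad.csv")


class TestComplianceFilter:
    def test_three_day_run_excluded(self):
        recs = _make_records({"a": [d for d in range(20) if d not in (5, 6, 7)]})
        retained, excluded = compliance_filter(recs, study_days=20)
        assert excluded == ["a"] and retained == []

    def test_short_runs_retained(self):
        recs = _make_records({"a": [d for d in range(20) if d not in (5, 6, 9)]})
        retained, excluded = compliance_filter(recs, study_days=20)
        assert retained == ["a"] and excluded == []

    def test_injected_dropouts_reproduce_cohort_exclusion_count(self):
        """50-subject cohort, 8 injected 3-day gaps -> 42 retained."""
        spec = CohortSpec(n_subjects=50, n_days=42,
                          regimes=default_regimes(2), seed=21)
        logs, _ = generate_cohort(spec)
        logs = inject_noncompliance(logs, 8, 3, seed=22)
        recs = [DailyRecord(str(r["subject_id"]), int(r["day_index"]),
                            {f: float(r[f]) for f in ALL_FEATURES})
                for r in logs.to_dict("records")]
        retained, excluded = compliance_filter(recs, study_days=42)
        assert len(retained) == 42 and len(excluded) == 8

    def test_empty_input(self):
        assert compliance_filter([]) == ([], [])

    def test_relaxing_gap_never_shrinks_retained_set(self):
        recs = _make_records({
            "a": [d for d in range(15) if d not in (3, 4, 5)],
            "b": [d for d in range(15) if d not in (7,)],
            "c": [d for d in range(15) if d not in (0, 1, 2, 3)],
        })
        previous: set[str] = set()
        for gap in (1, 2, 3, 4, 5):
            retained, _ = compliance_filter(recs, max_consecutive_gap=gap,
                                            study_days=15)
            assert previous <= set(retained)
            previous = set(retained)


class TestScreenFeatures:
    def test_policy_exclusion_leaves_twelve_features(self, cohort_10x42):
        _, logs, _ = cohort_10x42
        recs = [DailyRecord(str(r["subject_id"]), int(r["day_index"]),
                            {f: float(r[f]) for f in ALL_FEATURES})
                for r in logs.to_dict("records")]
        report = screen_features(recs, correlation_threshold=2.0)
        assert report.retained == list(RETAINED_FEATURES)
        assert len(report.retained) == 12
        assert "onbed_min" in report.policy_excluded

    def test_threshold_one_and_no_policy_keeps_everything(self, cohort_10x42):
        _, logs, _ = cohort_10x42
        recs = [DailyRecord(str(r["subject_id"]), int(r["day_index"]),
                            {f: float(r[f]) for f in ALL_FEATURES})
                for r in logs.to_dict("records")]
        report = screen_features(recs, excluded_by_policy=set(),
                                 correlation_threshold=1.0)
        assert report.retained == list(ALL_FEATURES)

    def test_exact_collinearity_is_flagged(self):
        """onbed_min = sleep_min + constant has |r| = 1 and must be flagged
        at any threshold below 1."""
        rng = np.random.default_rng(0)

        def feat_fn(sid, d, feats):
            feats["sleep_min"] = float(rng.normal(400, 30))
            feats["onbed_min"] = feats["sleep_min"] + 60.0
            return feats

        recs = _make_records({"a": list(range(30))}, feat_fn)
        report = screen_features(recs, excluded_by_policy=set(),
                                 correlation_threshold=0.99)
        flagged_features = {f for f, _, _ in report.flagged_pairs} | {
            p for _, p, _ in report.flagged_pairs}
        assert "onbed_min" in flagged_features
        assert any(r == pytest.approx(1.0) for _, _, r in report.flagged_pairs)

    def test_all_excluded_raises(self):
        recs = _make_records({"a": [0, 1]})
        with pytest.raises(ValidationError):
            screen_features(recs, excluded_by_policy=set(ALL_FEATURES))


class TestMinmaxNormalize:
    def _panel(self, column: np.ndarray) -> FeaturePanel:
        return FeaturePanel(["s"], ["x"], {"s": column.reshape(-1, 1)})

    def test_affine_mapping(self):
        out = minmax_normalize(self._panel(np.array([0.0, 5.0, 10.0])))
        assert np.allclose(out.values["s"].ravel(), [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        out = minmax_normalize(self._panel(np.array([7.0, 7.0, 7.0])))
        assert np.allclose(out.values["s"], 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6,
                              allow_nan=False, allow_infinity=False),
                    min_size=3, max_size=40))
    def test_output_spans_unit_interval_and_preserves_order(self, xs):
        col = np.array(xs)
        out = minmax_normalize(self._panel(col)).values["s"].ravel()
        assert out.min() >= 0 and out.max() <= 1
        if col.max() > col.min():
            assert out.min() == pytest.approx(0) and out.max() == pytest.approx(1)
            # monotone: sorting by raw value leaves normalized values sorted
            order = np.argsort(col, kind="stable")
            assert np.all(np.diff(out[order]) >= -1e-12)

    def test_inverse_recovers_raw_values(self):
        rng = np.random.default_rng(3)
        col = rng.normal(50, 10, size=30)
        panel = self._panel(col)
        out = minmax_normalize(panel)
        back = out.inverse_transform(out.values["s"])
        assert np.allclose(back.ravel(), col, atol=1e-9)

    def test_idempotent_on_already_normalized_data(self):
        col = np.array([0.0, 0.25, 1.0])
        once = minmax_normalize(self._panel(col))
        twice = minmax_normalize(FeaturePanel(["s"], ["x"], once.values))
        assert np.allclose(once.values["s"], twice.values["s"])


def test_preprocess_end_to_end_gives_unit_scaled_dense_panel(cohort_10x42):
    _, logs, _ = cohort_10x42
    recs = [DailyRecord(str(r["subject_id"]), int(r["day_index"]),
                        {f: float(r[f]) for f in ALL_FEATURES})
            for r in logs.to_dict("records")]
    panel, report, excluded = preprocess(recs)
    assert excluded == []
    assert panel.feature_names == list(RETAINED_FEATURES)
    for sid in panel.subjects:
        mat = panel.values[sid]
        assert mat.shape == (42, 12)
        assert np.isfinite(mat).all()
        assert mat.min() >= 0 and mat.max() <= 1


def test_interpolation_fills_isolated_gaps():
    recs = _make_records({"a": [d for d in range(10) if d != 4]},
                         feat_fn=lambda s, d, f: {**f, "sleep_min": float(d)})
    panel = build_panel(recs, ["sleep_min"], study_days=10)
    col = panel.values["a"].ravel()
    assert col[4] == pytest.approx(4.0)  # linear between day 3 and 5
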