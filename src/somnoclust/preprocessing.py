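"""Daily-log preprocessing: compliance exclusion, feature screening,
pooled min-max normalization.

The raw input is a long table of subject-day rows carrying the 13 daily
aggregates. Preprocessing (i) drops subjects who failed to wear the
device for more than ``max_consecutive_gap`` consecutive days, (ii)
removes ``onbed_min`` and any sleep-stage columns and flags strongly
collinear survivors, (iii) linearly interpolates the short wear gaps of
retained subjects so each subject has a dense day x feature matrix, and
(iv) min-max normalizes each feature to [0, 1] over the pooled cohort so
that all subjects share one scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .features import ALL_FEATURES, ID_COLUMNS, POLICY_EXCLUDED, UNIT_INTERVAL_FEATURES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DailyRecord:
    """One subject-day of raw features (units: minutes, counts, kcal, fractions)."""

    subject_id: str
    day_index: int
    features: dict[str, float]

    def __post_init__(self) -> None:
        if self.day_index < 0:
            raise ValidationError("day_index must be >= 0")
        for name in UNIT_INTERVAL_FEATURES:
            v = self.features.get(name)
            if v is not None and not -1e-9 <= v <= 1 + 1e-9:
                raise ValidationError(f"{name}={v} outside [0, 1] for {self.subject_id}")


@dataclass
class FeaturePanel:
    """Dense per-subject day x feature matrices on a common [0, 1] scale."""

    subjects: list[str]
    feature_names: list[str]
    values: dict[str, np.ndarray]              # subject -> (n_days, n_features)
    normalization_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def matrix(self, subject_id: str) -> np.ndarray:
        return self.values[subject_id]

    def inverse_transform(self, mat: np.ndarray) -> np.ndarray:
        """Map normalized values back to raw units using the stored bounds."""
        lo = np.array([self.normalization_bounds[f][0] for f in self.feature_names])
        hi = np.array([self.normalization_bounds[f][1] for f in self.feature_names])
        return mat * (hi - lo) + lo

    def save_bounds(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {f: [float(a), float(b)] for f, (a, b) in self.normalization_bounds.items()},
                fh,
            )


def load_daily_logs(path) -> list[DailyRecord]:
    """Read a daily-log CSV into records; unknown columns are ignored with a warning."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "day_index"} | set(ALL_FEATURES)
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path} missing required columns: {sorted(missing)}")
    unknown = set(df.columns) - required - set(ID_COLUMNS)
    if unknown:
        logger.warning("ignoring unknown columns in %s: %s", path, sorted(unknown))
    records = []
    for i, row in df.iterrows():
        feats = {}
        for name in ALL_FEATURES:
            v = row[name]
            try:
                feats[name] = float(v)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"non-numeric value {v!r} for {name} at row {i}") from exc
            if np.isnan(feats[name]):
                raise SchemaError(f"missing value for {name} at row {i}")
        records.append(DailyRecord(str(row["subject_id"]), int(row["day_index"]), feats))
    return records


def records_to_frame(records: list[DailyRecord]) -> pd.DataFrame:
    rows = [{"subject_id": r.subject_id, "day_index": r.day_index, **r.features}
            for r in records]
    return pd.DataFrame(rows)


def _max_gap_run(present_days: set[int], study_days: int) -> int:
    longest = run = 0
    for d in range(study_days):
        if d in present_days:
            run = 0
        else:
            run += 1
            longest = max(longest, run)
    return longest


def compliance_filter(records: list[DailyRecord], max_consecutive_gap: int = 2,
                      study_days: int | None = None) -> tuple[list[str], list[str]]:
    """Split subjects into (retained, excluded) by the wear-compliance rule.

    A subject is excluded iff they have a run of strictly more than
    ``max_consecutive_gap`` consecutive missing days within the study span
    (inferred as max day_index + 1 unless given).
    """
    if not records:
        return [], []
    if study_days is None:
        study_days = max(r.day_index for r in records) + 1
    days: dict[str, set[int]] = {}
    for r in records:
        days.setdefault(r.subject_id, set()).add(r.day_index)
    retained, excluded = [], []
    for sid in sorted(days):
        if _max_gap_run(days[sid], study_days) > max_consecutive_gap:
            excluded.append(sid)
        else:
            retained.append(sid)
    return retained, excluded


@dataclass
class ScreeningReport:
    retained: list[str]
    policy_excluded: list[str]
    flagged_pairs: list[tuple[str, str, float]]  # (feature, retained partner, |r|)


def screen_features(records: list[DailyRecord],
                    excluded_by_policy: frozenset[str] | set[str] = POLICY_EXCLUDED,
                    correlation_threshold: float = 0.9,
                    drop_flagged: bool = False) -> ScreeningReport:
    """Apply the fixed exclusion policy, then flag collinear survivors.

    Policy-excluded names are removed unconditionally. Any remaining
    feature whose absolute Pearson correlation with an earlier retained
    feature exceeds the threshold is flagged (and only dropped when
    ``drop_flagged``). Output preserves the canonical feature order.
    """
    if not records:
        raise ValidationError("cannot screen features of an empty record list")
    present = [f for f in ALL_FEATURES if f in records[0].features]
    policy_removed = [f for f in present if f in excluded_by_policy]
    candidates = [f for f in present if f not in excluded_by_policy]
    if not candidates:
        raise ValidationError("all features excluded by policy")

    df = records_to_frame(records)
    flagged: list[tuple[str, str, float]] = []
    retained: list[str] = []
    for name in candidates:
        partner = None
        for kept in retained:
            r = df[name].corr(df[kept])
            if np.isfinite(r) and abs(r) > correlation_threshold:
                partner = (kept, abs(float(r)))
                break
        if partner is not None:
            flagged.append((name, partner[0], partner[1]))
            logger.warning("feature %s correlates with %s (|r|=%.3f > %.2f)",
                           name, partner[0], partner[1], correlation_threshold)
            if drop_flagged:
                continue
        retained.append(name)
    # also flag policy-removed features that are collinear, for the report
    for name in policy_removed:
        if name not in df.columns:
            continue
        for kept in retained:
            r = df[name].corr(df[kept])
            if np.isfinite(r) and abs(r) > correlation_threshold:
                flagged.append((name, kept, abs(float(r))))
                break
    if not retained:
        raise ValidationError("screening removed every feature")
    return ScreeningReport(retained, policy_removed, flagged)


def _dense_subject_matrix(sub: pd.DataFrame, feature_names: list[str],
                          study_days: int) -> np.ndarray:
    """Reindex one subject to the full day range and fill short gaps by
    linear interpolation (edge gaps by nearest value)."""
    mat = (
        sub.set_index("day_index")[feature_names]
        .reindex(range(study_days))
        .interpolate(method="linear", limit_direction="both")
    )
    return mat.to_numpy(dtype=float)


def build_panel(records: list[DailyRecord], feature_names: list[str],
                subjects: list[str] | None = None,
                study_days: int | None = None) -> FeaturePanel:
    """Assemble dense raw-unit matrices for the given subjects (pre-normalization)."""
    if not records:
        raise ValidationError("no records")
    df = records_to_frame(records)
    if study_days is None:
        study_days = int(df["day_index"].max()) + 1
    if subjects is None:
        subjects = sorted(df["subject_id"].unique())
    values = {}
    for sid in subjects:
        sub = df[df["subject_id"] == sid]
        if sub.empty:
            raise ValidationError(f"subject {sid} has no records")
        values[sid] = _dense_subject_matrix(sub, feature_names, study_days)
    return FeaturePanel(list(subjects), list(feature_names), values)


def minmax_normalize(panel: FeaturePanel) -> FeaturePanel:
    """Normalize each feature to [0, 1] with bounds pooled over the whole
    cohort; constant features map to 0 everywhere. Bounds are stored so
    the transform is exactly invertible for non-constant features."""
    stacked = np.vstack([panel.values[s] for s in panel.subjects])
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = {s: np.clip((panel.values[s] - lo) / safe, 0.0, 1.0) for s in panel.subjects}
    for s in out:  # constant features -> 0 by convention
        out[s][:, span == 0] = 0.0
    bounds = {f: (float(lo[j]), float(hi[j])) for j, f in enumerate(panel.feature_names)}
    return FeaturePanel(list(panel.subjects), list(panel.feature_names), out, bounds)


def preprocess(records: list[DailyRecord], max_consecutive_gap: int = 2,
               correlation_threshold: float = 0.9,
               study_days: int | None = None) -> tuple[FeaturePanel, ScreeningReport, list[str]]:
    """Full preprocessing: compliance filter -> screening -> dense panel ->
    pooled min-max normalization. Returns (normalized panel, screening
    report, excluded subject ids)."""
    retained, excluded = compliance_filter(records, max_consecutive_gap, study_days)
    if not retained:
        raise ValidationError("compliance filter excluded every subject")
    kept_records = [r for r in records if r.subject_id in set(retained)]
    report = screen_features(kept_records, correlation_threshold=correlation_threshold)
    panel = build_panel(kept_records, report.retained, retained, study_days)
    return minmax_normalize(panel), report, excluded
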