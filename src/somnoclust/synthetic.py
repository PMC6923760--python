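"""Synthetic wearable-log cohorts with planted behavioural regimes.

Real multi-week smart-band cohorts are rarely shareable, so every
downstream stage of the pipeline is exercised against cohorts generated
here. A cohort is a set of subjects, each following a first-order Markov
chain over a small number of behavioural *regimes* (distinct daily means
for sleep duration, sleep efficiency, active calories, steps, stairs,
...). Each subject-day emits the 13 raw daily aggregates of the device
schema: primary features are drawn from per-regime truncated Gaussians,
and the derived features (sleep efficiency, awake-in-bed minutes, the
get-up time) are recomputed from the sampled primaries so every row is
internally consistent. Non-wear is modelled as absent rows, either as
i.i.d. missing days or as injected multi-day gaps used to exercise the
compliance filter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .features import (
    ALL_FEATURES,
    DERIVED_FEATURES,
    FEATURE_BOUNDS,
    UNIT_INTERVAL_FEATURES,
)

STUDY_START = date(2018, 4, 23)


@dataclass(frozen=True)
class RegimeSpec:
    """One behavioural regime: per-feature location/scale + day-to-day persistence."""

    regime_id: str
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    persistence: float = 0.95

    def __post_init__(self) -> None:
        missing = set(ALL_FEATURES) - set(self.feature_means)
        if missing:
            raise ValidationError(f"regime {self.regime_id!r} missing means for {sorted(missing)}")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValidationError(f"persistence must lie in [0, 1], got {self.persistence}")
        for name in UNIT_INTERVAL_FEATURES:
            v = self.feature_means[name]
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} mean must lie in [0, 1], got {v}")
        for name, sd in self.feature_sds.items():
            if sd < 0:
                raise ValidationError(f"sd for {name} must be >= 0, got {sd}")

    def with_consistent_derived(self) -> "RegimeSpec":
        """Return a copy whose derived-feature means satisfy the identities
        used by the generator (efficiency = sleep/onbed, awaken = onbed - sleep,
        end = start + 60*onbed)."""
        m = dict(self.feature_means)
        onbed, sleep = m["onbed_min"], m["sleep_min"]
        m["sleep_min"] = sleep = min(sleep, onbed)
        m["sleep_efficiency"] = sleep / onbed if onbed > 0 else 0.0
        m["awaken_min"] = onbed - sleep
        m["sleep_end_time"] = m["sleep_start_time"] + 60.0 * onbed
        m["active_calories"] = min(m["active_calories"], m["calories_consumed"])
        return dataclasses.replace(self, feature_means=m)


@dataclass(frozen=True)
class CohortSpec:
    """A full cohort: size, duration, regimes, initial assignment, missingness."""

    n_subjects: int
    n_days: int
    regimes: list[RegimeSpec]
    regime_assignment: dict[str, str] | None = None  # subject -> initial regime_id
    missing_day_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_days < 1:
            raise ValidationError("n_subjects and n_days must be positive")
        if not self.regimes:
            raise ValidationError("at least one regime is required")
        if not 0.0 <= self.missing_day_rate < 1.0:
            raise ValidationError("missing_day_rate must lie in [0, 1)")
        ids = [r.regime_id for r in self.regimes]
        if len(set(ids)) != len(ids):
            raise ValidationError("regime ids must be unique")

    @property
    def subject_ids(self) -> list[str]:
        width = max(2, len(str(self.n_subjects)))
        return [f"S{i + 1:0{width}d}" for i in range(self.n_subjects)]


# Six regime archetypes with well-separated daily profiles. Contrasts are
# concentrated on the markers a sleep clinician would look at first:
# time in bed / asleep, efficiency, active calories, steps, stairs.
_ARCHETYPES: list[dict[str, float]] = [
    # long sleeper, low efficiency, moderate activity
    dict(sleep_start_time=9000, onbed_min=540, sleep_min=400, awaken_moments=6,
         calories_consumed=2300, active_calories=500, walks=7000, distance=5.0,
         stairs=8, active_ratio=0.28),
    # short sleeper, high efficiency, high activity
    dict(sleep_start_time=16200, onbed_min=360, sleep_min=330, awaken_moments=2,
         calories_consumed=2800, active_calories=900, walks=13000, distance=9.0,
         stairs=16, active_ratio=0.42),
    # morning type, good sleep, low activity
    dict(sleep_start_time=10800, onbed_min=480, sleep_min=430, awaken_moments=3,
         calories_consumed=2000, active_calories=300, walks=4000, distance=3.0,
         stairs=3, active_ratio=0.20),
    # average sleep, frequent awakenings, high activity
    dict(sleep_start_time=13500, onbed_min=420, sleep_min=370, awaken_moments=8,
         calories_consumed=2600, active_calories=700, walks=10000, distance=7.0,
         stairs=12, active_ratio=0.35),
    # very long time in bed, sedentary
    dict(sleep_start_time=7200, onbed_min=600, sleep_min=460, awaken_moments=4,
         calories_consumed=1800, active_calories=150, walks=2000, distance=1.5,
         stairs=1, active_ratio=0.12),
    # fragmented short sleep, very high activity
    dict(sleep_start_time=18000, onbed_min=300, sleep_min=220, awaken_moments=12,
         calories_consumed=3100, active_calories=1100, walks=16000, distance=11.0,
         stairs=20, active_ratio=0.50),
]

_DEFAULT_SDS: dict[str, float] = dict(
    sleep_start_time=900, sleep_end_time=900, onbed_min=20, sleep_min=20,
    sleep_efficiency=0.02, awaken_min=10, awaken_moments=1.5,
    calories_consumed=150, active_calories=60, walks=800, distance=0.7,
    stairs=1.5, active_ratio=0.03,
)

_REGIME_NAMES = ("long_low_eff", "short_high_eff", "morning_low_act",
                 "awakener_active", "sedentary_long", "fragmented_short")


def default_regimes(n_regimes: int = 3, persistence: float = 0.95) -> list[RegimeSpec]:
    """The first ``n_regimes`` archetypes (2-6 supported), derived means made consistent."""
    if not 1 <= n_regimes <= len(_ARCHETYPES):
        raise ValidationError(f"n_regimes must lie in [1, {len(_ARCHETYPES)}]")
    regimes = []
    for name, proto in zip(_REGIME_NAMES[:n_regimes], _ARCHETYPES[:n_regimes]):
        means = dict(proto)
        # placeholders; with_consistent_derived recomputes them
        means.setdefault("sleep_end_time", 0.0)
        means.setdefault("sleep_efficiency", 0.5)
        means.setdefault("awaken_min", 0.0)
        regimes.append(
            RegimeSpec(name, means, dict(_DEFAULT_SDS), persistence).with_consistent_derived()
        )
    return regimes


def _sample_truncated(mean: float, sd: float, lo: float, hi: float | None,
                      size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    upper = np.inf if hi is None else hi
    a, b = (lo - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _simulate_regime_paths(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-subject first-order Markov regime trajectory, shape (n_subjects, n_days)."""
    ids = [r.regime_id for r in spec.regimes]
    index = {rid: i for i, rid in enumerate(ids)}
    k = len(ids)
    paths = np.empty((spec.n_subjects, spec.n_days), dtype=int)
    for s, sid in enumerate(spec.subject_ids):
        if spec.regime_assignment is not None:
            rid = spec.regime_assignment.get(sid)
            if rid is None or rid not in index:
                raise ValidationError(f"no valid initial regime for subject {sid}")
            state = index[rid]
        else:
            state = s % k
        for d in range(spec.n_days):
            paths[s, d] = state
            stay_p = spec.regimes[state].persistence
            if k > 1 and rng.random() >= stay_p:
                others = [j for j in range(k) if j != state]
                state = others[rng.integers(len(others))]
    return paths


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate daily logs and the ground-truth regime table.

    Returns ``(logs, truth)``. ``logs`` has one row per *worn* subject-day
    with columns subject_id, day_index, date and the 13 raw features;
    missing days are absent rows. ``truth`` covers every subject-day
    (subject_id, day_index, regime_id) regardless of wear.
    """
    rng = np.random.default_rng(spec.seed)
    paths = _simulate_regime_paths(spec, rng)
    sids = spec.subject_ids
    n_rows = spec.n_subjects * spec.n_days

    subj_col = np.repeat(sids, spec.n_days)
    day_col = np.tile(np.arange(spec.n_days), spec.n_subjects)
    flat_regime = paths.reshape(-1)

    values = np.empty((n_rows, len(ALL_FEATURES)))
    for g, regime in enumerate(spec.regimes):
        mask = flat_regime == g
        n = int(mask.sum())
        if n == 0:
            continue
        for j, name in enumerate(ALL_FEATURES):
            lo, hi = FEATURE_BOUNDS[name]
            values[mask, j] = _sample_truncated(
                regime.feature_means[name], regime.feature_sds[name], lo, hi, n, rng
            )

    cols = {name: values[:, j] for j, name in enumerate(ALL_FEATURES)}
    # enforce physical identities between the sampled aggregates
    cols["sleep_min"] = np.minimum(cols["sleep_min"], cols["onbed_min"])
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(cols["onbed_min"] > 0, cols["sleep_min"] / cols["onbed_min"], 0.0)
    cols["sleep_efficiency"] = np.clip(eff, 0.0, 1.0)
    cols["awaken_min"] = cols["onbed_min"] - cols["sleep_min"]
    cols["sleep_end_time"] = cols["sleep_start_time"] + 60.0 * cols["onbed_min"]
    cols["active_calories"] = np.minimum(cols["active_calories"], cols["calories_consumed"])

    logs = pd.DataFrame({"subject_id": subj_col, "day_index": day_col})
    logs["date"] = [str(STUDY_START + timedelta(days=int(d))) for d in day_col]
    for name in ALL_FEATURES:
        logs[name] = cols[name]

    truth = pd.DataFrame({
        "subject_id": subj_col,
        "day_index": day_col,
        "regime_id": [spec.regimes[g].regime_id for g in flat_regime],
    })

    if spec.missing_day_rate > 0:
        keep = rng.random(n_rows) >= spec.missing_day_rate
        logs = logs.loc[keep].reset_index(drop=True)

    return logs, truth


def inject_noncompliance(logs: pd.DataFrame, n_dropout_subjects: int,
                         gap_length: int, seed: int = 0) -> pd.DataFrame:
    """Remove one contiguous ``gap_length``-day run from each of
    ``n_dropout_subjects`` randomly chosen subjects; all others untouched."""
    if gap_length < 1:
        raise ValidationError("gap_length must be >= 1")
    if n_dropout_subjects == 0:
        return logs.copy()
    rng = np.random.default_rng(seed)
    subjects = sorted(logs["subject_id"].unique())
    if n_dropout_subjects > len(subjects):
        raise ValidationError("more dropout subjects than subjects in the table")
    n_days = int(logs["day_index"].max()) + 1
    if gap_length > n_days:
        raise ValidationError(f"gap_length {gap_length} exceeds study span {n_days}")
    chosen = rng.choice(subjects, size=n_dropout_subjects, replace=False)
    out = logs.copy()
    for sid in chosen:
        start = int(rng.integers(0, n_days - gap_length + 1))
        gap = range(start, start + gap_length)
        drop = (out["subject_id"] == sid) & out["day_index"].isin(gap)
        out = out.loc[~drop]
    return out.reset_index(drop=True)


def modal_regime(truth: pd.DataFrame) -> pd.Series:
    """Each subject's most frequent true regime across days (ties: first
    alphabetically). Used as subject-level ground truth in recovery checks."""
    return (
        truth.groupby("subject_id")["regime_id"]
        .agg(lambda s: s.value_counts().sort_index().idxmax())
    )


def write_cohort(logs: pd.DataFrame, truth: pd.DataFrame, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logs.to_csv(out / "daily_logs.csv", index=False)
    truth.to_csv(out / "regime_truth.csv", index=False)
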