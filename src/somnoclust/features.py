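"""Daily wearable-log feature schema.

The smart band exports two daily modalities: a sleep summary and an
activity summary. Thirteen daily aggregates form the raw schema; the
clustering pipeline retains twelve of them (``onbed_min`` is dropped
because it is nearly collinear with the other sleep-duration features)
giving a 6-sleep + 6-activity "multiplex" vector per subject-day.
Sleep-stage minutes (REM / narrow / deep) are considered unreliable on
wrist-worn devices and never enter the daily schema; they appear only in
the default exclusion policy so that configured inputs carrying them are
screened out.
"""

from __future__ import annotations

# Raw schema, in canonical (sleep-then-activity) order.
SLEEP_FEATURES: tuple[str, ...] = (
    "sleep_start_time",   # seconds from 20:00 to getting into bed
    "sleep_end_time",     # seconds from 20:00 to getting out of bed
    "onbed_min",          # minutes spent in bed
    "sleep_min",          # minutes actually asleep
    "sleep_efficiency",   # sleep_min / onbed_min, in [0, 1]
    "awaken_min",         # minutes awake while in bed
    "awaken_moments",     # number of awakenings
)

ACTIVITY_FEATURES: tuple[str, ...] = (
    "calories_consumed",  # kcal burned over the day
    "active_calories",    # kcal burned in active minutes
    "walks",              # step count
    "distance",           # km moved
    "stairs",             # floors climbed
    "active_ratio",       # active time / wear time, in [0, 1]
)

ALL_FEATURES: tuple[str, ...] = SLEEP_FEATURES + ACTIVITY_FEATURES

# Dropped before clustering: onbed_min by collinearity, stage minutes by
# device reliability (absent from the daily schema but screened anyway).
POLICY_EXCLUDED: frozenset[str] = frozenset(
    {"onbed_min", "rem_sleep", "narrow_sleep", "deep_sleep"}
)

RETAINED_FEATURES: tuple[str, ...] = tuple(
    f for f in ALL_FEATURES if f not in POLICY_EXCLUDED
)

# Physical bounds used for truncation in the generator and for sanity
# checks on loaded logs (lower, upper); None = unbounded above.
FEATURE_BOUNDS: dict[str, tuple[float, float | None]] = {
    "sleep_start_time": (0.0, 43200.0),
    "sleep_end_time": (0.0, 86400.0),
    "onbed_min": (0.0, 960.0),
    "sleep_min": (0.0, 960.0),
    "sleep_efficiency": (0.0, 1.0),
    "awaken_min": (0.0, 960.0),
    "awaken_moments": (0.0, 60.0),
    "calories_consumed": (0.0, 8000.0),
    "active_calories": (0.0, 4000.0),
    "walks": (0.0, 50000.0),
    "distance": (0.0, 60.0),
    "stairs": (0.0, 150.0),
    "active_ratio": (0.0, 1.0),
}

UNIT_INTERVAL_FEATURES: frozenset[str] = frozenset(
    {"sleep_efficiency", "active_ratio"}
)

# Features whose value is recomputed from primary ones after sampling so
# that every generated row is internally consistent.
DERIVED_FEATURES: tuple[str, ...] = (
    "sleep_end_time",
    "sleep_efficiency",
    "awaken_min",
)

ID_COLUMNS: tuple[str, ...] = ("subject_id", "day_index", "date")
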