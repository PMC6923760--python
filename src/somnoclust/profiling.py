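"""Per-cluster feature profiles and nonparametric group tests.

Cluster sizes in cohorts of a few dozen subjects are too small to lean
on normality, so group differences are tested with ANOVA on ranks (the
pooled values are replaced by their global mid-ranks and a standard
one-way ANOVA is run on the ranks, df = (k-1, N-k)) and the
Kruskal-Wallis H test with tie correction. Each subject contributes a
single value per feature — their across-day mean, mapped back to raw
units — to avoid pseudo-replicating days within subjects. Significance
stars follow the convention: dagger p<.10, * p<.05, ** p<.01, *** p<.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .assignment import ClusterAssignment
from .preprocessing import FeaturePanel

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.10, "†"))


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return ""


@dataclass
class RankAnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class KruskalResult:
    H: float
    df: int
    p: float


@dataclass
class ClusterProfile:
    """Raw-unit mean/SD per feature for one cluster's members."""

    cluster: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]  # NaN when n < 2


def _split(values: np.ndarray, groups: np.ndarray) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must align")
    out = [values[groups == g] for g in np.unique(groups)]
    if len(out) < 2:
        raise ValidationError("need at least 2 groups")
    if max(len(g) for g in out) < 2:
        raise ValidationError("need at least one group with 2 members")
    return out


def rank_anova(values: np.ndarray, groups: np.ndarray) -> RankAnovaResult:
    """One-way ANOVA on the global mid-ranks of the pooled values."""
    parts = _split(values, groups)
    pooled = np.concatenate(parts)
    if np.all(pooled == pooled[0]):
        raise ValidationError("rank ANOVA undefined: all values identical")
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    ranked_parts = []
    start = 0
    for part in parts:
        ranked_parts.append(ranks[start:start + len(part)])
        start += len(part)
    f, p = stats.f_oneway(*ranked_parts)
    k, n = len(parts), len(pooled)
    return RankAnovaResult(float(f), k - 1, n - k, float(p))


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> KruskalResult:
    """Kruskal-Wallis H with tie correction and chi-square p-value."""
    parts = _split(values, groups)
    pooled = np.concatenate(parts)
    if np.all(pooled == pooled[0]):
        raise ValidationError("Kruskal-Wallis undefined: all values identical")
    h, p = stats.kruskal(*parts)
    return KruskalResult(float(h), len(parts) - 1, float(p))


def subject_feature_table(panel: FeaturePanel) -> pd.DataFrame:
    """One row per subject: across-day mean of each feature in raw units."""
    rows = []
    for sid in panel.subjects:
        mat = panel.values[sid]
        raw = panel.inverse_transform(mat) if panel.normalization_bounds else mat
        rows.append({"subject_id": sid,
                     **dict(zip(panel.feature_names, raw.mean(axis=0)))})
    return pd.DataFrame(rows).set_index("subject_id")


def profile_report(assignments: dict[str, ClusterAssignment], panel: FeaturePanel,
                   holm: bool = True) -> tuple[list[ClusterProfile], pd.DataFrame]:
    """Cluster profiles plus the per-feature test table.

    Returns ``(profiles, tests)``: profiles give each non-empty cluster's
    raw-unit feature means/SDs over member subjects; tests carry rank-ANOVA
    F, Kruskal-Wallis H, dfs, unadjusted p-values, Holm-adjusted p-values,
    and significance stars. With fewer than two populated clusters the
    test table is empty (profiles only).
    """
    subj = subject_feature_table(panel)
    missing = set(assignments) - set(subj.index)
    if missing:
        raise ValidationError(f"panel missing subjects: {sorted(missing)}")
    labels = pd.Series({sid: a.dominant for sid, a in assignments.items()})
    labels = labels.loc[subj.index.intersection(labels.index)]
    subj = subj.loc[labels.index]

    profiles = []
    for letter in sorted(labels.unique()):
        members = subj.loc[labels == letter]
        profiles.append(ClusterProfile(
            cluster=letter, n=len(members),
            means={f: float(members[f].mean()) for f in panel.feature_names},
            sds={f: (float(members[f].std(ddof=1)) if len(members) > 1 else np.nan)
                 for f in panel.feature_names},
        ))

    rows = []
    if labels.nunique() >= 2:
        for feat in panel.feature_names:
            vals = subj[feat].to_numpy()
            grp = labels.to_numpy()
            try:
                ra = rank_anova(vals, grp)
                kw = kruskal_wallis(vals, grp)
            except ValidationError:
                continue
            rows.append({
                "feature": feat, "F": ra.F, "df_between": ra.df_between,
                "df_within": ra.df_within, "p_rank_anova": ra.p,
                "H": kw.H, "df_kw": kw.df, "p_kruskal": kw.p,
                "stars": significance_stars(ra.p),
            })
    tests = pd.DataFrame(rows)
    if holm and not tests.empty:
        from statsmodels.stats.multitest import multipletests

        tests["p_rank_anova_holm"] = multipletests(
            tests["p_rank_anova"], method="holm")[1]
    return profiles, tests


def plot_profiles(profiles: list[ClusterProfile], features: list[str],
                  out_path) -> None:
    """Bar charts of per-cluster feature means (one panel per feature)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(features)
    ncols = min(4, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False)
    letters = [p.cluster for p in profiles]
    for i, feat in enumerate(features):
        ax = axes[i // ncols][i % ncols]
        means = [p.means[feat] for p in profiles]
        errs = [0.0 if np.isnan(p.sds[feat]) else p.sds[feat] for p in profiles]
        ax.bar(letters, means, yerr=errs, capsize=3)
        ax.set_title(feat, fontsize=9)
    for j in range(n, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
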