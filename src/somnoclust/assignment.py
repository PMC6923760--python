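"""Dominant-cluster assignment of subjects via PageRank over their
window-label chains.

After window clustering, each subject is a time-ordered sequence of
cluster letters (one per window, e.g. ``A-A-D-C-C-E-B-...``). Treating
consecutive labels as a first-order Markov chain, the subject's
transition matrix is estimated from the observed pair counts and the
stationary scores of the damped chain d*P + (1-d)/K are computed by
power iteration (PageRank, damping 0.85 by default). The letter with the
highest score is the subject's dominant insomnia-activity cluster — the
state their chain visits most in the long run.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SequencingError, ValidationError

logger = logging.getLogger(__name__)

CLUSTER_LETTERS = string.ascii_uppercase


def cluster_alphabet(n_clusters: int) -> list[str]:
    return list(CLUSTER_LETTERS[:n_clusters])


@dataclass(frozen=True)
class LabelSequence:
    """One subject's time-ordered window cluster letters."""

    subject_id: str
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codes) < 1:
            raise ValidationError(f"empty label sequence for {self.subject_id}")


@dataclass
class TransitionModel:
    """Row-stochastic first-order chain over the cluster alphabet."""

    alphabet: list[str]
    matrix: np.ndarray
    counts: np.ndarray


@dataclass
class ClusterAssignment:
    """Subject -> dominant cluster plus the full PageRank score vector."""

    subject_id: str
    alphabet: list[str]
    pagerank: np.ndarray
    dominant: str

    @property
    def dominant_score(self) -> float:
        return float(self.pagerank[self.alphabet.index(self.dominant)])


def sequence_labels(label_table: pd.DataFrame) -> dict[str, LabelSequence]:
    """Build per-subject label sequences from a (subject_id, t, label) table.

    Rows may arrive in any order; they are sorted by t. Window times must
    be contiguous (consecutive t) within each subject.
    """
    required = {"subject_id", "t", "label"}
    if not required <= set(label_table.columns):
        raise SequencingError(f"label table needs columns {sorted(required)}")
    out: dict[str, LabelSequence] = {}
    for sid, grp in label_table.groupby("subject_id", sort=True):
        grp = grp.sort_values("t")
        ts = grp["t"].to_numpy()
        if len(ts) > 1 and not np.all(np.diff(ts) == 1):
            raise SequencingError(f"subject {sid}: window times not contiguous")
        if grp["t"].duplicated().any():
            raise SequencingError(f"subject {sid}: duplicate window times")
        out[str(sid)] = LabelSequence(str(sid), tuple(str(c) for c in grp["label"]))
    return out


def estimate_transitions(codes: tuple[str, ...] | list[str], alphabet: list[str],
                         smoothing: float = 0.0) -> TransitionModel:
    """Count consecutive label pairs and row-normalize.

    Additive smoothing (epsilon added to every cell of a row) applies only
    to rows with at least one observed transition; letters never left
    (dangling states) get a uniform outgoing row so the damped chain is
    well-defined.
    """
    if not alphabet:
        raise ValidationError("empty alphabet")
    if len(codes) < 2:
        raise ValidationError("need at least 2 codes to estimate transitions")
    idx = {a: i for i, a in enumerate(alphabet)}
    k = len(alphabet)
    counts = np.zeros((k, k))
    for a, b in zip(codes[:-1], codes[1:]):
        if a not in idx or b not in idx:
            raise ValidationError(f"code outside alphabet: {a!r}/{b!r}")
        counts[idx[a], idx[b]] += 1
    matrix = np.empty((k, k))
    row_tot = counts.sum(axis=1)
    for i in range(k):
        if row_tot[i] > 0:
            row = counts[i] + smoothing
            matrix[i] = row / row.sum()
        else:
            matrix[i] = 1.0 / k
    return TransitionModel(list(alphabet), matrix, counts)


def pagerank(model: TransitionModel, damping: float = 0.85,
             tol: float = 1e-10, max_iter: int = 100_000) -> np.ndarray:
    """Stationary scores of d*P + (1-d)*uniform by power iteration."""
    if not 0.0 <= damping <= 1.0:
        raise ValidationError("damping must lie in [0, 1]")
    p = np.asarray(model.matrix, dtype=float)
    k = p.shape[0]
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("transition matrix is not row-stochastic")
    s = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        s_new = damping * (s @ p) + (1.0 - damping) / k
        if np.abs(s_new - s).sum() < tol:
            s = s_new
            break
        s = s_new
    else:
        raise ArithmeticError(f"PageRank did not converge in {max_iter} iterations")
    return s / s.sum()


def dominant_cluster(scores: np.ndarray, alphabet: list[str]) -> str:
    """Argmax letter; ties broken alphabetically with a warning."""
    scores = np.asarray(scores, dtype=float)
    best = float(scores.max())
    winners = [a for a, v in zip(alphabet, scores) if np.isclose(v, best, atol=1e-12)]
    if len(winners) > 1:
        logger.warning("PageRank tie among %s; choosing %s", winners, sorted(winners)[0])
    return sorted(winners)[0]


def assign_subjects(sequences: dict[str, LabelSequence], alphabet: list[str],
                    damping: float = 0.85, smoothing: float = 0.0) -> dict[str, ClusterAssignment]:
    """Per-subject PageRank over that subject's own transition chain."""
    out = {}
    for sid, seq in sequences.items():
        model = estimate_transitions(seq.codes, alphabet, smoothing)
        scores = pagerank(model, damping=damping)
        out[sid] = ClusterAssignment(sid, list(alphabet), scores,
                                     dominant_cluster(scores, alphabet))
    return out


def assignment_table(assignments: dict[str, ClusterAssignment],
                     demographics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort summary per cluster: membership count and %, mean dominant
    PageRank of members, and mean (SD) BMI / ISI when demographics are
    given. Empty clusters appear with count 0 and blank statistics; rows
    are sorted by descending PageRank."""
    if not assignments:
        raise ValidationError("no assignments")
    alphabet = next(iter(assignments.values())).alphabet
    n = len(assignments)
    demo = None
    if demographics is not None:
        if "subject_id" not in demographics.columns:
            raise ValidationError("demographics table needs a subject_id column")
        demo = demographics.set_index(demographics["subject_id"].astype(str))
        missing = set(assignments) - set(demo.index)
        if missing:
            raise ValidationError(f"demographics missing subjects: {sorted(missing)}")
    rows = []
    for letter in alphabet:
        members = [a for a in assignments.values() if a.dominant == letter]
        row: dict = {"cluster": letter, "n": len(members),
                     "pct": round(100.0 * len(members) / n)}
        if members:
            row["pagerank"] = float(np.mean([m.dominant_score for m in members]))
        else:
            row["pagerank"] = np.nan
        for col in ("BMI", "ISI"):
            if demo is not None and col in demo.columns and members:
                vals = demo.loc[[m.subject_id for m in members], col].astype(float)
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            else:
                row[f"{col}_mean"] = np.nan
                row[f"{col}_sd"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        "pagerank", ascending=False, na_position="last"
    ).reset_index(drop=True)
    return table
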