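"""Benchmark experiments on planted-structure cohorts.

These routines run the full pipeline against synthetic cohorts whose
ground truth is known, and are the basis of the package's self-checks:
window-count arithmetic, planted-regime recovery, autoencoder learning
curves, and the calibration of the group tests under the null.

Problem sizes mirror the reference study design (42 subjects x 42 days,
8-day windows, 12 features -> 1470 window images); recovery runs use a
small number of embedding trials and a 150-epoch training budget, which
is ample at this data size.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cae import CAEConfig
from .imaging import WindowConfig
from .pipeline import PipelineConfig, run_pipeline
from .profiling import kruskal_wallis, rank_anova
from .synthetic import CohortSpec, default_regimes, generate_cohort, modal_regime


def make_study_cohort(seed: int, n_subjects: int = 42, n_days: int = 42,
                      n_regimes: int = 3, persistence: float = 0.95):
    """A study-sized cohort with well-separated planted regimes."""
    spec = CohortSpec(n_subjects=n_subjects, n_days=n_days,
                      regimes=default_regimes(n_regimes, persistence), seed=seed)
    return (*generate_cohort(spec), spec)


def recovery_trial(seed: int, out_dir, n_regimes: int = 3,
                   persistence: float = 0.95, epochs: int = 150,
                   n_embedding_trials: int = 3) -> dict:
    """One end-to-end pipeline run on a planted cohort.

    Returns the selected cluster count, silhouette, the adjusted Rand
    index of the dominant-cluster assignment against each subject's modal
    planted regime, and the autoencoder loss trajectory endpoints.
    """
    logs, truth, spec = make_study_cohort(seed, n_regimes=n_regimes,
                                          persistence=persistence)
    cfg = PipelineConfig(
        out_dir=out_dir, seed=seed,
        cae=CAEConfig(epochs=epochs, early_stopping=False),
        window=WindowConfig(),
        n_embedding_trials=n_embedding_trials,
        methods=("kmeans",), make_plots=False,
    )
    res = run_pipeline(cfg, logs=logs)
    truth_modal = modal_regime(truth)
    subjects = sorted(res.assignments)
    ari = adjusted_rand_score(
        [truth_modal[s] for s in subjects],
        [res.assignments[s].dominant for s in subjects],
    )
    return {
        "seed": seed,
        "n_images": res.stack.n_images,
        "n_pixels": res.stack.n_pixels,
        "selected_k": res.clustering.n_clusters,
        "AS": res.clustering.AS,
        "SSE": res.clustering.SSE,
        "ari_vs_planted": float(ari),
        "epoch1_loss": res.trained.loss_history[0],
        "final_loss": res.trained.final_loss,
        "epoch1_recon_mse": res.trained.recon_history[0],
        "final_recon_mse": res.trained.recon_history[-1],
    }


def recovery_experiment(base_seed: int, out_dir, n_runs: int = 10,
                        **trial_kwargs) -> pd.DataFrame:
    """``n_runs`` independently seeded recovery trials."""
    rows = [recovery_trial(base_seed + i, out_dir, **trial_kwargs)
            for i in range(n_runs)]
    return pd.DataFrame(rows)


def type_one_error_calibration(seed: int, n_subjects: int = 42,
                               group_sizes: tuple[int, ...] = (12, 9, 4, 12, 5),
                               n_permutations: int = 1000,
                               alpha: float = 0.05) -> dict:
    """Empirical size of rank-ANOVA / Kruskal-Wallis under permuted labels.

    Subject values are drawn once from a single null distribution; group
    labels of the reference design's sizes are then permuted; the rate of
    p < alpha estimates the type-I error.
    """
    if sum(group_sizes) != n_subjects:
        raise ValueError("group sizes must sum to n_subjects")
    rng = np.random.default_rng(seed)
    values = rng.normal(size=n_subjects)
    base_labels = np.repeat(np.arange(len(group_sizes)), group_sizes)
    hits_ra = hits_kw = 0
    for _ in range(n_permutations):
        labels = rng.permutation(base_labels)
        hits_ra += rank_anova(values, labels).p < alpha
        hits_kw += kruskal_wallis(values, labels).p < alpha
    return {
        "rank_anova_type1": hits_ra / n_permutations,
        "kruskal_type1": hits_kw / n_permutations,
        "n_permutations": n_permutations,
    }
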