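"""End-to-end orchestration: logs -> panel -> images -> codes -> window
clusters -> dominant-cluster assignment -> profiles.

A single integer seed fans out into per-stage seeds (CRC32 of
"stage:seed", kept below 2**31) so each stage is independently
reproducible and reruns with the same config and seed yield identical
artifacts. Every intermediate artifact is persisted to the output
directory and hashed into a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment as ua
from . import clustering as ec
from .cae import CAEConfig, TrainedCAE, encode, train_cae
from .errors import SomnoclustError, ValidationError
from .imaging import ImageStack, WindowConfig, assemble_dataset
from .preprocessing import (
    DailyRecord,
    FeaturePanel,
    ScreeningReport,
    load_daily_logs,
    preprocess,
)
from .profiling import ClusterProfile, plot_profiles, profile_report

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{stage}:{seed}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Everything one run needs; nested stage configs keep their own defaults."""

    out_dir: str | Path = "somnoclust_out"
    logs_path: str | Path | None = None
    demographics_path: str | Path | None = None
    max_consecutive_gap: int = 2
    correlation_threshold: float = 0.9
    window: WindowConfig = field(default_factory=WindowConfig)
    cae: CAEConfig = field(default_factory=CAEConfig)
    perplexity: float = 30.0
    n_embedding_trials: int = 100
    k_min: int = 2
    k_max: int = 10
    methods: tuple[str, ...] = ("kmeans", "hierarchical")
    damping: float = 0.85
    smoothing: float = 0.0
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        window = WindowConfig(**raw.pop("window", {}))
        cae = CAEConfig(**raw.pop("cae", {}))
        return cls(window=window, cae=cae, **raw)


@dataclass
class PipelineResult:
    panel: FeaturePanel
    screening: ScreeningReport
    excluded_subjects: list[str]
    stack: ImageStack
    trained: TrainedCAE
    latents: np.ndarray
    embedding: ec.EmbeddingRun
    clustering: ec.ClusteringResult
    candidates: list[ec.ClusteringResult]
    label_table: pd.DataFrame
    assignments: dict[str, ua.ClusterAssignment]
    assignment_summary: pd.DataFrame
    profiles: list[ClusterProfile]
    tests: pd.DataFrame
    manifest: dict


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _letters_by_size(labels: np.ndarray) -> dict[int, str]:
    """Map raw cluster ids to letters, largest cluster first (noise excluded)."""
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    return {int(cid): ua.CLUSTER_LETTERS[i] for i, cid in enumerate(order)}


def _assign_noise_to_nearest(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Give DBSCAN noise windows the letter of the nearest cluster centroid
    so every subject keeps a full-length label sequence."""
    out = labels.copy()
    noise = out < 0
    if not noise.any():
        return out
    ids = np.unique(out[~noise])
    cents = np.stack([points[out == c].mean(axis=0) for c in ids])
    d = np.linalg.norm(points[noise][:, None, :] - cents[None, :, :], axis=2)
    out[noise] = ids[np.argmin(d, axis=1)]
    return out


def _cluster_all_methods(config: PipelineConfig):
    k_range = range(config.k_min, config.k_max + 1)

    def clusterer(points: np.ndarray) -> ec.ClusteringResult:
        candidates = []
        for method in config.methods:
            try:
                if method == "kmeans":
                    candidates.append(ec.kmeans_sweep(
                        points, k_range, seed=stage_seed(config.seed, "kmeans")))
                elif method == "hierarchical":
                    candidates.append(ec.hierarchical_sweep(points, k_range))
                elif method == "dbscan":
                    candidates.append(ec.dbscan_cluster(points))
                else:
                    raise ValidationError(f"unknown clustering method {method!r}")
            except ec.ClusteringError as exc:
                logger.warning("method %s failed: %s", method, exc)
        winner = ec.select_method(candidates)
        winner.candidates = candidates  # type: ignore[attr-defined]
        return winner

    return clusterer


def run_pipeline(config: PipelineConfig,
                 logs: pd.DataFrame | None = None,
                 demographics: pd.DataFrame | None = None) -> PipelineResult:
    """Execute the five pipeline stages and persist all artifacts.

    ``logs``/``demographics`` may be passed in memory; otherwise they are
    read from the configured paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}

    def _stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"seed": stage_seed(config.seed, name)}
        return manifest["stages"][name]

    # Stage 1: preprocessing -------------------------------------------------
    info = _stage("preprocess")
    try:
        if logs is None:
            if config.logs_path is None:
                raise ValidationError("no logs given (neither logs_path nor in-memory)")
            records = load_daily_logs(config.logs_path)
        else:
            from .preprocessing import records_to_frame  # noqa: F401  (symmetry)

            records = [
                DailyRecord(str(r["subject_id"]), int(r["day_index"]),
                            {c: float(r[c]) for c in logs.columns
                             if c not in ("subject_id", "day_index", "date")})
                for r in logs.to_dict("records")
            ]
        panel, screening, excluded = preprocess(
            records, config.max_consecutive_gap, config.correlation_threshold)
    except SomnoclustError as exc:
        raise type(exc)(f"[stage preprocess] {exc}") from exc
    info["n_subjects"] = len(panel.subjects)
    info["n_excluded"] = len(excluded)
    info["features"] = panel.feature_names
    panel.save_bounds(out / "normalization_bounds.yaml")

    # Stage 2: imaging -------------------------------------------------------
    info = _stage("imaging")
    try:
        stack = assemble_dataset({s: panel.values[s] for s in panel.subjects},
                                 config.window)
    except SomnoclustError as exc:
        raise type(exc)(f"[stage imaging] {exc}") from exc
    info["n_images"] = stack.n_images
    info["n_pixels"] = stack.n_pixels
    stack.save(out / "image_stack.npy", out / "image_index.csv")

    # Stage 3: autoencoder ---------------------------------------------------
    info = _stage("cae")
    cae_cfg = dataclasses.replace(config.cae, seed=stage_seed(config.seed, "cae"))
    try:
        trained = train_cae(stack.images, cae_cfg)
        latents = encode(trained, stack.images)
    except SomnoclustError as exc:
        raise type(exc)(f"[stage cae] {exc}") from exc
    info["final_loss"] = trained.final_loss
    info["epochs_run"] = len(trained.loss_history)
    trained.save(out / "cae_checkpoint.npz")
    pd.DataFrame({"epoch": np.arange(1, len(trained.loss_history) + 1),
                  "regularized_loss": trained.loss_history,
                  "reconstruction_mse": trained.recon_history}
                 ).to_csv(out / "loss_history.csv", index=False)
    np.savetxt(out / "latents.csv", latents, delimiter=",")

    # Stage 4: embedding + clustering ---------------------------------------
    info = _stage("clustering")
    try:
        embedding, winner = ec.best_of_trials(
            latents, clusterer=_cluster_all_methods(config),
            n_trials=config.n_embedding_trials, perplexity=config.perplexity,
            base_seed=stage_seed(config.seed, "tsne"))
    except SomnoclustError as exc:
        raise type(exc)(f"[stage clustering] {exc}") from exc
    candidates = getattr(winner, "candidates", [winner])
    info["method"] = winner.method
    info["n_clusters"] = winner.n_clusters
    info["AS"] = winner.AS
    info["SSE"] = winner.SSE
    info["significant"] = bool(winner.significant)
    ec.comparison_table(candidates).to_csv(out / "method_comparison.csv", index=False)

    full_labels = _assign_noise_to_nearest(embedding.coordinates, winner.labels)
    letters = _letters_by_size(full_labels)
    label_table = stack.index.copy()
    label_table["label"] = [letters[int(c)] for c in full_labels]
    label_table.to_csv(out / "window_labels.csv", index=False)

    # Stage 5: subject assignment + profiling -------------------------------
    info = _stage("assignment")
    try:
        sequences = ua.sequence_labels(label_table)
        alphabet = ua.cluster_alphabet(winner.n_clusters)
        assignments = ua.assign_subjects(sequences, alphabet,
                                         damping=config.damping,
                                         smoothing=config.smoothing)
        if demographics is None and config.demographics_path is not None:
            demographics = pd.read_csv(config.demographics_path)
        summary = ua.assignment_table(assignments, demographics)
    except SomnoclustError as exc:
        raise type(exc)(f"[stage assignment] {exc}") from exc
    info["dominant_counts"] = summary.set_index("cluster")["n"].to_dict()
    summary.to_csv(out / "assignment_summary.csv", index=False)
    pd.DataFrame([{"subject_id": a.subject_id, "dominant": a.dominant,
                   **{f"pr_{l}": s for l, s in zip(a.alphabet, a.pagerank)}}
                  for a in assignments.values()]
                 ).to_csv(out / "assignments.csv", index=False)

    _stage("profiling")
    try:
        profiles, tests = profile_report(assignments, panel)
    except SomnoclustError as exc:
        raise type(exc)(f"[stage profiling] {exc}") from exc
    pd.DataFrame([{"cluster": p.cluster, "n": p.n,
                   **{f"{f}_mean": p.means[f] for f in panel.feature_names},
                   **{f"{f}_sd": p.sds[f] for f in panel.feature_names}}
                  for p in profiles]).to_csv(out / "cluster_profiles.csv", index=False)
    tests.to_csv(out / "feature_tests.csv", index=False)
    if config.make_plots and profiles:
        plot_profiles(profiles, panel.feature_names, out / "cluster_profiles.png")
        _reconstruction_grid(trained, stack, panel.subjects[0],
                             out / "reconstruction_grid.png")

    for p in sorted(out.iterdir()):
        if p.is_file():
            manifest["artifacts"][p.name] = _file_hash(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(panel, screening, excluded, stack, trained, latents,
                          embedding, winner, candidates, label_table, assignments,
                          summary, profiles, tests, manifest)


def _reconstruction_grid(trained: TrainedCAE, stack: ImageStack, subject_id: str,
                         out_path, max_images: int = 12) -> None:
    """Paired input/reconstruction heatmaps for one subject (visual check)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask = (stack.index["subject_id"] == subject_id).to_numpy()
    imgs = stack.images[mask][:max_images]
    recon = trained.reconstruct(imgs)
    n = imgs.shape[0]
    fig, axes = plt.subplots(2, n, figsize=(1.2 * n, 2.8), squeeze=False)
    for i in range(n):
        axes[0][i].imshow(imgs[i], vmin=0, vmax=1, aspect="auto")
        axes[1][i].imshow(recon[i], vmin=0, vmax=1, aspect="auto")
        for ax in (axes[0][i], axes[1][i]):
            ax.set_xticks([])
            ax.set_yticks([])
    axes[0][0].set_ylabel("input", fontsize=8)
    axes[1][0].set_ylabel("recon", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
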