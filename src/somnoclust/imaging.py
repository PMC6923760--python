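"""Discounted sliding-window "images" of daily feature matrices.

Each subject's normalized day x feature matrix is cut into overlapping
windows of ``win_size`` consecutive days (default 8, long enough to
always contain a weekend). Sleep debt is cumulative but dominated by the
most recent nights, so within a window the rows are exponentially
down-weighted by recency: the day closest to the prediction day t (the
day immediately after the window) has closeness rank m = 1 and keeps
weight 1, the oldest has rank m = win_size, and row m is multiplied by
gamma^(m-1). A 42-day series with 8-day windows yields 42 - 8 + 1 = 35
images per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry and recency discount.

    ``discount_exponent_offset`` selects the weighting convention:
    1 (default) weights closeness rank m by gamma^(m-1) so the newest
    day is unscaled; 0 uses gamma^m.
    """

    win_size: int = 8
    stride: int = 1
    discount: float = 0.75
    discount_exponent_offset: int = 1

    def __post_init__(self) -> None:
        if self.win_size < 1 or self.stride < 1:
            raise ValidationError("win_size and stride must be >= 1")
        if not 0.0 < self.discount <= 1.0:
            raise ValidationError(f"discount must lie in (0, 1], got {self.discount}")
        if self.discount_exponent_offset not in (0, 1):
            raise ValidationError("discount_exponent_offset must be 0 or 1")

    def row_weights(self, n_features: int) -> np.ndarray:
        """(win_size, n_features) weight matrix; row 0 is the oldest day."""
        m = np.arange(self.win_size, 0, -1)  # closeness rank per row, oldest first
        w = self.discount ** (m - self.discount_exponent_offset)
        return np.repeat(w[:, None], n_features, axis=1)


@dataclass(frozen=True)
class WindowImage:
    """One discounted win_size x n_features image; ``t`` is the 0-based
    index of the day immediately after the window (reported 1-based)."""

    subject_id: str
    t: int
    matrix: np.ndarray

    @property
    def t_report(self) -> int:
        return self.t + 1


def make_windows(matrix: np.ndarray, config: WindowConfig,
                 subject_id: str = "?") -> tuple[np.ndarray, np.ndarray]:
    """Cut a dense (D, F) matrix into raw (undiscounted) windows.

    Returns ``(windows, starts)`` with windows shaped
    (n_windows, win_size, F); window i covers days
    [starts[i], starts[i] + win_size). For stride 1 there are exactly
    D - win_size + 1 windows.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("subject matrix must be 2-D (days x features)")
    d = matrix.shape[0]
    if d < config.win_size:
        raise InsufficientDataError(
            f"subject {subject_id}: {d} days < window size {config.win_size}"
        )
    if not np.isfinite(matrix).all():
        raise ValidationError(f"subject {subject_id}: matrix contains non-finite values")
    starts = np.arange(0, d - config.win_size + 1, config.stride)
    windows = np.stack([matrix[s:s + config.win_size] for s in starts])
    return windows, starts


def apply_discount(window: np.ndarray, discount: float,
                   discount_exponent_offset: int = 1) -> np.ndarray:
    """Apply the recency discount to one (win_size, F) window."""
    window = np.asarray(window, dtype=float)
    cfg = WindowConfig(win_size=window.shape[0], discount=discount,
                       discount_exponent_offset=discount_exponent_offset)
    return window * cfg.row_weights(window.shape[1])


@dataclass
class ImageStack:
    """All subjects' discounted window images plus their (subject, t) index."""

    images: np.ndarray          # (N, win_size, F)
    index: pd.DataFrame         # columns: subject_id, t (0-based), t_report

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.images.shape))

    def save(self, array_path, index_path) -> None:
        np.save(array_path, self.images)
        self.index.to_csv(index_path, index=False)


def assemble_dataset(panels: dict[str, np.ndarray], config: WindowConfig) -> ImageStack:
    """Window + discount every subject's matrix into one image stack.

    Subjects are processed in the given order; within a subject, windows
    are time-ordered, so row i of the index identifies image i.
    """
    if not panels:
        raise ValidationError("empty cohort")
    chunks, rows = [], []
    for sid, matrix in panels.items():
        windows, starts = make_windows(matrix, config, subject_id=sid)
        weights = config.row_weights(matrix.shape[1])
        chunks.append(windows * weights[None, :, :])
        for s in starts:
            t = int(s) + config.win_size
            rows.append((sid, t, t + 1))
    images = np.concatenate(chunks, axis=0)
    index = pd.DataFrame(rows, columns=["subject_id", "t", "t_report"])
    return ImageStack(images, index)
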