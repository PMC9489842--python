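"""Sliding-window functional connectivity and the FCD matrix.

A rectangular window of fixed width slides one frame per step over the
recording; within each fully contained window the pairwise Pearson matrix is
computed and its strictly-lower-triangle entries are flattened into one row of
the windowed series.  Correlating every pair of those rows yields the
time-versus-time functional-connectivity-dynamics (FCD) matrix, whose
off-diagonal blocks reveal reoccurring connectivity configurations.

Pair-order convention (version "lower-colmajor-v1"): entry order is (i, j)
with i > j, sorted lexicographically by (j, i) — i.e. column-major over the
strictly lower triangle, equivalently ``matrix[np.triu_indices(n, 1)[::-1]]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import FluorescenceMatrix
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

PAIR_ORDER_VERSION = "lower-colmajor-v1"


def pair_index(n_neurons: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices (i, j), i > j, in the documented fixed pair order."""
    j, i = np.triu_indices(n_neurons, 1)
    return i, j


@dataclass
class WindowedFCSeries:
    """Vectorized per-window correlation matrices, one row per window start."""

    vectors: np.ndarray  # (n_windows, n_pairs)
    window_width_frames: int
    step_frames: int
    window_start_frames: np.ndarray
    n_neurons: int

    def __post_init__(self):
        expected = self.n_neurons * (self.n_neurons - 1) // 2
        if self.vectors.shape[1] != expected:
            raise InvalidArgumentError(
                f"expected {expected} pairs for {self.n_neurons} neurons, "
                f"got {self.vectors.shape[1]}"
            )

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.vectors.shape[1]


@dataclass
class FCDMatrix:
    """Window-by-window correlation of the wFC series."""

    c: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InvalidArgumentError("FCD matrix must be square")
        self.c = c

    @property
    def n_windows(self) -> int:
        return self.c.shape[0]


def sliding_window_fc(
    matrix: FluorescenceMatrix,
    window_width_frames: int = 70,
    step_frames: int = 1,
) -> WindowedFCSeries:
    """Per-window pairwise Pearson correlations over fully contained windows.

    With step 1 this yields ``n_frames - window_width_frames + 1`` windows.
    Pairs involving a neuron that is constant within a window get correlation
    0 for that window (counted and logged) so the series stays rectangular.
    """
    n_frames = matrix.n_frames
    if window_width_frames < 3:
        raise InvalidArgumentError("window width must be >= 3 frames")
    if window_width_frames > n_frames:
        raise InvalidArgumentError("window width exceeds the number of frames")
    if step_frames < 1:
        raise InvalidArgumentError("step_frames must be >= 1")
    if matrix.n_neurons < 2:
        raise InvalidArgumentError("need at least 2 neurons")

    n = matrix.n_neurons
    i_idx, j_idx = pair_index(n)
    starts = np.arange(0, n_frames - window_width_frames + 1, step_frames)
    vectors = np.empty((len(starts), len(i_idx)))
    n_imputed = 0
    values = matrix.values
    for row, start in enumerate(starts):
        window = values[:, start : start + window_width_frames]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(window)
        vec = corr[i_idx, j_idx]
        bad = ~np.isfinite(vec)
        if bad.any():
            n_imputed += int(bad.sum())
            vec = np.where(bad, 0.0, vec)
        vectors[row] = vec
    if n_imputed:
        logger.warning(
            "imputed %d zero-variance pair correlation(s) as 0 across %d windows",
            n_imputed,
            len(starts),
        )
    return WindowedFCSeries(
        vectors=vectors,
        window_width_frames=int(window_width_frames),
        step_frames=int(step_frames),
        window_start_frames=starts,
        n_neurons=n,
    )


def fcd(series: WindowedFCSeries) -> FCDMatrix:
    """Pearson correlation between every pair of wFC vectors."""
    if series.n_windows < 2:
        raise InvalidArgumentError("FCD requires at least 2 windows")
    if series.n_pairs < 2:
        raise InvalidArgumentError("FCD requires at least 2 neuron pairs")
    rows = series.vectors
    sd = rows.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(rows)
    if flat.size:
        logger.warning("%d zero-variance wFC row(s); their correlations set to 0", flat.size)
        c[flat, :] = 0.0
        c[:, flat] = 0.0
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return FCDMatrix(c=c)
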