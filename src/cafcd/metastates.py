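"""ICA correlation patterns, window weights, and signed-quartile meta-states.

Each network's windowed FC series is decomposed by FastICA into four
correlation patterns (CPs) in neuron-pair space.  Every window is then
expressed as four regression weights on those patterns, and each weight is
discretized into a signed quartile code in {±1, ±2, ±3, ±4} — positives and
negatives ranked separately.  The 4-tuple of codes is the window's meta-state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .dynamic_fc import WindowedFCSeries
from .errors import (
    DegenerateBasisError,
    DegenerateComponentError,
    ICAConvergenceError,
    InvalidArgumentError,
)

logger = logging.getLogger(__name__)

SIGN_CONVENTION = "nonnegative-weight-skewness"


@dataclass
class CorrelationPatternBasis:
    """Per-network ICA basis of connectivity patterns (rows, pair space)."""

    patterns: np.ndarray  # (n_components, n_pairs)
    converged: bool
    seed: int
    n_iterations: int
    sign_convention: str = SIGN_CONVENTION

    def __post_init__(self):
        norms = np.linalg.norm(self.patterns, axis=1)
        if np.any(norms == 0):
            raise DegenerateBasisError("a correlation pattern has zero norm")

    @property
    def n_components(self) -> int:
        return self.patterns.shape[0]


@dataclass
class WeightSeries:
    """Per-window regression weights on the pattern basis."""

    w: np.ndarray  # (n_windows, n_components)


@dataclass
class MetaStateSequence:
    """Signed-quartile codes per window plus their run-length encoding."""

    codes: np.ndarray  # (n_windows, n_components), entries in {±1..±4}
    runs: list[tuple[tuple[int, ...], int, int]]  # (meta-state, start window, length)

    def __post_init__(self):
        if np.any(self.codes == 0):
            raise InvalidArgumentError("meta-state codes must be nonzero")
        if np.any(np.abs(self.codes) > 4):
            raise InvalidArgumentError("meta-state codes must lie in ±(1..4)")


def extract_correlation_patterns(
    series: WindowedFCSeries,
    n_components: int = 4,
    seed: int = 0,
    max_retries: int = 5,
) -> CorrelationPatternBasis:
    """Fixed-point ICA (with whitening) over the temporal set of wFC vectors.

    Patterns are the mixing-matrix columns, so each wFC vector is (up to the
    removed mean) a weighted sum of the patterns.  Non-convergent attempts are
    retried with fresh sub-seeds; after ``max_retries`` failures the network is
    flagged via :class:`ICAConvergenceError` so callers can exclude it from
    meta-state statistics.  Pattern signs are fixed so each pattern's weight
    time series has nonnegative skewness.
    """
    if series.n_windows <= n_components:
        raise InvalidArgumentError("need more windows than components")
    if series.n_pairs < n_components:
        raise InvalidArgumentError("need at least as many pairs as components")

    sub_seeds = np.random.SeedSequence(seed).generate_state(max_retries)
    last_iter = 0
    for attempt in range(max_retries):
        ica = FastICA(
            n_components=n_components,
            whiten="unit-variance",
            random_state=int(sub_seeds[attempt] % (2**31 - 1)),
            max_iter=1000,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(series.vectors)
        last_iter = int(ica.n_iter_)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if not converged:
            logger.info("ICA attempt %d/%d did not converge", attempt + 1, max_retries)
            continue
        patterns = ica.mixing_.T.copy()  # (n_components, n_pairs)
        # resolve sign indeterminacy: weight series skewness >= 0 per component
        flips = np.where(stats.skew(sources, axis=0) < 0, -1.0, 1.0)
        patterns *= flips[:, None]
        return CorrelationPatternBasis(
            patterns=patterns, converged=True, seed=seed, n_iterations=last_iter
        )
    raise ICAConvergenceError(
        f"FastICA failed to converge in {max_retries} attempts "
        f"(last run used {last_iter} iterations)",
        retries=max_retries,
    )


def compute_weights(
    series: WindowedFCSeries, basis: CorrelationPatternBasis
) -> WeightSeries:
    """Ordinary least-squares weights of each wFC vector on the CP basis.

    No intercept: each window is modeled as a linear combination of the four
    patterns only.
    """
    patterns = basis.patterns
    if np.linalg.matrix_rank(patterns) < patterns.shape[0]:
        raise DegenerateBasisError("pattern basis is rank-deficient")
    solution, *_ = np.linalg.lstsq(patterns.T, series.vectors.T, rcond=None)
    return WeightSeries(w=solution.T)


def _quartile_codes(values: np.ndarray) -> np.ndarray:
    """Codes 1..4 by empirical quartile, boundary ties to the lower quartile."""
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    return 1 + (values > q1).astype(np.int64) + (values > q2) + (values > q3)


def discretize_weights(weights: WeightSeries) -> MetaStateSequence:
    """Signed-quartile discretization of each component's weight series.

    Positive weights are ranked among that component's positive weights
    (ascending value) into quartiles 1..4; negative weights are ranked among
    negatives by ascending magnitude into −1..−4.  Exact zeros get code +1
    (logged).  A component with all-zero weights cannot be discretized.
    """
    w = np.asarray(weights.w, dtype=float)
    if w.size == 0:
        raise InvalidArgumentError("weight series is empty")
    codes = np.zeros(w.shape, dtype=np.int64)
    for comp in range(w.shape[1]):
        col = w[:, comp]
        if np.all(col == 0):
            raise DegenerateComponentError(f"component {comp} has all-zero weights")
        pos = col > 0
        neg = col < 0
        zero = col == 0
        if pos.any():
            codes[pos, comp] = _quartile_codes(col[pos])
        if neg.any():
            codes[neg, comp] = -_quartile_codes(-col[neg])
        if zero.any():
            logger.warning(
                "component %d: %d zero weight(s) assigned code +1", comp, int(zero.sum())
            )
            codes[zero, comp] = 1
    return MetaStateSequence(codes=codes, runs=metastate_sequence(codes))


def metastate_sequence(codes: np.ndarray) -> list[tuple[tuple[int, ...], int, int]]:
    """Run-length encode the per-window meta-state 4-tuples, in temporal order."""
    codes = np.asarray(codes)
    runs: list[tuple[tuple[int, ...], int, int]] = []
    if len(codes) == 0:
        return runs
    start = 0
    current = tuple(int(c) for c in codes[0])
    for t in range(1, len(codes)):
        state = tuple(int(c) for c in codes[t])
        if state != current:
            runs.append((current, start, t - start))
            current, start = state, t
    runs.append((current, start, len(codes) - start))
    return runs
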