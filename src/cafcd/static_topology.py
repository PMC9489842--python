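"""Whole-recording functional-connectivity topology.

Builds the static Pearson-correlation matrix over all frames, thresholds it at
|r| > 0.4 into a functional graph, and fits the resulting connectivity-degree
frequencies with Poisson, Binomial, or power-law models.  The power-law
scaling exponent comes from ordinary least squares on (log10 degree, log10
relative frequency).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .core import FluorescenceMatrix
from .errors import FitFailureError, InsufficientSupportError, InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class StaticFCMatrix:
    """Symmetric pairwise Pearson matrix with unit diagonal.

    ``neuron_indices`` maps rows back to the original neuron indices after
    zero-variance neurons were dropped.
    """

    r: np.ndarray
    neuron_indices: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise InvalidArgumentError("correlation matrix must be square")
        if not np.allclose(r, r.T):
            raise InvalidArgumentError("correlation matrix must be symmetric")
        if np.any(np.abs(r) > 1 + 1e-9):
            raise InvalidArgumentError("correlations must lie in [-1, 1]")
        self.r = r

    @property
    def n_neurons(self) -> int:
        return self.r.shape[0]


@dataclass
class DegreeFitResult:
    """Fit of a degree-frequency model; ``parameters`` are family-specific."""

    family: str  # poisson | binomial | powerlaw
    parameters: dict[str, float]
    residual_error: float

    def __post_init__(self):
        if self.family not in ("poisson", "binomial", "powerlaw"):
            raise InvalidArgumentError(f"unknown family {self.family!r}")
        if self.residual_error < 0:
            raise InvalidArgumentError("residual_error must be nonnegative")


def static_fc(matrix: FluorescenceMatrix) -> StaticFCMatrix:
    """Pearson correlation between every pair of neuron traces, all frames.

    Zero-variance neurons are dropped (their identities logged) because the
    correlation is undefined for them.
    """
    if matrix.n_neurons < 2:
        raise InvalidArgumentError("static FC requires at least 2 neurons")
    variances = matrix.values.var(axis=1)
    keep = np.flatnonzero(variances > 0)
    dropped = np.flatnonzero(variances == 0)
    if dropped.size:
        logger.warning("dropping %d zero-variance neuron(s): %s", dropped.size, dropped.tolist())
    if keep.size < 2:
        raise InvalidArgumentError("fewer than 2 neurons with nonzero variance")
    r = np.corrcoef(matrix.values[keep])
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return StaticFCMatrix(r=r, neuron_indices=keep)


def threshold_graph(fc: StaticFCMatrix, cutoff: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Functional adjacency (edge iff |r| strictly above cutoff) and degrees."""
    if not 0.0 < cutoff < 1.0:
        raise InvalidArgumentError("cutoff must lie strictly in (0, 1)")
    adjacency = (np.abs(fc.r) > cutoff).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    degrees = adjacency.sum(axis=1).astype(np.int64)
    return adjacency, degrees


# ---------------------------------------------------------------------------
# Degree-distribution fitting


def _poisson_pmf(k, lam):
    # continuous-in-k extension so bin centers need not be integers
    return np.exp(k * np.log(lam) - lam - special.gammaln(k + 1.0))


def _binomial_pmf(k, p, n_trials):
    return np.exp(
        special.gammaln(n_trials + 1.0)
        - special.gammaln(k + 1.0)
        - special.gammaln(n_trials - k + 1.0)
        + k * np.log(p)
        + (n_trials - k) * np.log1p(-p)
    )


def _binned_frequencies(degrees: np.ndarray, n_bins: int):
    counts, edges = np.histogram(degrees, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    density = counts / counts.sum() / width  # comparable to a pmf at unit spacing
    return centers, density, counts


def fit_count_distribution(
    degrees: np.ndarray,
    family: str,
    n_bins: int = 11,
    binomial_n: int | None = None,
) -> DegreeFitResult:
    """Nonlinear least-squares fit of a count model to binned degree data.

    Empirical relative frequencies are binned into ``n_bins`` equal-width bins
    and the family's mass function (evaluated at bin centers, continuous in k)
    is fitted by least squares.  For the binomial family the number of trials
    is fixed — ``binomial_n`` or, by default, the number of nodes.
    """
    degrees = np.asarray(degrees, dtype=float)
    centers, density, counts = _binned_frequencies(degrees, n_bins)
    if np.count_nonzero(counts) < 3:
        raise InsufficientSupportError("need at least 3 nonempty degree bins")
    mean = max(degrees.mean(), 1e-6)
    try:
        if family == "poisson":
            popt, _ = optimize.curve_fit(_poisson_pmf, centers, density, p0=[mean], maxfev=10000)
            params = {"lam": float(popt[0])}
            predicted = _poisson_pmf(centers, *popt)
        elif family == "binomial":
            n_trials = int(binomial_n) if binomial_n is not None else len(degrees)
            popt, _ = optimize.curve_fit(
                lambda k, p: _binomial_pmf(k, p, n_trials),
                centers,
                density,
                p0=[min(max(mean / n_trials, 1e-6), 1 - 1e-6)],
                bounds=(1e-9, 1 - 1e-9),
                maxfev=10000,
            )
            params = {"n": float(n_trials), "p": float(popt[0])}
            predicted = _binomial_pmf(centers, popt[0], n_trials)
        elif family == "powerlaw":
            popt, _ = optimize.curve_fit(
                lambda k, c, a: c * np.maximum(k, 1e-9) ** a,
                centers,
                density,
                p0=[density.max(), -1.0],
                maxfev=10000,
            )
            params = {"scale": float(popt[0]), "slope": float(popt[1])}
            predicted = popt[0] * np.maximum(centers, 1e-9) ** popt[1]
        else:
            raise InvalidArgumentError(f"unknown family {family!r}")
    except RuntimeError as exc:  # curve_fit non-convergence
        raise FitFailureError(
            f"{family} fit did not converge", diagnostics={"message": str(exc), "n_bins": n_bins}
        ) from exc
    residual = float(np.sum((density - predicted) ** 2))
    return DegreeFitResult(family=family, parameters=params, residual_error=residual)


def fit_power_law(degrees: np.ndarray) -> DegreeFitResult:
    """Scaling exponent via OLS of log10 relative frequency on log10 degree.

    Zero degrees are excluded (log undefined); only degrees with nonzero
    observed frequency contribute, and the y-axis uses relative frequency so
    the intercept absorbs any rescaling.
    """
    degrees = np.asarray(degrees)
    positive = degrees[degrees > 0]
    values, counts = np.unique(positive, return_counts=True)
    if len(values) < 3:
        raise InsufficientSupportError(
            f"need >= 3 distinct positive degree values, got {len(values)}"
        )
    freq = counts / counts.sum()
    log_k = np.log10(values.astype(float))
    log_f = np.log10(freq)
    fit = stats.linregress(log_k, log_f)
    residual = float(np.sum((log_f - (fit.intercept + fit.slope * log_k)) ** 2))
    return DegreeFitResult(
        family="powerlaw",
        parameters={"slope": float(fit.slope), "intercept": float(fit.intercept)},
        residual_error=residual,
    )
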