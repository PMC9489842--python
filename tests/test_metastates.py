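import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cafcd.dynamic_fc import WindowedFCSeries
from cafcd.errors import (
    DegenerateBasisError,
    DegenerateComponentError,
    ICAConvergenceError,
    InvalidArgumentError,
)
from cafcd.metastates import (
    CorrelationPatternBasis,
    WeightSeries,
    compute_weights,
    discretize_weights,
    extract_correlation_patterns,
    metastate_sequence,
)

N_NEURONS = 12  # 66 pairs
N_PAIRS = N_NEURONS * (N_NEURONS - 1) // 2


def make_series(vectors):
    vectors = np.asarray(vectors, dtype=float)
    return WindowedFCSeries(
        vectors=vectors,
        window_width_frames=10,
        step_frames=1,
        window_start_frames=np.arange(len(vectors)),
        n_neurons=N_NEURONS,
    )


def planted_series(n_windows=600, seed=0):
    """Known mixing of 4 orthogonal patterns with non-Gaussian weights."""
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.normal(size=(N_PAIRS, 4)))
    patterns = basis.T  # orthonormal rows
    weights = rng.laplace(size=(n_windows, 4)) * np.array([1.0, 1.5, 2.0, 0.7])
    return make_series(weights @ patterns), patterns, weights


def orthonormal_basis(seed=1):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(N_PAIRS, 4)))
    return CorrelationPatternBasis(patterns=q.T, converged=True, seed=seed, n_iterations=1)


class TestExtractCorrelationPatterns:
    def test_planted_mixing_recovery(self):
        series, planted, _ = planted_series()
        basis = extract_correlation_patterns(series, seed=0)
        assert basis.converged
        # match recovered to planted patterns by absolute cosine similarity
        norm = lambda m: m / np.linalg.norm(m, axis=1, keepdims=True)
        cosines = np.abs(norm(basis.patterns) @ norm(planted).T)
        best = cosines.max(axis=1)
        assert np.all(best > 0.95)
        assert len(set(cosines.argmax(axis=1))) == 4  # one-to-one match

    def test_determinism(self):
        series, _, _ = planted_series(seed=3)
        b1 = extract_correlation_patterns(series, seed=42)
        b2 = extract_correlation_patterns(series, seed=42)
        np.testing.assert_array_equal(b1.patterns, b2.patterns)

    def test_sign_convention_nonnegative_skewness(self):
        series, _, _ = planted_series(seed=5)
        basis = extract_correlation_patterns(series, seed=0)
        from scipy import stats

        weights = compute_weights(series, basis)
        assert np.all(stats.skew(weights.w, axis=0) >= -1e-8)

    def test_retry_exhaustion_flags_network(self, monkeypatch):
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        import cafcd.metastates as ms

        class AlwaysDiverges:
            n_iter_ = 1000

            def __init__(self, **kwargs):
                pass

            def fit_transform(self, x):
                warnings.warn("no convergence", ConvergenceWarning)
                return np.zeros((len(x), 4))

        monkeypatch.setattr(ms, "FastICA", AlwaysDiverges)
        series, _, _ = planted_series()
        with pytest.raises(ICAConvergenceError) as exc_info:
            extract_correlation_patterns(series, seed=0, max_retries=3)
        assert exc_info.value.retries == 3

    def test_precondition_checks(self):
        series, _, _ = planted_series(n_windows=3)
        with pytest.raises(InvalidArgumentError):
            extract_correlation_patterns(series, n_components=4)


class TestComputeWeights:
    def test_basis_reproduction(self):
        basis = orthonormal_basis()
        series = make_series(basis.patterns[1][None, :])
        w = compute_weights(series, basis).w
        np.testing.assert_allclose(w[0], [0, 1, 0, 0], atol=1e-10)

    def test_linearity(self):
        basis = orthonormal_basis()
        row = 2.0 * basis.patterns[0] - 3.0 * basis.patterns[3]
        w = compute_weights(make_series(row[None, :]), basis).w
        np.testing.assert_allclose(w[0], [2, 0, 0, -3], atol=1e-10)

    def test_normal_equations_oracle(self, rng):
        basis = orthonormal_basis(seed=7)
        # non-orthonormal variant: scale + mix rows so lstsq has real work
        patterns = basis.patterns * np.array([[1.0], [2.0], [0.5], [3.0]])
        patterns[0] += 0.3 * patterns[1]
        mixed = CorrelationPatternBasis(patterns=patterns, converged=True, seed=7, n_iterations=1)
        x = rng.normal(size=(20, N_PAIRS))
        w = compute_weights(make_series(x), mixed).w
        p = patterns
        expected = np.linalg.solve(p @ p.T, p @ x.T).T  # normal equations
        np.testing.assert_allclose(w, expected, atol=1e-8)

    def test_rank_deficient_basis_rejected(self):
        basis = orthonormal_basis()
        patterns = basis.patterns.copy()
        patterns[3] = patterns[0]
        broken = CorrelationPatternBasis(patterns=patterns, converged=True, seed=0, n_iterations=1)
        with pytest.raises(DegenerateBasisError):
            compute_weights(make_series(np.zeros((5, N_PAIRS))), broken)


def quartile_oracle(values):
    """Brute-force percentile binning: manual sort-and-interpolate, ties low."""
    v = np.sort(np.asarray(values, dtype=float))

    def pct(q):
        h = (len(v) - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, len(v) - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, q2, q3 = pct(0.25), pct(0.5), pct(0.75)
    return np.array([1 + (x > q1) + (x > q2) + (x > q3) for x in values])


class TestDiscretizeWeights:
    def test_equal_quartile_occupancy(self):
        w = np.zeros((8, 4))
        w[:, 0] = np.arange(1, 9, dtype=float)
        w[:, 1:] = 1.0  # keep other components non-degenerate
        seq = discretize_weights(WeightSeries(w=w))
        np.testing.assert_array_equal(seq.codes[:, 0], [1, 1, 2, 2, 3, 3, 4, 4])

    def test_sign_mirror_symmetry(self, rng):
        w = rng.normal(size=(50, 4))
        seq_pos = discretize_weights(WeightSeries(w=w))
        seq_neg = discretize_weights(WeightSeries(w=-w))
        np.testing.assert_array_equal(seq_neg.codes, -seq_pos.codes)

    def test_rank_then_bin_oracle(self, rng):
        w = rng.normal(size=(80, 4))
        seq = discretize_weights(WeightSeries(w=w))
        for comp in range(4):
            col = w[:, comp]
            pos, neg = col > 0, col < 0
            expected = np.zeros(len(col), dtype=int)
            expected[pos] = quartile_oracle(col[pos])
            expected[neg] = -quartile_oracle(-col[neg])
            np.testing.assert_array_equal(seq.codes[:, comp], expected)

    def test_positive_rescaling_invariance(self, rng):
        w = rng.normal(size=(60, 4))
        scaled = w * np.array([3.0, 0.1, 7.5, 1.0])
        np.testing.assert_array_equal(
            discretize_weights(WeightSeries(w=w)).codes,
            discretize_weights(WeightSeries(w=scaled)).codes,
        )

    def test_zero_weights_code_plus_one(self):
        w = np.ones((6, 4))
        w[2, 1] = 0.0
        w[:, 0] = [-3, -2, -1, 1, 2, 3]
        seq = discretize_weights(WeightSeries(w=w))
        assert seq.codes[2, 1] == 1

    def test_all_zero_component_signal(self):
        w = np.ones((5, 4))
        w[:, 2] = 0.0
        with pytest.raises(DegenerateComponentError):
            discretize_weights(WeightSeries(w=w))

    def test_code_range_bound(self, rng):
        w = rng.standard_cauchy(size=(200, 4))
        seq = discretize_weights(WeightSeries(w=w))
        assert np.all(np.abs(seq.codes) >= 1)
        assert np.all(np.abs(seq.codes) <= 4)


class TestMetastateSequence:
    def test_constant_codes_single_run(self):
        codes = np.tile([1, 2, -3, 4], (10, 1))
        runs = metastate_sequence(codes)
        assert runs == [((1, 2, -3, 4), 0, 10)]

    def test_rle_example(self):
        a, b = (1, 1, 1, 1), (2, 1, 1, 1)
        codes = np.array([a, a, b, b, a])
        assert metastate_sequence(codes) == [(a, 0, 2), (b, 2, 2), (a, 4, 1)]

    @settings(max_examples=30, deadline=None)
    @given(
        seq=st.lists(st.integers(0, 2), min_size=1, max_size=50),
    )
    def test_run_lengths_concatenate(self, seq):
        tuples = [((s + 1, 1, 1, 1)) for s in seq]
        codes = np.array(tuples)
        runs = metastate_sequence(codes)
        assert sum(r[2] for r in runs) == len(seq)
        # reconstruction round trip
        rebuilt = []
        for state, _start, length in runs:
            rebuilt.extend([state] * length)
        assert rebuilt == [tuple(t) for t in tuples]
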