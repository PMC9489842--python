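"""Synthetic calcium-network generator with planted ground truth.

Produces fluorescence matrices whose pairwise-correlation structure switches
between a small number of planted connectivity states, on top of a structural
graph whose degree frequencies follow a truncated discrete power law.  Every
stage of the analysis pipeline can therefore be tested against known truth
without any external recording.

Randomness is organised as a seed hierarchy: one root seed spawns independent
named streams (graph, states, spikes, noise), so each sub-process can be
reproduced in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .core import DEFAULT_SAMPLING_PERIOD_S, FluorescenceMatrix
from .errors import ConfigurationError, ConstructiveFailureError, InvalidArgumentError

logger = logging.getLogger(__name__)

AssemblyMap = list[list[list[int]]]  # per state -> list of assemblies -> neuron indices


@dataclass
class SimConfig:
    """Parameters of one simulated network recording.

    ``assembly_map`` maps each planted state to a partition of all neurons into
    co-active assemblies; when ``None`` a deterministic rotating-block partition
    is built by :func:`default_assembly_map`.  ``max_half_width_s``, when set,
    rejects kernel shapes whose half-width reaches that bound (used to enforce
    transient kinetics faster than the analysis window).
    """

    n_neurons: int = 30
    n_frames: int = 1877
    sampling_period_s: float = DEFAULT_SAMPLING_PERIOD_S
    n_states: int = 2
    mean_dwell_frames: float = 150.0
    assembly_map: AssemblyMap | None = None
    baseline_rate_hz: float = 0.02
    coactivation_prob: float = 0.10
    kernel_rise_s: float = 0.3
    kernel_decay_s: float = 1.5
    noise_sd: float = 0.05
    bleach_tau_s: float | None = None
    degree_exponent: float = -1.4
    max_half_width_s: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 1 or self.n_frames < 1:
            raise InvalidArgumentError("n_neurons and n_frames must be positive")
        if self.n_states < 1:
            raise InvalidArgumentError("n_states must be >= 1")
        if self.mean_dwell_frames < 1:
            raise InvalidArgumentError("mean_dwell_frames must be >= 1")
        if not (0.0 <= self.coactivation_prob <= 1.0):
            raise InvalidArgumentError("coactivation_prob must lie in [0, 1]")
        if self.baseline_rate_hz < 0 or self.noise_sd < 0:
            raise InvalidArgumentError("rates and noise sd must be nonnegative")
        if self.kernel_rise_s <= 0 or self.kernel_decay_s <= 0:
            raise InvalidArgumentError("kernel time constants must be positive")
        if self.kernel_rise_s >= self.kernel_decay_s:
            raise InvalidArgumentError("kernel_rise_s must be smaller than kernel_decay_s")
        if self.bleach_tau_s is not None and self.bleach_tau_s <= 0:
            raise InvalidArgumentError("bleach_tau_s must be positive when present")
        if self.degree_exponent >= 0:
            raise InvalidArgumentError("degree_exponent must be negative")
        if self.assembly_map is not None:
            _validate_assembly_map(self.assembly_map, self.n_neurons, self.n_states)


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery tests."""

    state_labels: np.ndarray  # int, per frame, values in 1..K
    spike_trains: list[np.ndarray]  # per neuron, sorted event frame indices
    structural_adjacency: np.ndarray  # symmetric binary, zero diagonal
    planted_degree_exponent: float

    def __post_init__(self):
        adj = np.asarray(self.structural_adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise InvalidArgumentError("structural_adjacency must be square")
        if np.any(np.diag(adj) != 0) or not np.array_equal(adj, adj.T):
            raise InvalidArgumentError("adjacency must be symmetric with zero diagonal")


def _validate_assembly_map(amap: AssemblyMap, n_neurons: int, n_states: int) -> None:
    if len(amap) != n_states:
        raise InvalidArgumentError("assembly_map must define one partition per state")
    full = set(range(n_neurons))
    for k, partition in enumerate(amap):
        seen: list[int] = []
        for assembly in partition:
            seen.extend(assembly)
        if sorted(seen) != sorted(full):
            raise InvalidArgumentError(
                f"assembly_map state {k} does not partition all {n_neurons} neurons"
            )


def default_assembly_map(n_neurons: int, n_states: int, n_assemblies: int = 2) -> AssemblyMap:
    """Deterministic partition: contiguous blocks, cyclically rotated per state.

    State ``k`` shifts the block boundaries by ``k * n_neurons / (n_states *
    n_assemblies)`` positions, so different states group different neuron sets
    and produce distinct block-correlation structure.
    """
    amap: AssemblyMap = []
    block = n_neurons / n_assemblies
    for k in range(n_states):
        shift = int(round(k * n_neurons / (n_states * n_assemblies)))
        order = [(i + shift) % n_neurons for i in range(n_neurons)]
        partition = [
            sorted(order[int(round(a * block)) : int(round((a + 1) * block))])
            for a in range(n_assemblies)
        ]
        amap.append(partition)
    return amap


# ---------------------------------------------------------------------------
# State sequence


def generate_state_sequence(
    n_states: int,
    n_frames: int,
    mean_dwell_frames: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """First-order Markov chain over states ``1..K`` with geometric dwell times.

    The per-frame probability of leaving the current state is
    ``1 / mean_dwell_frames``; on leaving, the next state is uniform over the
    remaining ones.  Dwell times are therefore geometric with the stated mean,
    and the stationary distribution is uniform.
    """
    if n_states < 1 or n_frames < 1:
        raise InvalidArgumentError("n_states and n_frames must be positive")
    if mean_dwell_frames < 1:
        raise InvalidArgumentError("mean_dwell_frames must be >= 1")
    labels = np.empty(n_frames, dtype=np.int64)
    if n_states == 1:
        labels[:] = 1
        return labels
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_leave = 1.0 / mean_dwell_frames
    state = int(rng.integers(1, n_states + 1))
    for t in range(n_frames):
        labels[t] = state
        if rng.random() < p_leave:
            others = [s for s in range(1, n_states + 1) if s != state]
            state = int(rng.choice(others))
    return labels


# ---------------------------------------------------------------------------
# Structural graph


def powerlaw_degree_sequence(n_neurons: int, exponent: float) -> np.ndarray:
    """Degree sequence realizing a truncated discrete power law in frequency.

    Target counts are ``C * k**exponent`` for degrees ``k`` in ``[1,
    n_neurons - 1]``; ``C`` is tuned by bisection so the counts sum to
    ``n_neurons``.  Degrees whose expected count falls below one are excluded
    from the support (finite-size truncation), which keeps the empirical
    degree-frequency histogram on the planted power law rather than producing a
    flat singleton tail.
    """
    ks = np.arange(1, n_neurons, dtype=float)

    def counts_for(scale: float) -> np.ndarray:
        raw = scale * ks**exponent
        return np.where(raw >= 1.0, np.round(raw), 0.0).astype(np.int64)

    lo, hi = 1e-12, 2.0
    while counts_for(hi).sum() < n_neurons:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if counts_for(mid).sum() < n_neurons:
            lo = mid
        else:
            hi = mid
    counts = counts_for(hi)
    seq = np.repeat(np.arange(1, n_neurons), counts)
    if len(seq) > n_neurons:  # overshoot: drop surplus low-degree entries
        seq = np.sort(seq)[len(seq) - n_neurons :]
    while len(seq) < n_neurons:  # undershoot: pad with degree-1 nodes
        seq = np.append(seq, 1)
    return np.asarray(seq, dtype=np.int64)


def generate_scale_free_graph(
    n_neurons: int,
    exponent: float,
    seed: int | np.random.Generator = 0,
    max_retries: int = 50,
) -> np.ndarray:
    """Random simple graph whose degree frequencies follow a power law.

    The degree sequence from :func:`powerlaw_degree_sequence` is shuffled over
    nodes and realized by stub matching; self-loops and multi-edges are
    rejected and repaired by degree-preserving edge swaps.  Raises
    :class:`ConstructiveFailureError` naming the retry limit if no valid simple
    graph is found.
    """
    if n_neurons < 3:
        raise InvalidArgumentError("need at least 3 neurons")
    if exponent >= 0:
        raise InvalidArgumentError("exponent must be negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    degrees = powerlaw_degree_sequence(n_neurons, exponent)
    rng.shuffle(degrees)
    if degrees.sum() % 2 == 1:  # stub count must be even
        candidates = np.flatnonzero(degrees < n_neurons - 1)
        degrees[rng.choice(candidates)] += 1

    stubs_template = np.repeat(np.arange(n_neurons), degrees)
    for _ in range(max_retries):
        stubs = stubs_template.copy()
        rng.shuffle(stubs)
        pairs = stubs.reshape(-1, 2)
        edges: set[tuple[int, int]] = set()
        bad: list[tuple[int, int]] = []
        for u, v in pairs:
            u, v = int(u), int(v)
            key = (min(u, v), max(u, v))
            if u == v or key in edges:
                bad.append((u, v))
            else:
                edges.add(key)
        if _repair_edges(edges, bad, rng, swap_budget=200 * max(1, len(bad))):
            adj = np.zeros((n_neurons, n_neurons), dtype=np.int8)
            idx = np.array(sorted(edges))
            adj[idx[:, 0], idx[:, 1]] = 1
            adj[idx[:, 1], idx[:, 0]] = 1
            return adj
    raise ConstructiveFailureError(
        f"could not realize a simple graph on {n_neurons} nodes with exponent {exponent}",
        retries=max_retries,
    )


def _repair_edges(
    edges: set[tuple[int, int]],
    bad: list[tuple[int, int]],
    rng: np.random.Generator,
    swap_budget: int,
) -> bool:
    """Resolve offending stub pairs by swapping endpoints with existing edges.

    A bad pair (u, v) and a random good edge (x, y) are rewired to (u, x) and
    (v, y) when both are new valid simple edges; degrees are preserved.
    """
    budget = swap_budget
    pending = list(bad)
    while pending and budget > 0:
        u, v = pending.pop()
        placed = False
        edge_list = list(edges)
        while budget > 0 and not placed:
            budget -= 1
            x, y = edge_list[int(rng.integers(len(edge_list)))]
            if rng.random() < 0.5:
                x, y = y, x
            e1 = (min(u, x), max(u, x))
            e2 = (min(v, y), max(v, y))
            if u != x and v != y and e1 not in edges and e2 not in edges and e1 != e2:
                edges.discard((min(x, y), max(x, y)))
                edges.add(e1)
                edges.add(e2)
                placed = True
        if not placed:
            return False
    return not pending


# ---------------------------------------------------------------------------
# Fluorescence synthesis


def calcium_kernel(rise_s: float, decay_s: float, sampling_period_s: float) -> np.ndarray:
    """Difference-of-exponentials transient sampled on the frame grid, peak 1."""
    t_extent = decay_s * np.log(1e3)  # until the decay term has fallen to 1e-3
    t = np.arange(0.0, t_extent, sampling_period_s)
    kern = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = kern.max()
    if peak <= 0:
        raise InvalidArgumentError("degenerate kernel: rise must be faster than decay")
    return kern / peak


def kernel_half_width_s(rise_s: float, decay_s: float) -> float:
    """Half-width (duration above half peak) of the continuous kernel.

    Solved by root finding on the analytic expression, independent of any
    sampling grid — used as the oracle for event-detection tests.
    """

    def h(t: float) -> float:
        return np.exp(-t / decay_s) - np.exp(-t / rise_s)

    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)
    half = 0.5 * h(t_peak)
    t_left = optimize.brentq(lambda t: h(t) - half, 1e-12, t_peak)
    t_hi = t_peak
    while h(t_hi) > half:
        t_hi *= 2.0
    t_right = optimize.brentq(lambda t: h(t) - half, t_peak, t_hi)
    return float(t_right - t_left)


def simulate_fluorescence(config: SimConfig) -> tuple[FluorescenceMatrix, GroundTruth]:
    """Simulate one network recording plus its ground truth.

    Events are per-frame Bernoulli at the configured spontaneous rate, plus
    assembly-wide co-activations drawn per frame for the assemblies of the
    currently active planted state.  Each event injects a
    difference-of-exponentials transient; Gaussian noise and an optional
    multiplicative bleach trend are added on top.
    """
    if config.max_half_width_s is not None:
        hw = kernel_half_width_s(config.kernel_rise_s, config.kernel_decay_s)
        if hw >= config.max_half_width_s:
            raise ConfigurationError(
                f"kernel half-width {hw:.2f}s reaches the configured bound "
                f"{config.max_half_width_s:.2f}s"
            )

    ss = np.random.SeedSequence(config.seed)
    rng_graph, rng_states, rng_spikes, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    adjacency = generate_scale_free_graph(config.n_neurons, config.degree_exponent, rng_graph)
    labels = generate_state_sequence(
        config.n_states, config.n_frames, config.mean_dwell_frames, rng_states
    )
    amap = config.assembly_map or default_assembly_map(config.n_neurons, config.n_states)

    T = config.sampling_period_s
    p_base = min(1.0, config.baseline_rate_hz * T)
    spikes = rng_spikes.random((config.n_neurons, config.n_frames)) < p_base
    if config.coactivation_prob > 0:
        for t in range(config.n_frames):
            partition = amap[int(labels[t]) - 1]
            for assembly in partition:
                if rng_spikes.random() < config.coactivation_prob:
                    spikes[assembly, t] = True

    kernel = calcium_kernel(config.kernel_rise_s, config.kernel_decay_s, T)
    traces = signal.fftconvolve(spikes.astype(float), kernel[None, :], axes=1)[
        :, : config.n_frames
    ]
    if config.bleach_tau_s is not None:
        t_s = np.arange(config.n_frames) * T
        traces = traces * np.exp(-t_s / config.bleach_tau_s)[None, :]
    if config.noise_sd > 0:
        traces = traces + rng_noise.normal(0.0, config.noise_sd, traces.shape)

    matrix = FluorescenceMatrix(values=traces, sampling_period_s=T)
    truth = GroundTruth(
        state_labels=labels,
        spike_trains=[np.flatnonzero(spikes[i]) for i in range(config.n_neurons)],
        structural_adjacency=adjacency,
        planted_degree_exponent=config.degree_exponent,
    )
    return matrix, truth
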