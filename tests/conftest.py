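import numpy as np
import pytest

from cafcd.core import FluorescenceMatrix
from cafcd.synthetic_data import SimConfig, simulate_fluorescence


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_matrix(rng):
    """Small unstructured recording: 5 neurons, 100 frames."""
    return FluorescenceMatrix(values=rng.normal(size=(5, 100)), sampling_period_s=0.1506)


@pytest.fixture(scope="session")
def switching_network():
    """One simulated K=2 switching network with distinct assembly partitions."""
    n = 24
    amap = [
        [list(range(0, n // 2)), list(range(n // 2, n))],
        [list(range(0, n, 2)), list(range(1, n, 2))],
    ]
    config = SimConfig(
        n_neurons=n,
        n_frames=1200,
        n_states=2,
        mean_dwell_frames=300,
        assembly_map=amap,
        coactivation_prob=0.5,
        baseline_rate_hz=0.0,
        noise_sd=0.01,
        seed=0,
    )
    matrix, truth = simulate_fluorescence(config)
    return config, matrix, truth


def window_state_labels(frame_labels: np.ndarray, width: int) -> np.ndarray:
    """Majority ground-truth state over each fully contained window."""
    n_windows = len(frame_labels) - width + 1
    out = np.empty(n_windows, dtype=int)
    for t in range(n_windows):
        values, counts = np.unique(frame_labels[t : t + width], return_counts=True)
        out[t] = values[np.argmax(counts)]
    return out
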