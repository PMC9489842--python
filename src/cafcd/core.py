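"""Core data containers shared across pipeline stages.

The central object is :class:`FluorescenceMatrix`: one row per active neuron,
one column per acquisition frame, together with the sampling period and the
metadata labels (network, plate, cell line, diagnosis) that the group-level
statistics need downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .errors import InvalidArgumentError

#: Default sampling period in seconds (6.64 Hz acquisition).
DEFAULT_SAMPLING_PERIOD_S = 0.1506


@dataclass
class FluorescenceMatrix:
    """Fluorescence traces for one recorded network.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_neurons, n_frames)``.
    sampling_period_s
        Time between consecutive frames, in seconds.
    network_id, plate_id, cell_line_id, diagnosis
        Free-form labels carried through the pipeline; ``diagnosis`` is
        conventionally ``"HC"`` or ``"SZ"``.
    """

    values: np.ndarray
    sampling_period_s: float = DEFAULT_SAMPLING_PERIOD_S
    network_id: str = ""
    plate_id: str = ""
    cell_line_id: str = ""
    diagnosis: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError(
                f"values must be 2-D (neurons x frames), got shape {self.values.shape}"
            )
        if self.values.shape[1] < 2:
            raise InvalidArgumentError("a recording needs at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("fluorescence values must be finite")
        if not self.sampling_period_s > 0:
            raise InvalidArgumentError("sampling_period_s must be positive")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.sampling_period_s

    def with_values(self, values: np.ndarray) -> "FluorescenceMatrix":
        """Return a copy holding ``values`` with all metadata preserved."""
        return replace(self, values=values)


def frames_to_seconds(n_frames: float, sampling_period_s: float = DEFAULT_SAMPLING_PERIOD_S) -> float:
    """Convert a frame count to seconds at the given sampling period."""
    return float(n_frames) * float(sampling_period_s)


# ---------------------------------------------------------------------------
# I/O


def write_fluorescence_text(matrix: FluorescenceMatrix, path) -> None:
    """Write traces as tab-delimited text, neurons in rows, frames in columns.

    Metadata goes into ``#key=value`` header lines so a round trip preserves it.
    """
    header = "\n".join(
        f"{k}={getattr(matrix, k)}"
        for k in ("sampling_period_s", "network_id", "plate_id", "cell_line_id", "diagnosis")
    )
    np.savetxt(path, matrix.values, delimiter="\t", header=header)


def read_fluorescence_text(path) -> FluorescenceMatrix:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return FluorescenceMatrix(
        values=values,
        sampling_period_s=float(meta.get("sampling_period_s", DEFAULT_SAMPLING_PERIOD_S)),
        network_id=meta.get("network_id", ""),
        plate_id=meta.get("plate_id", ""),
        cell_line_id=meta.get("cell_line_id", ""),
        diagnosis=meta.get("diagnosis", ""),
    )


def write_fluorescence_h5(matrix: FluorescenceMatrix, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("fluorescence", data=matrix.values)
        ds.attrs["sampling_period_s"] = matrix.sampling_period_s
        for k in ("network_id", "plate_id", "cell_line_id", "diagnosis"):
            ds.attrs[k] = getattr(matrix, k)


def read_fluorescence_h5(path) -> FluorescenceMatrix:
    with h5py.File(path, "r") as fh:
        ds = fh["fluorescence"]
        attrs = {k: ds.attrs.get(k, "") for k in ("network_id", "plate_id", "cell_line_id", "diagnosis")}
        return FluorescenceMatrix(
            values=ds[...],
            sampling_period_s=float(ds.attrs["sampling_period_s"]),
            **{k: str(v) for k, v in attrs.items()},
        )


def read_fluorescence(path) -> FluorescenceMatrix:
    """Dispatch on extension: ``.h5``/``.hdf5`` binary, anything else delimited text."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        return read_fluorescence_h5(path)
    return read_fluorescence_text(path)
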