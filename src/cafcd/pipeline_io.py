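"""End-to-end orchestration: simulate/ingest -> preprocess -> topology -> dFC
-> meta-states -> variables, with reproducible artifacts and a manifest.

Every run writes tidy delimited tables (events, topology, one variable table
per window width) plus ``manifest.json`` holding a config hash, package
version, per-file checksums, and the registry of ICA-non-convergent networks
(excluded from meta-state statistics, never fatal).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import FluorescenceMatrix, read_fluorescence
from .dynamic_fc import PAIR_ORDER_VERSION, fcd, sliding_window_fc
from .errors import ConfigurationError, ICAConvergenceError, InsufficientSupportError
from .fc_variables import compute_fc_variables
from .metastates import compute_weights, discretize_weights, extract_correlation_patterns
from .preprocessing import detect_events_matrix, subtract_baseline
from .static_topology import fit_power_law, static_fc, threshold_graph
from .synthetic_data import SimConfig, simulate_fluorescence

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run over a cohort of networks."""

    out_dir: str
    sim_configs: list[SimConfig] = field(default_factory=list)
    sim_metadata: list[dict] = field(default_factory=list)  # labels per sim network
    input_paths: list[str] = field(default_factory=list)
    window_widths: tuple[int, ...] = (70,)
    fc_cutoff: float = 0.4
    n_components: int = 4
    baseline_quantile: float = 0.08
    threshold_fraction: float = 0.4
    min_separation_frames: int = 3
    n_bins: int = 11
    ica_seed: int = 0
    max_ica_retries: int = 5
    save_intermediates: bool = False

    def __post_init__(self):
        if not self.sim_configs and not self.input_paths:
            raise ConfigurationError("run config names no inputs (simulated or on disk)")
        if any(w < 3 for w in self.window_widths):
            raise ConfigurationError("window widths must be >= 3 frames")
        if self.sim_metadata and len(self.sim_metadata) != len(self.sim_configs):
            raise ConfigurationError("sim_metadata must align with sim_configs")


def load_run_config(path: str | Path, out_dir: str | Path | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML document (see docs/example)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sim_configs, sim_metadata = [], []
    for entry in doc.get("simulate", []):
        labels = {
            k: entry.pop(k, "")
            for k in ("network_id", "plate_id", "cell_line_id", "diagnosis")
        }
        sim_configs.append(SimConfig(**entry))
        sim_metadata.append(labels)
    kwargs = {k: v for k, v in doc.items() if k != "simulate"}
    if "window_widths" in kwargs:
        kwargs["window_widths"] = tuple(kwargs["window_widths"])
    if out_dir is not None:
        kwargs["out_dir"] = str(out_dir)
    return RunConfig(sim_configs=sim_configs, sim_metadata=sim_metadata, **kwargs)


def _load_networks(config: RunConfig) -> list[tuple[FluorescenceMatrix, dict]]:
    networks = []
    for idx, sim in enumerate(config.sim_configs):
        matrix, truth = simulate_fluorescence(sim)
        labels = (
            dict(config.sim_metadata[idx])
            if config.sim_metadata
            else {"network_id": f"sim{idx:03d}"}
        )
        labels.setdefault("network_id", f"sim{idx:03d}")
        matrix = dataclasses.replace(
            matrix,
            network_id=str(labels.get("network_id", "")),
            plate_id=str(labels.get("plate_id", "")),
            cell_line_id=str(labels.get("cell_line_id", "")),
            diagnosis=str(labels.get("diagnosis", "")),
        )
        networks.append((matrix, {"ground_truth": truth, "seed": sim.seed}))
    for path in config.input_paths:
        matrix = read_fluorescence(path)
        if not matrix.network_id:
            matrix = dataclasses.replace(matrix, network_id=Path(path).stem)
        networks.append((matrix, {"seed": None}))
    return networks


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def analyse_network(
    matrix: FluorescenceMatrix, config: RunConfig
) -> tuple[dict, list[dict], dict[int, dict | None]]:
    """Run every analysis stage for one network.

    Returns the topology row, event rows, and a mapping from window width to a
    variable row (``None`` when ICA did not converge at that width).
    """
    transients = subtract_baseline(matrix, config.baseline_quantile)
    events = detect_events_matrix(
        transients,
        threshold_fraction=config.threshold_fraction,
        min_separation_frames=config.min_separation_frames,
    )
    event_rows = [
        {
            "network_id": matrix.network_id,
            "neuron": e.neuron_index,
            "onset_frame": e.onset_frame,
            "peak_frame": e.peak_frame,
            "amplitude": e.amplitude,
            "half_width_s": e.half_width_s,
        }
        for e in events
    ]

    fc = static_fc(transients)
    _, degrees = threshold_graph(fc, config.fc_cutoff)
    try:
        power = fit_power_law(degrees)
        slope = power.parameters["slope"]
    except InsufficientSupportError:
        logger.warning("network %s: too few degree values for a power-law fit", matrix.network_id)
        slope = float("nan")
    topology_row = {
        "network_id": matrix.network_id,
        "n_neurons": matrix.n_neurons,
        "n_events": len(events),
        "mean_degree": float(degrees.mean()),
        "max_degree": int(degrees.max()),
        "scaling_exponent": slope,
    }

    n_conn = matrix.n_neurons * (matrix.n_neurons - 1) // 2
    per_width: dict[int, dict | None] = {}
    for width in config.window_widths:
        series = sliding_window_fc(transients, window_width_frames=width)
        try:
            basis = extract_correlation_patterns(
                series,
                n_components=config.n_components,
                seed=config.ica_seed,
                max_retries=config.max_ica_retries,
            )
        except ICAConvergenceError:
            logger.warning(
                "network %s width %d: ICA did not converge; excluded", matrix.network_id, width
            )
            per_width[width] = None
            continue
        weights = compute_weights(series, basis)
        sequence = discretize_weights(weights)
        variables = compute_fc_variables(sequence, matrix.sampling_period_s)
        row = {
            "network_id": matrix.network_id,
            "plate_id": matrix.plate_id,
            "cell_line_id": matrix.cell_line_id,
            "diagnosis": matrix.diagnosis,
            "n_neurons": matrix.n_neurons,
            "n_possible_connections": n_conn,
            "window_width_frames": width,
            "ica_seed": config.ica_seed,
            "scaling_exponent": slope,
        }
        row.update(dataclasses.asdict(variables))
        per_width[width] = row
    return topology_row, event_rows, per_width


def _save_intermediates(matrix, config, out_dir: Path) -> list[Path]:
    written = []
    transients = subtract_baseline(matrix, config.baseline_quantile)
    for width in config.window_widths:
        series = sliding_window_fc(transients, window_width_frames=width)
        matrix_fcd = fcd(series)
        path = out_dir / f"{matrix.network_id}_w{width}.h5"
        with h5py.File(path, "w") as fh:
            wfc = fh.create_dataset("wfc", data=series.vectors)
            wfc.attrs["window_width_frames"] = width
            wfc.attrs["step_frames"] = series.step_frames
            wfc.attrs["pair_order"] = PAIR_ORDER_VERSION
            fh.create_dataset("fcd", data=matrix_fcd.c)
        written.append(path)
    return written


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and persist all artifacts; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    networks = _load_networks(config)

    topology_rows, event_rows = [], []
    width_rows: dict[int, list[dict]] = {w: [] for w in config.window_widths}
    nonconvergent: list[dict] = []
    for matrix, _extra in networks:
        try:
            topo, events, per_width = analyse_network(matrix, config)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for network {matrix.network_id!r}: {exc}"
            ) from exc
        topology_rows.append(topo)
        event_rows.extend(events)
        for width, row in per_width.items():
            if row is None:
                nonconvergent.append({"network_id": matrix.network_id, "width": width})
            else:
                width_rows[width].append(row)
        if config.save_intermediates:
            _save_intermediates(matrix, config, out_dir)

    files = []
    _write_table(pd.DataFrame(topology_rows), out_dir / "topology.tsv")
    files.append("topology.tsv")
    _write_table(
        pd.DataFrame(
            event_rows,
            columns=["network_id", "neuron", "onset_frame", "peak_frame", "amplitude", "half_width_s"],
        ),
        out_dir / "events.tsv",
    )
    files.append("events.tsv")
    for width, rows in width_rows.items():
        name = f"variables_w{width}.tsv"
        _write_table(pd.DataFrame(rows), out_dir / name)
        files.append(name)

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "pair_order": PAIR_ORDER_VERSION,
        "n_networks": len(networks),
        "window_widths": list(config.window_widths),
        "nonconvergent": nonconvergent,
        "files": {
            name: hashlib.sha256((out_dir / name).read_bytes()).hexdigest() for name in files
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
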