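"""Baseline subtraction and calcium-transient event detection.

Baseline is the per-neuron 8th-percentile fluorescence (linear interpolation
between order statistics), subtracted from every frame.  Events are amplitude
excursions whose peak reaches 40% of the trace maximum; the half-width of each
event is the duration between the rising and falling crossings of half the
event amplitude, linearly interpolated between frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import FluorescenceMatrix
from .errors import EmptyInputError, InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalciumEvent:
    """One detected transient on one neuron's trace."""

    neuron_index: int
    onset_frame: int
    peak_frame: int
    amplitude: float
    half_width_s: float

    def __post_init__(self):
        if self.onset_frame > self.peak_frame:
            raise InvalidArgumentError("onset_frame must not exceed peak_frame")
        if self.half_width_s <= 0:
            raise InvalidArgumentError("half_width_s must be positive")


@dataclass(frozen=True)
class HalfWidthHistogram:
    counts: np.ndarray
    bin_edges_s: np.ndarray
    cumulative_fraction: np.ndarray


def subtract_baseline(
    raw: FluorescenceMatrix, baseline_quantile: float = 0.08
) -> FluorescenceMatrix:
    """Subtract each neuron's ``baseline_quantile`` fluorescence from its trace.

    The quantile uses linear interpolation between order statistics.  Constant
    traces come out all-zero (logged, not an error).  Output shape and metadata
    are preserved exactly; every output value is input minus a per-trace
    constant.
    """
    if not 0.0 < baseline_quantile < 1.0:
        raise InvalidArgumentError("baseline_quantile must lie strictly in (0, 1)")
    baselines = np.quantile(raw.values, baseline_quantile, axis=1, keepdims=True)
    constant = np.flatnonzero(np.ptp(raw.values, axis=1) == 0)
    if constant.size:
        logger.warning(
            "%d constant trace(s) (neurons %s) become all-zero after baseline subtraction",
            constant.size,
            constant.tolist(),
        )
    return raw.with_values(raw.values - baselines)


def _interp_crossing(trace: np.ndarray, i_lo: int, i_hi: int, level: float) -> float:
    """Fractional frame index where the trace crosses ``level`` between two frames."""
    y0, y1 = trace[i_lo], trace[i_hi]
    if y1 == y0:
        return float(i_lo)
    return i_lo + (level - y0) / (y1 - y0) * (i_hi - i_lo)


def detect_events(
    trace: np.ndarray,
    sampling_period_s: float,
    threshold_fraction: float = 0.4,
    min_separation_frames: int = 3,
    neuron_index: int = 0,
) -> list[CalciumEvent]:
    """Detect transient events on a baseline-subtracted single-neuron trace.

    A frame qualifies as an event peak when it is a local maximum whose value
    is at least ``threshold_fraction`` times the trace maximum (ties count as
    detected).  Peaks closer than ``min_separation_frames`` are merged keeping
    the higher one.  The half-width is measured at half the event amplitude
    (peak minus the larger of zero and the pre-onset local minimum), with
    linear interpolation between frames.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise InvalidArgumentError("threshold_fraction must lie strictly in (0, 1)")
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise InvalidArgumentError("detect_events expects a single-neuron 1-D trace")
    peak_max = trace.max(initial=-np.inf)
    if peak_max <= 0:
        return []
    threshold = threshold_fraction * peak_max
    # nextafter keeps an exact tie at the threshold detected (>= semantics)
    peaks, _ = signal.find_peaks(
        trace, height=np.nextafter(threshold, -np.inf), distance=max(1, min_separation_frames)
    )
    events = []
    for peak in peaks:
        peak = int(peak)
        onset = peak
        while onset > 0 and trace[onset - 1] < trace[onset]:
            onset -= 1
        amplitude = trace[peak] - max(0.0, trace[onset])
        if amplitude <= 0:
            continue
        level = trace[peak] - amplitude / 2.0
        left = peak
        while left > 0 and trace[left - 1] >= level:
            left -= 1
        t_left = _interp_crossing(trace, left - 1, left, level) if left > 0 else float(left)
        right = peak
        n = len(trace)
        while right < n - 1 and trace[right + 1] >= level:
            right += 1
        t_right = _interp_crossing(trace, right, right + 1, level) if right < n - 1 else float(right)
        half_width_s = max(t_right - t_left, 1e-12) * sampling_period_s
        events.append(
            CalciumEvent(
                neuron_index=neuron_index,
                onset_frame=onset,
                peak_frame=peak,
                amplitude=float(amplitude),
                half_width_s=float(half_width_s),
            )
        )
    return events


def detect_events_matrix(
    matrix: FluorescenceMatrix,
    threshold_fraction: float = 0.4,
    min_separation_frames: int = 3,
) -> list[CalciumEvent]:
    """Run :func:`detect_events` over every neuron of a network."""
    events: list[CalciumEvent] = []
    for i in range(matrix.n_neurons):
        events.extend(
            detect_events(
                matrix.values[i],
                matrix.sampling_period_s,
                threshold_fraction=threshold_fraction,
                min_separation_frames=min_separation_frames,
                neuron_index=i,
            )
        )
    return events


def half_width_histogram(
    events: list[CalciumEvent], bin_width_s: float
) -> HalfWidthHistogram:
    """Histogram of event half-widths with the running cumulative fraction."""
    if not events:
        raise EmptyInputError("cannot histogram an empty event list")
    if bin_width_s <= 0:
        raise InvalidArgumentError("bin_width_s must be positive")
    widths = np.array([e.half_width_s for e in events])
    # right-inclusive bins (0, b], (b, 2b], ... so a width landing exactly on
    # an edge counts toward the lower bin
    idx = np.maximum(np.ceil(widths / bin_width_s).astype(int) - 1, 0)
    n_bins = int(idx.max()) + 1
    edges = np.arange(n_bins + 1) * bin_width_s
    counts = np.bincount(idx, minlength=n_bins)
    cumulative = np.cumsum(counts) / len(events)
    return HalfWidthHistogram(counts=counts, bin_edges_s=edges, cumulative_fraction=cumulative)
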