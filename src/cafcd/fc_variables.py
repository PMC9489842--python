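"""The nine functional-connectivity-dynamics variables of one network.

All distances are Manhattan (L1) on the integer meta-state code scale; times
are run lengths (in windows) converted to seconds by the sampling period.  A
"visit" is one maximal run of a meta-state, and a hub is a meta-state visited
in at least two separate runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .errors import InvalidArgumentError
from .metastates import MetaStateSequence

Run = tuple[tuple[int, ...], int, int]


@dataclass
class FCVariables:
    n_visited_ms: int
    n_change_points: int
    mean_time_in_ms_s: float
    max_successive_distance: int
    traveled_distance: int
    dynamic_range: int
    n_hub_ms: int
    mean_time_in_hub_s: float
    n_visits_to_hubs: int


def manhattan(ms_a: tuple[int, ...], ms_b: tuple[int, ...]) -> int:
    """L1 distance between two meta-state code tuples."""
    if len(ms_a) != len(ms_b):
        raise InvalidArgumentError("meta-states must have equal dimension")
    return int(sum(abs(a - b) for a, b in zip(ms_a, ms_b)))


def compute_fc_variables(
    runs: list[Run] | MetaStateSequence, sampling_period_s: float
) -> FCVariables:
    """All nine dynamics variables from a meta-state run sequence.

    ``mean_time_in_hub_s`` is 0 when no hub exists; ``max_successive_distance``
    and ``traveled_distance`` are 0 when there is a single run.
    """
    if isinstance(runs, MetaStateSequence):
        runs = runs.runs
    if not runs:
        raise InvalidArgumentError("meta-state run sequence is empty")
    if sampling_period_s <= 0:
        raise InvalidArgumentError("sampling_period_s must be positive")

    states = [r[0] for r in runs]
    lengths = [r[2] for r in runs]

    distinct = set(states)
    successive = [manhattan(states[k], states[k + 1]) for k in range(len(states) - 1)]

    visit_counts: dict[tuple[int, ...], int] = {}
    for s in states:
        visit_counts[s] = visit_counts.get(s, 0) + 1
    hubs = {s for s, c in visit_counts.items() if c >= 2}
    hub_lengths = [L for s, _, L in runs if s in hubs]

    return FCVariables(
        n_visited_ms=len(distinct),
        n_change_points=len(runs) - 1,
        mean_time_in_ms_s=float(sum(lengths) / len(lengths) * sampling_period_s),
        max_successive_distance=max(successive) if successive else 0,
        traveled_distance=int(sum(successive)),
        dynamic_range=(
            max(manhattan(a, b) for a, b in combinations(distinct, 2)) if len(distinct) > 1 else 0
        ),
        n_hub_ms=len(hubs),
        mean_time_in_hub_s=(
            float(sum(hub_lengths) / len(hub_lengths) * sampling_period_s) if hub_lengths else 0.0
        ),
        n_visits_to_hubs=len(hub_lengths),
    )
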