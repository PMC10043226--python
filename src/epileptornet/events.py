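"""Seizure event detection and the derived Results statistics.

Events are detected on the fast variable x1 with hysteresis: an onset is an
upward crossing of ``on_level`` from the interictal state, an offset is
declared once x1 has stayed below ``off_level`` for a sustained dwell.  For
this model the ictal discharge keeps x1 above roughly -0.5 while the
interictal branch sits near -1.6, so the default levels (-0.5 / -1.0)
separate the two phases with a wide margin and the fast ictal ripple never
reaches the off level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, InsufficientEventsError, ParameterError

__all__ = [
    "SeizureEventTable",
    "detect_events",
    "mean_period",
    "onset_delays",
    "recruitment_fraction",
    "mean_pairwise_synchrony",
]


@dataclass(frozen=True)
class SeizureEventTable:
    """Per-node lists of (onset, offset) pairs, in model time units."""

    events: tuple[tuple[tuple[float, float], ...], ...]

    def __post_init__(self) -> None:
        ev = tuple(tuple((float(a), float(b)) for a, b in node)
                   for node in self.events)
        object.__setattr__(self, "events", ev)
        for node in ev:
            last_off = -np.inf
            for on, off in node:
                if off <= on:
                    raise ParameterError("event offset must follow its onset")
                if on <= last_off:
                    raise ParameterError("events must be ordered and disjoint")
                last_off = off

    @property
    def n_nodes(self) -> int:
        return len(self.events)

    def onsets(self, node: int) -> list[float]:
        return [on for on, _ in self.events[node]]

    def nodes_with_events(self) -> list[int]:
        return [i for i, ev in enumerate(self.events) if ev]


def _detect_one(times: np.ndarray, x1: np.ndarray, on_level: float,
                off_level: float, min_ictal: float) -> list[tuple[float, float]]:
    dwell = min_ictal / 5.0
    events: list[tuple[float, float]] = []
    # start in the ictal state with unknown onset if already above on_level
    ictal = x1[0] > on_level
    onset: float | None = None
    below_since: float | None = None
    for k in range(1, len(x1)):
        v = x1[k]
        if not ictal:
            if v > on_level and x1[k - 1] <= on_level:
                ictal = True
                onset = times[k]
                below_since = None
        else:
            if v < off_level:
                if below_since is None:
                    below_since = times[k]
                elif times[k] - below_since >= dwell:
                    if onset is not None and below_since - onset >= min_ictal:
                        events.append((onset, below_since))
                    ictal = False
                    onset = None
                    below_since = None
            else:
                below_since = None
    return events


def detect_events(
    times: np.ndarray,
    x1: np.ndarray,
    on_level: float = -0.5,
    off_level: float = -1.0,
    min_ictal: float = 50.0,
) -> SeizureEventTable:
    """Hysteresis event detection on per-node x1 series.

    ``x1`` has shape (T,) or (T, n).  An event opens at an upward crossing
    of ``on_level`` and closes at the first instant of a dwell of
    ``min_ictal/5`` time units spent entirely below ``off_level``; events
    shorter than ``min_ictal`` are discarded, as is any event still open at
    the end of the series.  Deterministic.
    """
    if on_level <= off_level:
        raise ParameterError("need on_level > off_level (hysteresis)")
    if min_ictal <= 0:
        raise ParameterError("min_ictal must be positive")
    times = np.asarray(times, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if x1.size == 0 or times.size < 2:
        raise InsufficientDataError("empty or single-sample series")
    if x1.shape[0] != times.size:
        raise ParameterError("times and x1 must share their first axis")
    if x1.ndim == 1:
        x1 = x1[:, None]
    per_node = tuple(
        tuple(_detect_one(times, x1[:, i], on_level, off_level, min_ictal))
        for i in range(x1.shape[1]))
    return SeizureEventTable(events=per_node)


def mean_period(
    table: SeizureEventTable, node_subset: Iterable[int] | None = None
) -> float:
    """Mean onset-to-onset seizure interval pooled over a node subset.

    The first onset of every node is discarded as an initial-condition
    transient; consecutive differences of the remaining onsets are pooled.
    Nodes contributing fewer than three onsets add no intervals.
    """
    nodes = range(table.n_nodes) if node_subset is None else node_subset
    intervals: list[float] = []
    for i in nodes:
        onsets = table.onsets(int(i))[1:]
        intervals.extend(np.diff(onsets).tolist())
    if len(intervals) < 2:
        raise InsufficientEventsError(
            f"only {len(intervals)} usable onset intervals (need >= 2)")
    return float(np.mean(intervals))


def onset_delays(
    table: SeizureEventTable, focal_indices: Sequence[int]
) -> dict[int, float | None]:
    """Delay of each non-focal node's first onset behind the earliest focal
    onset.

    Returns {node: delay} over non-focal nodes; nodes that were never
    recruited map to None.
    """
    focal = {int(i) for i in focal_indices}
    focal_firsts = [table.onsets(i)[0] for i in focal if table.onsets(i)]
    if not focal_firsts:
        raise InsufficientEventsError("no focal node has any seizure event")
    ref = min(focal_firsts)
    out: dict[int, float | None] = {}
    for i in range(table.n_nodes):
        if i in focal:
            continue
        onsets = table.onsets(i)
        out[i] = (onsets[0] - ref) if onsets else None
    return out


def recruitment_fraction(
    table: SeizureEventTable, focal_indices: Sequence[int]
) -> float:
    """Fraction of non-focal nodes with at least one seizure event."""
    focal = {int(i) for i in focal_indices}
    nonfocal = [i for i in range(table.n_nodes) if i not in focal]
    if not nonfocal:
        raise ParameterError("no non-focal nodes")
    recruited = sum(1 for i in nonfocal if table.events[i])
    return recruited / len(nonfocal)


def mean_pairwise_synchrony(
    signals: np.ndarray,
    subset: Iterable[int] | None = None,
    transient_fraction: float = 0.0,
) -> float:
    """Mean off-diagonal Pearson correlation over a node subset.

    ``signals`` has shape (T, n).  Zero-variance channels are excluded
    with a warning.
    """
    sig = np.asarray(signals, dtype=float)
    if sig.ndim != 2:
        raise ParameterError("signals must be a (T, n) array")
    start = int(sig.shape[0] * transient_fraction)
    sig = sig[start:]
    cols = list(range(sig.shape[1])) if subset is None else [int(i) for i in subset]
    if len(cols) < 2:
        raise ParameterError("need at least 2 nodes")
    sub = sig[:, cols]
    sd = sub.std(axis=0)
    keep = sd > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} zero-variance channel(s) "
                      "from synchrony", stacklevel=2)
    sub = sub[:, keep]
    if sub.shape[1] < 2:
        raise InsufficientDataError("fewer than 2 channels with variance")
    corr = np.corrcoef(sub, rowvar=False)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    return float(off.mean())
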