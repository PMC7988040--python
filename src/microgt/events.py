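"""Single-cell temporal statistics of calcium-transient trains.

Inter-event intervals (IEIs) characterise burstiness: a Poisson-like neuron
has exponential IEIs, while a bursting neuron shows an excess of short
intervals.  The joint-IEI histogram plots each transient's preceding interval
against its following interval; a boundary (by default the mean interval)
splits the plane into four quadrants that classify transients as within-burst
(both short), burst-initial (long then short), burst-final (short then long)
or sporadic (both long).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolution import EventTrain

__all__ = [
    "IEIDistribution",
    "JointIEIHistogram",
    "compute_iei",
    "iei_histogram",
    "event_rate",
    "joint_iei",
    "amplitude_summary",
    "session_event_summary",
]

QUADRANTS = ("within_burst", "burst_initial", "burst_final", "sporadic")


@dataclass
class IEIDistribution:
    intervals: np.ndarray  # ms, positive
    mean_iei: float
    sem_iei: float
    n: int

    @classmethod
    def from_intervals(cls, intervals: np.ndarray) -> "IEIDistribution":
        intervals = np.asarray(intervals, dtype=float)
        n = int(intervals.size)
        if n == 0:
            return cls(intervals=intervals, mean_iei=np.nan, sem_iei=np.nan, n=0)
        mean = float(intervals.mean())
        sem = float(intervals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return cls(intervals=intervals, mean_iei=mean, sem_iei=sem, n=n)


@dataclass
class JointIEIHistogram:
    pairs: np.ndarray  # (n_pairs, 2): preceding_ms, following_ms
    boundary: float  # ms
    quadrant_counts: dict[str, int]
    quadrant_labels: np.ndarray  # per pair

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])


def compute_iei(events: EventTrain) -> IEIDistribution:
    """Successive time differences of one neuron's events (ms).

    Fewer than two events yield an empty distribution.  Strictly increasing
    times are guaranteed by EventTrain's own validation.
    """
    times = np.asarray(events.times_ms, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("event times must be strictly increasing")
    if times.size < 2:
        return IEIDistribution.from_intervals(np.empty(0))
    return IEIDistribution.from_intervals(np.diff(times))


def iei_histogram(intervals: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Counts per left-closed right-open bin [edge_i, edge_{i+1}).

    Out-of-range intervals are dropped; the returned counts sum to the number
    of in-range intervals.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    x = np.asarray(intervals, dtype=float)
    idx = np.digitize(x, edges, right=False)  # bin i means edges[i-1] <= x < edges[i]
    in_range = (idx >= 1) & (idx <= edges.size - 1)
    return np.bincount(idx[in_range] - 1, minlength=edges.size - 1)


def event_rate(events: EventTrain) -> tuple[int, float]:
    """(events per session, events per minute)."""
    if events.session_duration_ms <= 0:
        raise ValueError("session_duration must be > 0")
    count = events.n_events
    per_minute = count / (events.session_duration_ms / 60000.0)
    return count, per_minute


def joint_iei(
    iei: IEIDistribution,
    boundary_rule: str = "mean",
    fixed_boundary_ms: float | None = None,
) -> JointIEIHistogram:
    """Pairs of consecutive intervals with quadrant classification.

    Pair i is (interval_i, interval_{i+1}).  The boundary is the mean interval
    (rule "mean") or a user value (rule "fixed"); ties at the boundary
    classify to the >= side, so both-short means strictly below the boundary.
    Fewer than two intervals give an empty histogram.
    """
    if boundary_rule not in ("mean", "fixed"):
        raise ValueError("boundary_rule must be 'mean' or 'fixed'")
    iv = np.asarray(iei.intervals, dtype=float)
    if boundary_rule == "fixed":
        if fixed_boundary_ms is None or fixed_boundary_ms <= 0:
            raise ValueError("fixed boundary requires a positive fixed_boundary_ms")
        boundary = float(fixed_boundary_ms)
    else:
        boundary = float(iv.mean()) if iv.size else np.nan
    if iv.size < 2:
        return JointIEIHistogram(
            pairs=np.empty((0, 2)),
            boundary=boundary,
            quadrant_counts={q: 0 for q in QUADRANTS},
            quadrant_labels=np.empty(0, dtype=object),
        )
    pairs = np.column_stack([iv[:-1], iv[1:]])
    pre_short = pairs[:, 0] < boundary
    post_short = pairs[:, 1] < boundary
    labels = np.empty(pairs.shape[0], dtype=object)
    labels[pre_short & post_short] = "within_burst"
    labels[~pre_short & post_short] = "burst_initial"
    labels[pre_short & ~post_short] = "burst_final"
    labels[~pre_short & ~post_short] = "sporadic"
    counts = {q: int(np.sum(labels == q)) for q in QUADRANTS}
    return JointIEIHistogram(
        pairs=pairs, boundary=boundary, quadrant_counts=counts, quadrant_labels=labels
    )


def amplitude_summary(trains: list[EventTrain]) -> pd.DataFrame:
    """Pooled event amplitudes across neurons, provenance preserved.

    One row per event: (neuron_id, time_ms, amplitude).  Aggregate with
    standard pandas ops; group comparisons need the per-neuron provenance.
    """
    rows = [
        pd.DataFrame(
            {"neuron_id": t.neuron_id, "time_ms": t.times_ms, "amplitude": t.amplitudes}
        )
        for t in trains
        if t.n_events
    ]
    if not rows:
        return pd.DataFrame(columns=["neuron_id", "time_ms", "amplitude"])
    return pd.concat(rows, ignore_index=True)


def session_event_summary(trains: list[EventTrain]) -> pd.DataFrame:
    """Per-neuron event counts, rates, mean amplitudes and mean IEIs."""
    rows = []
    for t in trains:
        count, per_min = event_rate(t)
        iei = compute_iei(t)
        rows.append(
            {
                "neuron_id": t.neuron_id,
                "n_events": count,
                "events_per_minute": per_min,
                "mean_amplitude": float(t.amplitudes.mean()) if count else np.nan,
                "mean_iei_ms": iei.mean_iei,
                "n_intervals": iei.n,
            }
        )
    return pd.DataFrame(rows)
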