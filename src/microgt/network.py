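"""Session-level functional connectivity graphs.

Nodes are neuronal somata, links are pairwise Pearson correlations of their
activity.  The correlated signal defaults to binned deconvolved activity
(500 ms bins): deconvolution removes the slow kernel autocorrelation that
would otherwise inflate correlations between raw fluorescence traces.
Negative correlations are zeroed by default (absolute-value mode available),
and a display view keeps only links above a configurable fraction of the
session's maximum link strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .deconvolution import EventTrain

__all__ = [
    "ActivityMatrix",
    "CorrelationMatrix",
    "FunctionalGraph",
    "activity_matrix",
    "activity_matrix_from_events",
    "pearson_matrix",
    "build_graph",
]


@dataclass
class ActivityMatrix:
    values: np.ndarray  # neurons x bins
    bin_width_ms: float
    source: str  # deconvolved | dff | binned_events
    neuron_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("activity matrix needs >= 2 time bins")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity matrix contains non-finite entries")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])


@dataclass
class CorrelationMatrix:
    values: np.ndarray  # neurons x neurons, Pearson
    neuron_ids: np.ndarray
    excluded: np.ndarray  # zero-variance neuron ids dropped before correlating
    method: str = "pearson"

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class FunctionalGraph:
    """Weighted undirected graph plus a thresholded binary display view."""

    graph: nx.Graph
    display_threshold: float  # absolute weight threshold of the display view
    display_edges: set[tuple] = field(default_factory=set)
    negative_policy: str = "zero"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def display_view(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(self.display_edges)
        return g


def _bin_columns(x: np.ndarray, frames_per_bin: int) -> np.ndarray:
    n_bins = x.shape[1] // frames_per_bin
    return x[:, : n_bins * frames_per_bin].reshape(x.shape[0], n_bins, frames_per_bin).sum(axis=2)


def activity_matrix(
    signals: np.ndarray,
    frame_rate: float,
    bin_width_ms: float = 500.0,
    source: str = "deconvolved",
    neuron_ids: np.ndarray | None = None,
) -> ActivityMatrix:
    """Bin per-frame signals (deconvolved activity, dF/F, or spike counts).

    Sums frames within each ``bin_width_ms`` bin; a trailing partial bin is
    dropped.  Raises if fewer than two full bins fit in the session.
    """
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be > 0")
    if source not in ("deconvolved", "dff", "binned_events"):
        raise ValueError(f"unknown source {source!r}")
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    frames_per_bin = max(int(round(bin_width_ms / 1000.0 * frame_rate)), 1)
    binned = _bin_columns(x, frames_per_bin)
    if binned.shape[1] < 2:
        raise ValueError("session shorter than two bins at this bin width")
    return ActivityMatrix(
        values=binned, bin_width_ms=bin_width_ms, source=source, neuron_ids=neuron_ids
    )


def activity_matrix_from_events(
    trains: list[EventTrain],
    bin_width_ms: float = 500.0,
    amplitude_weighted: bool = False,
) -> ActivityMatrix:
    """Bin discrete event trains into a neurons x bins count (or amplitude) matrix."""
    if not trains:
        raise ValueError("no event trains supplied")
    duration = max(t.session_duration_ms for t in trains)
    n_bins = int(duration // bin_width_ms)
    if n_bins < 2:
        raise ValueError("session shorter than two bins at this bin width")
    values = np.zeros((len(trains), n_bins))
    for i, t in enumerate(trains):
        idx = np.minimum((t.times_ms // bin_width_ms).astype(int), n_bins - 1)
        weights = t.amplitudes if amplitude_weighted else np.ones(t.n_events)
        np.add.at(values[i], idx, weights)
    return ActivityMatrix(
        values=values,
        bin_width_ms=bin_width_ms,
        source="binned_events",
        neuron_ids=np.array([t.neuron_id for t in trains]),
    )


def pearson_matrix(activity: ActivityMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlations; silent (zero-variance) neurons excluded.

    Excluded neurons are reported on the result and a warning is emitted,
    since their correlation is undefined.
    """
    x = activity.values
    sd = x.std(axis=1)
    valid = sd > 0
    if valid.sum() < 2:
        raise ValueError("fewer than 2 neurons with nonzero variance")
    excluded = np.asarray(activity.neuron_ids)[~valid]
    if excluded.size:
        warnings.warn(
            f"excluding {excluded.size} zero-variance neuron(s) from the correlation matrix",
            stacklevel=2,
        )
    r = np.corrcoef(x[valid])
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        values=r, neuron_ids=np.asarray(activity.neuron_ids)[valid], excluded=excluded
    )


def build_graph(
    corr: CorrelationMatrix,
    negative_policy: str = "zero",
    display_threshold_fraction: float = 0.5,
) -> FunctionalGraph:
    """Weighted graph from a correlation matrix.

    ``negative_policy="zero"`` drops anticorrelated pairs, ``"absolute"``
    keeps their magnitude.  The binary display view retains edges whose weight
    exceeds ``display_threshold_fraction`` times the maximum off-diagonal
    weight; topology metrics operate on the full weighted graph.
    """
    if negative_policy not in ("zero", "absolute"):
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    if not 0.0 <= display_threshold_fraction <= 1.0:
        raise ValueError("display_threshold_fraction must be in [0, 1]")
    w = corr.values.copy()
    np.fill_diagonal(w, 0.0)
    if negative_policy == "absolute":
        w = np.abs(w)
    else:
        w[w < 0] = 0.0
    ids = corr.neuron_ids
    g = nx.Graph()
    g.add_nodes_from(ids.tolist())
    iu, ju = np.triu_indices_from(w, k=1)
    pos = w[iu, ju] > 0
    g.add_weighted_edges_from(
        (ids[i], ids[j], float(w[i, j])) for i, j in zip(iu[pos], ju[pos])
    )
    w_max = float(w[iu, ju].max()) if iu.size else 0.0
    thr = display_threshold_fraction * w_max
    display = {
        (ids[i], ids[j])
        for i, j in zip(iu[pos], ju[pos])
        if w[i, j] > thr
    } if w_max > 0 else set()
    return FunctionalGraph(
        graph=g,
        display_threshold=thr,
        display_edges=display,
        negative_policy=negative_policy,
    )
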