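"""Diagnostic plots for fitted cohort analyses.

Deliberately minimal: IEI histograms per group, per-session topology-index
boxplots, and a thresholded network view.  All functions return the axes so
callers can restyle; nothing is written to disk here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_iei_histograms", "plot_metric_by_group", "plot_network"]


def plot_iei_histograms(results, bin_edges_ms=None, ax=None, density=True):
    """Overlaid group IEI histograms from a CohortAnalysisResults."""
    import matplotlib.pyplot as plt

    from .events import iei_histogram

    if ax is None:
        _, ax = plt.subplots()
    if bin_edges_ms is None:
        upper = max(np.percentile(v, 99) for v in results.iei_by_group.values())
        bin_edges_ms = np.linspace(0.0, upper, 40)
    centers = 0.5 * (np.asarray(bin_edges_ms)[:-1] + np.asarray(bin_edges_ms)[1:])
    for group, intervals in results.iei_by_group.items():
        counts = iei_histogram(intervals, bin_edges_ms).astype(float)
        if density and counts.sum():
            counts /= counts.sum()
        ax.step(centers, counts, where="mid", label=group)
    ax.set_xlabel("inter-event interval (ms)")
    ax.set_ylabel("proportion" if density else "count")
    ax.legend()
    return ax


def plot_metric_by_group(results, metric="mean_degree", ax=None):
    """Per-session values of one topology index, grouped by condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = results.session_metrics[results.session_metrics["metric"] == metric]
    groups = list(dict.fromkeys(sub["group"]))
    data = [sub.loc[sub["group"] == g, "value"].to_numpy() for g in groups]
    ax.boxplot(data, tick_labels=groups)
    for i, vals in enumerate(data, start=1):
        ax.plot(np.full(vals.size, i), vals, "k.", alpha=0.6)
    ax.set_ylabel(metric)
    return ax


def plot_network(fgraph, ax=None, seed=0):
    """Display view of a functional graph (edges above the display threshold)."""
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots()
    g = fgraph.display_view()
    pos = nx.spring_layout(g, seed=seed)
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=30, with_labels=False)
    ax.set_axis_off()
    return ax
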