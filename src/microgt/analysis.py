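"""End-to-end cohort analysis as a model/results pair.

``CohortAnalysis`` is constructed from data (a simulated cohort or sessions
loaded from disk) plus analysis options; ``fit()`` runs deconvolution, event
extraction, single-cell statistics, network construction and topology metrics
for every session, then the group-comparison layer, and returns a
``CohortAnalysisResults`` carrying the per-neuron and per-session tables, the
test results and a printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from . import network as net
from .deconvolution import EventTrain, deconvolve_session
from .metrics import GraphMetricsReport, degree_stats, metrics_report
from .simulate import CohortConfig, CohortDataset, SessionData, generate_cohort
from .stats import GroupSample, compare_cohorts, kruskal_wallis, ks_two_sample

__all__ = ["CohortAnalysis", "CohortAnalysisResults", "analyze_session"]

METRIC_NAMES = (
    "mean_degree",
    "characteristic_path_length",
    "global_efficiency",
    "modularity_q",
    "mean_betweenness",
    "assortativity",
)


def analyze_session(
    session: SessionData,
    gamma: float | None = None,
    penalty: float | str = "auto",
    threshold_sd_multiple: float = 3.0,
    min_separation_ms: float = 100.0,
    bin_width_ms: float = 500.0,
    network_source: str = "binned_events",
    negative_policy: str = "zero",
    display_threshold_fraction: float = 0.5,
    weighted: bool = True,
    metrics_level: str = "full",
    seed: int = 0,
) -> dict:
    """Run the full single-session pipeline; returns events, graph and metrics.

    ``network_source`` selects the correlated signal: "binned_events"
    (default) bins the detected transient events, "deconvolved" bins the raw
    non-negative activity including its sub-threshold residue, "dff" bins the
    baseline-subtracted fluorescence itself.  ``metrics_level="degree"``
    skips the path-based indexes and community detection, reporting only the
    degree distribution (useful for large screening runs).
    """
    results, trains, _ = deconvolve_session(
        session.traces,
        session.frame_rate,
        gamma=gamma,
        penalty=penalty,
        threshold_sd_multiple=threshold_sd_multiple,
        min_separation_ms=min_separation_ms,
    )
    activity = np.stack([r.activity for r in results])
    if network_source == "binned_events":
        am = net.activity_matrix_from_events(trains, bin_width_ms=bin_width_ms)
    elif network_source in ("deconvolved", "dff"):
        signal = activity if network_source == "deconvolved" else session.traces
        am = net.activity_matrix(
            signal, session.frame_rate, bin_width_ms=bin_width_ms, source=network_source
        )
    else:
        raise ValueError(f"unknown network_source {network_source!r}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = net.pearson_matrix(am)
    graph = net.build_graph(
        corr,
        negative_policy=negative_policy,
        display_threshold_fraction=display_threshold_fraction,
    )
    if metrics_level == "full":
        report = metrics_report(graph, seed=seed, weighted=weighted)
    elif metrics_level == "degree":
        deg, mean_deg = degree_stats(graph, weighted=weighted)
        report = GraphMetricsReport(
            mean_degree=mean_deg,
            degree_distribution=deg,
            characteristic_path_length=float("nan"),
            path_length_defined=False,
            n_disconnected_pairs=0,
            global_efficiency=float("nan"),
            modularity_q=float("nan"),
            communities={},
            mean_betweenness=float("nan"),
            betweenness_per_node=np.full(deg.shape, np.nan),
            assortativity=float("nan"),
            assortativity_defined=False,
            weighted_mode=weighted,
            node_ids=list(graph.graph.nodes),
        )
    else:
        raise ValueError(f"unknown metrics_level {metrics_level!r}")
    return {
        "events": trains,
        "activity": activity,
        "correlation": corr,
        "graph": graph,
        "report": report,
    }


@dataclass
class CohortAnalysisResults:
    """Fitted cohort analysis: tables, per-session reports and group tests."""

    neuron_summary: pd.DataFrame  # session_id, group, per-neuron event stats
    session_metrics: pd.DataFrame  # tidy: session_id, group, metric, value
    reports: dict[str, GraphMetricsReport]
    events: dict[str, list[EventTrain]]
    iei_by_group: dict[str, np.ndarray]  # pooled IEIs (ms)
    amplitudes_by_group: dict[str, np.ndarray]
    metric_tests: pd.DataFrame
    iei_kw: object
    rate_kw: object
    amplitude_kw: object
    iei_ks_pairs: dict[tuple[str, str], object] = field(default_factory=dict)

    def plot_iei_histograms(self, **kwargs):
        from .plotting import plot_iei_histograms

        return plot_iei_histograms(self, **kwargs)

    def plot_metric(self, metric: str = "mean_degree", **kwargs):
        from .plotting import plot_metric_by_group

        return plot_metric_by_group(self, metric=metric, **kwargs)

    def group_mean(self, metric: str) -> pd.Series:
        sub = self.session_metrics[self.session_metrics["metric"] == metric]
        return sub.groupby("group", sort=False)["value"].mean()

    def summary(self) -> str:
        lines = ["Cohort analysis summary", "=" * 23, ""]
        counts = self.neuron_summary.groupby("group", sort=False).agg(
            sessions=("session_id", "nunique"), neurons=("neuron_id", "size")
        )
        for grp, row in counts.iterrows():
            lines.append(f"{grp}: {row.sessions} sessions, {row.neurons} neurons")
        lines.append("")
        lines.append("Single-cell statistics (rank-based tests, mean ranks reported)")
        lines.append(f"  IEI: {self.iei_kw}")
        lines.append(f"  event rate: {self.rate_kw}")
        lines.append(f"  amplitude: {self.amplitude_kw}")
        for (a, b), res in self.iei_ks_pairs.items():
            lines.append(f"  IEI {a} vs {b}: {res}")
        lines.append("")
        lines.append("Graph topology (per-session values)")
        for metric in METRIC_NAMES:
            means = self.group_mean(metric)
            vals = ", ".join(f"{g} = {v:.4g}" for g, v in means.items())
            lines.append(f"  {metric}: {vals}")
        if len(self.metric_tests):
            lines.append("")
            lines.append("Group tests on topology metrics")
            for _, row in self.metric_tests.iterrows():
                lines.append(
                    f"  {row['metric']}: {row['method']}, statistic = "
                    f"{row['statistic']:.4f}, p = {row['p_repr']}"
                )
        return "\n".join(lines)


class CohortAnalysis:
    """Microcircuit analysis of a cohort of imaging sessions.

    Parameters mirror the pipeline stages: AR(1) deconvolution (``gamma``
    estimated per trace when None, noise-constrained penalty when "auto"),
    event extraction threshold/merging, correlation binning, edge policy and
    the weighted/binary metric mode.
    """

    def __init__(
        self,
        dataset: CohortDataset | list[SessionData],
        gamma: float | None = None,
        penalty: float | str = "auto",
        threshold_sd_multiple: float = 3.0,
        min_separation_ms: float = 100.0,
        bin_width_ms: float = 500.0,
        network_source: str = "binned_events",
        negative_policy: str = "zero",
        display_threshold_fraction: float = 0.5,
        weighted: bool = True,
        metrics_level: str = "full",
    ) -> None:
        self.sessions = dataset.sessions if isinstance(dataset, CohortDataset) else list(dataset)
        if not self.sessions:
            raise ValueError("no sessions supplied")
        self.gamma = gamma
        self.penalty = penalty
        self.threshold_sd_multiple = threshold_sd_multiple
        self.min_separation_ms = min_separation_ms
        self.bin_width_ms = bin_width_ms
        self.network_source = network_source
        self.negative_policy = negative_policy
        self.display_threshold_fraction = display_threshold_fraction
        self.weighted = weighted
        self.metrics_level = metrics_level

    @classmethod
    def from_simulation(cls, config: CohortConfig, **kwargs) -> "CohortAnalysis":
        return cls(generate_cohort(config), **kwargs)

    def fit(self, seed: int = 0) -> CohortAnalysisResults:
        neuron_rows = []
        metric_rows = []
        reports: dict[str, GraphMetricsReport] = {}
        all_events: dict[str, list[EventTrain]] = {}
        iei_by_group: dict[str, list[np.ndarray]] = {}
        amp_by_group: dict[str, list[np.ndarray]] = {}
        for session in self.sessions:
            out = analyze_session(
                session,
                gamma=self.gamma,
                penalty=self.penalty,
                threshold_sd_multiple=self.threshold_sd_multiple,
                min_separation_ms=self.min_separation_ms,
                bin_width_ms=self.bin_width_ms,
                network_source=self.network_source,
                negative_policy=self.negative_policy,
                display_threshold_fraction=self.display_threshold_fraction,
                weighted=self.weighted,
                metrics_level=self.metrics_level,
                seed=seed,
            )
            all_events[session.session_id] = out["events"]
            reports[session.session_id] = out["report"]
            summ = ev.session_event_summary(out["events"])
            summ.insert(0, "session_id", session.session_id)
            summ.insert(1, "group", session.group)
            neuron_rows.append(summ)
            for train in out["events"]:
                iei = ev.compute_iei(train)
                if iei.n:
                    iei_by_group.setdefault(session.group, []).append(iei.intervals)
                if train.n_events:
                    amp_by_group.setdefault(session.group, []).append(train.amplitudes)
            rep = out["report"]
            for metric in METRIC_NAMES:
                value = getattr(rep, metric)
                metric_rows.append(
                    {
                        "session_id": session.session_id,
                        "group": session.group,
                        "metric": metric,
                        "value": value,
                    }
                )
        neuron_summary = pd.concat(neuron_rows, ignore_index=True)
        session_metrics = pd.DataFrame(metric_rows).dropna(subset=["value"])
        iei_pooled = {g: np.concatenate(v) for g, v in iei_by_group.items()}
        amp_pooled = {g: np.concatenate(v) for g, v in amp_by_group.items()}

        groups = list(dict.fromkeys(s.group for s in self.sessions))
        iei_kw = rate_kw = amp_kw = None
        if len(groups) >= 2:
            if all(g in iei_pooled for g in groups):
                iei_kw = kruskal_wallis(
                    [GroupSample(g, iei_pooled[g], unit="ms") for g in groups]
                )
            rate_samples = [
                GroupSample(
                    g,
                    neuron_summary.loc[neuron_summary["group"] == g, "n_events"].to_numpy(),
                    unit="events",
                )
                for g in groups
            ]
            rate_kw = kruskal_wallis(rate_samples)
            if all(g in amp_pooled for g in groups):
                amp_kw = kruskal_wallis(
                    [GroupSample(g, amp_pooled[g]) for g in groups]
                )
        ks_pairs = {}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                if a in iei_pooled and b in iei_pooled:
                    ks_pairs[(a, b)] = ks_two_sample(
                        GroupSample(a, iei_pooled[a]), GroupSample(b, iei_pooled[b])
                    )
        metric_tests = (
            compare_cohorts(session_metrics) if len(groups) >= 2 else pd.DataFrame()
        )
        return CohortAnalysisResults(
            neuron_summary=neuron_summary,
            session_metrics=session_metrics,
            reports=reports,
            events=all_events,
            iei_by_group=iei_pooled,
            amplitudes_by_group=amp_pooled,
            metric_tests=metric_tests,
            iei_kw=iei_kw,
            rate_kw=rate_kw,
            amplitude_kw=amp_kw,
            iei_ks_pairs=ks_pairs,
        )
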