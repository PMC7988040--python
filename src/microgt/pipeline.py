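"""Staged, reproducible pipeline runs with on-disk intermediates.

A run directory holds one subdirectory per stage (traces, events, network,
metrics, stats); every stage can be re-run from the previous stage's files,
and a checksummed manifest records every output.  Identical config and seed
give identical numerical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import events as ev
from . import io
from . import network as net
from .analysis import METRIC_NAMES
from .deconvolution import deconvolve_session
from .metrics import metrics_report
from .simulate import CohortConfig, generate_cohort, paper_like_config
from .stats import compare_cohorts

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "deconvolve", "events", "network", "metrics", "stats")

log = logging.getLogger("microgt")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a directory of trace files) or
    ``simulation`` (a CohortConfig, or None for the paper-like default when
    the simulate stage is enabled) provides the data.
    """

    out_dir: str = "microgt_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    input_path: str | None = None
    input_format: str = "hdf5"  # hdf5 | csv
    simulation: CohortConfig | None = None
    gamma: float | None = None
    penalty: float | str = "auto"
    threshold_sd_multiple: float = 3.0
    min_separation_ms: float = 100.0
    bin_width_ms: float = 500.0
    network_source: str = "binned_events"  # binned_events | deconvolved | dff
    negative_policy: str = "zero"
    display_threshold_fraction: float = 0.5
    weighted: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.input_path is not None and "simulate" in self.stages:
            raise ValueError("provide either input_path or the simulate stage, not both")
        if self.input_path is None and "simulate" not in self.stages:
            # later stages may still run from an existing out_dir
            pass

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


def _session_ids(out: Path) -> list[str]:
    meta = io.read_json(out / "sessions.json")
    return [s["session_id"] for s in meta["sessions"]]


def _session_meta(out: Path) -> dict[str, dict]:
    meta = io.read_json(out / "sessions.json")
    return {s["session_id"]: s for s in meta["sessions"]}


def _require(path: Path, stage: str, needed_by: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path}, produced by stage '{stage}'; "
            f"enable '{stage}' or point --out at a directory containing it"
        )


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    sim = cfg.simulation or paper_like_config(seed=cfg.seed)
    if sim.seed != cfg.seed:
        sim = dataclasses.replace(sim, seed=cfg.seed)
    ds = generate_cohort(sim)
    tdir = out / "traces"
    gdir = out / "ground_truth"
    tdir.mkdir(parents=True, exist_ok=True)
    gdir.mkdir(parents=True, exist_ok=True)
    sessions = []
    for s in ds.sessions:
        io.write_traces_h5(tdir / f"{s.session_id}.h5", s.traces, s.frame_rate, s.group)
        io.write_ground_truth(
            gdir / f"{s.session_id}.csv", gdir / f"{s.session_id}.json", s
        )
        sessions.append(
            {
                "session_id": s.session_id,
                "group": s.group,
                "frame_rate_hz": s.frame_rate,
                "n_neurons": int(s.n_neurons),
                "n_frames": int(s.traces.shape[1]),
            }
        )
    io.write_json(out / "sessions.json", {"sessions": sessions})
    log.info("simulated %d sessions", len(sessions))


def _ingest_input(cfg: RunConfig, out: Path) -> None:
    """Register external trace files so later stages see uniform metadata."""
    src = Path(cfg.input_path)
    files = sorted(
        src.glob("*.h5") if cfg.input_format == "hdf5" else src.glob("*.csv*")
    )
    if not files:
        raise FileNotFoundError(f"no {cfg.input_format} trace files under {src}")
    tdir = out / "traces"
    tdir.mkdir(parents=True, exist_ok=True)
    sessions = []
    for f in files:
        if cfg.input_format == "hdf5":
            traces, fr, group = io.read_traces_h5(f)
        else:
            traces, fr = io.read_traces_csv(f)
            group = f.stem.split("_")[0]
        sid = f.stem.replace(".csv", "")
        io.write_traces_h5(tdir / f"{sid}.h5", traces, fr, group)
        sessions.append(
            {
                "session_id": sid,
                "group": group or sid,
                "frame_rate_hz": fr,
                "n_neurons": int(traces.shape[0]),
                "n_frames": int(traces.shape[1]),
            }
        )
    io.write_json(out / "sessions.json", {"sessions": sessions})
    log.info("ingested %d sessions from %s", len(sessions), src)


def _stage_deconvolve(cfg: RunConfig, out: Path) -> None:
    _require(out / "sessions.json", "simulate", "deconvolve")
    ddir = out / "deconvolved"
    ddir.mkdir(parents=True, exist_ok=True)
    edir = out / "events"
    edir.mkdir(parents=True, exist_ok=True)
    for sid, meta in _session_meta(out).items():
        path = out / "traces" / f"{sid}.h5"
        _require(path, "simulate", "deconvolve")
        traces, fr, _ = io.read_traces_h5(path)
        results, trains, gamma_used = deconvolve_session(
            traces,
            fr,
            gamma=cfg.gamma,
            penalty=cfg.penalty,
            threshold_sd_multiple=cfg.threshold_sd_multiple,
            min_separation_ms=cfg.min_separation_ms,
        )
        activity = np.stack([r.activity for r in results])
        per_neuron = [
            {
                "neuron_id": i,
                "gamma": r.params.gamma,
                "noise_sd": r.params.noise_sd,
                "penalty": r.sparsity_penalty,
            }
            for i, r in enumerate(results)
        ]
        io.write_traces_h5(ddir / f"{sid}.h5", activity, fr)
        io.write_events_csv(edir / f"{sid}.csv", trains)
        io.write_json(
            edir / f"{sid}.json",
            {
                "session_id": sid,
                "gamma_session": gamma_used,
                "threshold_sd_multiple": cfg.threshold_sd_multiple,
                "min_separation_ms": cfg.min_separation_ms,
                "per_neuron": per_neuron,
            },
        )
        log.info("deconvolved %s (%d neurons)", sid, traces.shape[0])


def _stage_events(cfg: RunConfig, out: Path) -> None:
    """Single-cell statistics from the event tables."""
    _require(out / "sessions.json", "simulate", "events")
    sdir = out / "event_stats"
    sdir.mkdir(parents=True, exist_ok=True)
    rows = []
    joint_rows = []
    for sid, meta in _session_meta(out).items():
        epath = out / "events" / f"{sid}.csv"
        _require(epath, "deconvolve", "events")
        duration_ms = meta["n_frames"] / meta["frame_rate_hz"] * 1000.0
        trains = io.read_events_csv(epath, duration_ms)
        summ = ev.session_event_summary(trains)
        summ.insert(0, "session_id", sid)
        summ.insert(1, "group", meta["group"])
        rows.append(summ)
        for train in trains:
            iei = ev.compute_iei(train)
            joint = ev.joint_iei(iei)
            for (pre, post), lab in zip(joint.pairs, joint.quadrant_labels):
                joint_rows.append(
                    {
                        "session_id": sid,
                        "group": meta["group"],
                        "neuron_id": train.neuron_id,
                        "preceding_ms": pre,
                        "following_ms": post,
                        "quadrant": lab,
                    }
                )
    pd.concat(rows, ignore_index=True).to_csv(
        sdir / "neuron_summary.csv", index=False, float_format=io.FLOAT_FMT
    )
    pd.DataFrame(
        joint_rows,
        columns=["session_id", "group", "neuron_id", "preceding_ms", "following_ms", "quadrant"],
    ).to_csv(sdir / "joint_iei_pairs.csv", index=False, float_format=io.FLOAT_FMT)
    log.info("event statistics written")


def _stage_network(cfg: RunConfig, out: Path) -> None:
    _require(out / "sessions.json", "simulate", "network")
    ndir = out / "network"
    ndir.mkdir(parents=True, exist_ok=True)
    import warnings

    for sid, meta in _session_meta(out).items():
        if cfg.network_source == "binned_events":
            epath = out / "events" / f"{sid}.csv"
            _require(epath, "deconvolve", "network")
            duration_ms = meta["n_frames"] / meta["frame_rate_hz"] * 1000.0
            trains = io.read_events_csv(epath, duration_ms)
            by_id = {t.neuron_id: t for t in trains}
            from .deconvolution import EventTrain

            trains = [
                by_id.get(
                    i,
                    EventTrain(
                        times_ms=np.empty(0),
                        amplitudes=np.empty(0),
                        session_duration_ms=duration_ms,
                        neuron_id=i,
                    ),
                )
                for i in range(meta["n_neurons"])
            ]
            am = net.activity_matrix_from_events(trains, bin_width_ms=cfg.bin_width_ms)
        else:
            dpath = out / "deconvolved" / f"{sid}.h5"
            _require(dpath, "deconvolve", "network")
            activity, fr, _ = io.read_traces_h5(dpath)
            am = net.activity_matrix(
                activity, fr, bin_width_ms=cfg.bin_width_ms, source=cfg.network_source
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = net.pearson_matrix(am)
        graph = net.build_graph(
            corr,
            negative_policy=cfg.negative_policy,
            display_threshold_fraction=cfg.display_threshold_fraction,
        )
        io.write_correlation_csv(ndir / f"{sid}_corr.csv", corr)
        io.write_graph(ndir / f"{sid}_edges.csv", ndir / f"{sid}.graphml", graph)
        log.info("network built for %s", sid)


def _stage_metrics(cfg: RunConfig, out: Path) -> None:
    _require(out / "sessions.json", "simulate", "metrics")
    mdir = out / "metrics"
    mdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, meta in _session_meta(out).items():
        gpath = out / "network" / f"{sid}.graphml"
        _require(gpath, "network", "metrics")
        graph = io.read_graph(gpath)
        report = metrics_report(graph, seed=cfg.seed, weighted=cfg.weighted)
        io.write_json(mdir / f"{sid}.json", report.to_dict())
        for metric in METRIC_NAMES:
            rows.append(
                {
                    "session_id": sid,
                    "group": meta["group"],
                    "metric": metric,
                    "value": getattr(report, metric),
                }
            )
    pd.DataFrame(rows).to_csv(
        mdir / "cohort_metrics.csv", index=False, float_format=io.FLOAT_FMT
    )
    log.info("metrics written for %d sessions", len(_session_ids(out)))


def _stage_stats(cfg: RunConfig, out: Path) -> None:
    mpath = out / "metrics" / "cohort_metrics.csv"
    _require(mpath, "metrics", "stats")
    sdir = out / "stats"
    sdir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(mpath).dropna(subset=["value"])
    tests = compare_cohorts(table)
    tests.to_csv(sdir / "group_tests.csv", index=False, float_format=io.FLOAT_FMT)
    lines = ["Group comparisons on topology metrics", ""]
    for _, row in tests.iterrows():
        lines.append(
            f"{row['metric']}: {row['method']}, statistic = {row['statistic']:.4f}, "
            f"p = {row['p_repr']} ({row['groups']})"
        )
        ranks = {
            c.split("[")[1][:-1]: row[c]
            for c in tests.columns
            if c.startswith("mean_rank[") and pd.notna(row.get(c))
        }
        if ranks:
            lines.append(
                "  mean ranks: " + ", ".join(f"{k} = {v:.2f}" for k, v in ranks.items())
            )
    (sdir / "report.txt").write_text("\n".join(lines) + "\n")
    log.info("group statistics written")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "deconvolve": _stage_deconvolve,
    "events": _stage_events,
    "network": _stage_network,
    "metrics": _stage_metrics,
    "stats": _stage_stats,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the manifest path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(cfg.log_level.upper())
    try:
        io.write_yaml(out / "config.yaml", cfg.to_dict())
        if cfg.input_path is not None:
            _ingest_input(cfg, out)
        for stage in STAGES:
            if stage in cfg.stages:
                log.info("=== stage: %s ===", stage)
                _STAGE_FUNCS[stage](cfg, out)
        return io.write_manifest(out, cfg.to_dict(), __version__)
    finally:
        log.removeHandler(handler)
        handler.close()
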