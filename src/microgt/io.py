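"""Readers and writers for every pipeline stage.

Formats: HDF5 traces (dataset ``traces`` of shape neurons x frames with a
``frame_rate_hz`` attribute), CSV traces (one row per neuron, optionally
gzipped), ground-truth spike CSVs (neuron_id, frame, count) with a JSON
sidecar (module assignments, group label), event CSVs (neuron_id, time_ms,
amplitude), correlation CSVs, weighted edge lists plus GraphML, per-session
metric JSON, tidy cohort CSVs, YAML configs, and a checksummed run manifest.
All numeric payloads round-trip losslessly (CSV written at full precision).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .deconvolution import EventTrain
from .simulate import SessionData

__all__ = [
    "write_traces_h5",
    "read_traces_h5",
    "write_traces_csv",
    "read_traces_csv",
    "write_ground_truth",
    "read_ground_truth",
    "write_events_csv",
    "read_events_csv",
    "write_correlation_csv",
    "write_graph",
    "read_graph",
    "write_json",
    "read_json",
    "write_yaml",
    "read_yaml",
    "write_manifest",
]

FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def write_traces_h5(path, traces: np.ndarray, frame_rate: float, group: str = "") -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("traces", data=np.asarray(traces, dtype=float))
        d.attrs["frame_rate_hz"] = float(frame_rate)
        if group:
            d.attrs["group"] = group


def read_traces_h5(path) -> tuple[np.ndarray, float, str]:
    with h5py.File(path, "r") as f:
        d = f["traces"]
        return d[...], float(d.attrs["frame_rate_hz"]), str(d.attrs.get("group", ""))


def write_traces_csv(path, traces: np.ndarray, frame_rate: float) -> None:
    """One row per neuron; frame rate stored in the header comment line."""
    path = Path(path)
    arr = np.asarray(traces, dtype=float)
    header = f"frame_rate_hz={frame_rate!r}"
    np.savetxt(path, arr, delimiter=",", fmt=FLOAT_FMT, header=header)


def read_traces_csv(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as f:
        first = f.readline().strip()
    if not first.startswith("#") or "frame_rate_hz=" not in first:
        raise ValueError("trace CSV missing 'frame_rate_hz' header line")
    frame_rate = float(first.split("frame_rate_hz=")[1])
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return arr, frame_rate


def write_ground_truth(path_csv, path_json, session: SessionData) -> None:
    neuron, frame = np.nonzero(session.spikes)
    pd.DataFrame(
        {"neuron_id": neuron, "frame": frame, "count": session.spikes[neuron, frame]}
    ).to_csv(path_csv, index=False)
    write_json(
        path_json,
        {
            "group": session.group,
            "session_id": session.session_id,
            "frame_rate_hz": session.frame_rate,
            "n_neurons": int(session.n_neurons),
            "n_frames": int(session.traces.shape[1]),
            "module_assignment": session.module_assignment.tolist(),
        },
    )


def read_ground_truth(path_csv, path_json) -> tuple[np.ndarray, dict]:
    meta = read_json(path_json)
    spikes = np.zeros((meta["n_neurons"], meta["n_frames"]), dtype=np.int64)
    df = pd.read_csv(path_csv)
    spikes[df["neuron_id"], df["frame"]] = df["count"]
    return spikes, meta


def write_events_csv(path, trains: list[EventTrain]) -> None:
    rows = []
    for t in trains:
        for time, amp in zip(t.times_ms, t.amplitudes):
            rows.append({"neuron_id": t.neuron_id, "time_ms": time, "amplitude": amp})
    df = pd.DataFrame(rows, columns=["neuron_id", "time_ms", "amplitude"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_events_csv(path, session_duration_ms: float) -> list[EventTrain]:
    df = pd.read_csv(path)
    expected = {"neuron_id", "time_ms", "amplitude"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing column(s): {sorted(missing)}")
    trains = []
    for nid, sub in df.groupby("neuron_id", sort=True):
        sub = sub.sort_values("time_ms")
        trains.append(
            EventTrain(
                times_ms=sub["time_ms"].to_numpy(),
                amplitudes=sub["amplitude"].to_numpy(),
                session_duration_ms=session_duration_ms,
                neuron_id=nid,
            )
        )
    return trains


def write_correlation_csv(path, corr) -> None:
    pd.DataFrame(corr.values, index=corr.neuron_ids, columns=corr.neuron_ids).to_csv(
        path, float_format=FLOAT_FMT
    )


def write_graph(path_edges, path_graphml, fgraph) -> None:
    g = fgraph.graph if hasattr(fgraph, "display_edges") else fgraph
    rows = [
        {"node_i": u, "node_j": v, "weight": d.get("weight", 1.0)}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
        path_edges, index=False, float_format=FLOAT_FMT
    )
    if path_graphml is not None:
        nx.write_graphml(g, path_graphml)


def read_graph(path_graphml) -> nx.Graph:
    g = nx.read_graphml(path_graphml)
    return nx.relabel_nodes(g, {n: int(n) if str(n).lstrip("-").isdigit() else n for n in g.nodes})


def write_json(path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, default=_json_default)
        f.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def read_json(path) -> dict:
    with open(path) as f:
        return json.load(f)


def write_yaml(path, obj) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, version: str) -> Path:
    """Checksummed listing of every file under the run directory."""
    out_dir = Path(out_dir)
    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": version,
        "config": config,
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    path = out_dir / "manifest.json"
    write_json(path, manifest)
    return path
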