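"""Plain-text readers and writers for every pipeline artifact.

Spike data travel as two TSV tables (spikes: time_s, unit_id; units:
unit_id, region_label) plus a key=value metadata file.  Count and correlation
matrices are TSV with a JSON sidecar; graphs are edge lists; partitions and
ensemble results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ConfigError, CorrelationMatrix, FunctionalGraph, SpikeCountMatrix, SpikeData
from .partitions import Partition


def write_key_value(path, mapping: dict) -> None:
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_key_value(path) -> dict:
    """Parse a key = value text file; values become int/float/bool if possible."""
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"cannot parse config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = _coerce(value)
    return out


def _coerce(value: str):
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def write_spike_data(spikes: SpikeData, directory, extra_meta: dict | None = None):
    """Write spikes.tsv, units.tsv and meta.txt into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    times = np.concatenate([ts for ts in spikes.spike_times if ts.size] or [[]])
    units = np.concatenate(
        [
            np.repeat(uid, len(ts))
            for uid, ts in zip(spikes.unit_ids, spikes.spike_times)
        ]
        or [[]]
    )
    order = np.argsort(times, kind="stable")
    pd.DataFrame({"time_s": times[order], "unit_id": units[order]}).to_csv(
        directory / "spikes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"unit_id": spikes.unit_ids, "region_label": spikes.region_labels}
    ).to_csv(directory / "units.tsv", sep="\t", index=False)
    meta = {"t_start": spikes.window[0], "t_end": spikes.window[1]}
    meta.update(extra_meta or {})
    write_key_value(directory / "meta.txt", meta)


def read_spike_data(directory) -> SpikeData:
    """Read the spikes/units/meta triplet written by :func:`write_spike_data`."""
    directory = Path(directory)
    spikes_df = pd.read_csv(directory / "spikes.tsv", sep="\t")
    units_df = pd.read_csv(directory / "units.tsv", sep="\t")
    meta_path = directory / "meta.txt"
    unit_ids = units_df["unit_id"].to_numpy()
    grouped = {
        uid: np.sort(grp["time_s"].to_numpy())
        for uid, grp in spikes_df.groupby("unit_id", sort=False)
    }
    spike_times = [grouped.get(uid, np.array([])) for uid in unit_ids]
    if meta_path.exists():
        meta = read_key_value(meta_path)
        window = (float(meta["t_start"]), float(meta["t_end"]))
    else:
        t_max = spikes_df["time_s"].max() if len(spikes_df) else 1.0
        window = (0.0, float(t_max))
    return SpikeData(
        unit_ids, spike_times, units_df["region_label"].to_numpy(), window
    )


def write_counts(counts: SpikeCountMatrix, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(prefix.with_suffix(".tsv"), counts.counts, fmt="%d", delimiter="\t")
    sidecar = {
        "bin_width_s": counts.bin_width,
        "t_start": counts.t_start,
        "unit_ids": [str(u) for u in counts.unit_ids],
        "region_labels": [str(r) for r in counts.region_labels],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_counts(prefix) -> SpikeCountMatrix:
    prefix = Path(prefix)
    counts = np.loadtxt(prefix.with_suffix(".tsv"), dtype=np.int64, delimiter="\t", ndmin=2)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return SpikeCountMatrix(
        counts,
        float(meta["bin_width_s"]),
        float(meta["t_start"]),
        np.array(meta["unit_ids"]),
        np.array(meta["region_labels"]),
    )


def write_correlation(corr: CorrelationMatrix, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(prefix.with_suffix(".tsv"), corr.values, delimiter="\t")
    sidecar = {
        "bin_width_s": corr.bin_width,
        "unit_ids": [str(u) for u in corr.unit_ids],
        "region_labels": [str(r) for r in corr.region_labels],
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_correlation(prefix) -> CorrelationMatrix:
    prefix = Path(prefix)
    values = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return CorrelationMatrix(
        values,
        ~np.isnan(values),
        float(meta["bin_width_s"]),
        np.array(meta["unit_ids"]),
        np.array(meta["region_labels"]),
    )


def write_graph(graph: FunctionalGraph, prefix) -> None:
    """Edge list TSV (unit_a, unit_b, weight), node table, JSON metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    iu = np.triu_indices(graph.n_nodes, k=1)
    nz = graph.weights[iu] > 0
    pd.DataFrame(
        {
            "unit_a": graph.node_ids[iu[0][nz]],
            "unit_b": graph.node_ids[iu[1][nz]],
            "weight": graph.weights[iu][nz],
        }
    ).to_csv(prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
    pd.DataFrame({"unit_id": graph.node_ids}).to_csv(
        prefix.with_suffix(".nodes.tsv"), sep="\t", index=False
    )
    prefix.with_suffix(".meta.json").write_text(
        json.dumps(graph.meta, indent=2, default=str)
    )


def read_graph(prefix) -> FunctionalGraph:
    prefix = Path(prefix)
    edges = pd.read_csv(prefix.with_suffix(".edges.tsv"), sep="\t")
    nodes = pd.read_csv(prefix.with_suffix(".nodes.tsv"), sep="\t")
    meta_path = prefix.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    node_ids = nodes["unit_id"].to_numpy()
    index = {str(nid): i for i, nid in enumerate(node_ids)}
    n = len(node_ids)
    weights = np.zeros((n, n))
    for _, row in edges.iterrows():
        i, j = index[str(row["unit_a"])], index[str(row["unit_b"])]
        weights[i, j] = weights[j, i] = row["weight"]
    return FunctionalGraph(weights, node_ids, meta=meta)


def write_partition(partition: Partition, path) -> None:
    payload = {
        str(nid): int(code)
        for nid, code in zip(partition.node_ids, partition.codes())
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_partition(path) -> Partition:
    payload = json.loads(Path(path).read_text())
    return Partition(np.array(list(payload)), np.array(list(payload.values())))
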