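"""Plain-text dataset I/O.

A dataset directory holds, per subject:

* ``<id>_oxy.tsv`` / ``<id>_deoxy.tsv`` — delimited matrices, one row per
  sample, one column per channel, header row of 1-based channel ids;
* ``<id>.json`` — sidecar with sampling rate, block annotations (label,
  start, end sample) and the valid-channel mask;
* ``<id>_events.tsv`` — tab-separated events: ``onset_s``, ``event_type``
  (``stimulus``/``response``) and ``block``.

A generated dataset additionally carries ``ground_truth.json`` with the
planted structure.  Everything is text, so datasets diff and version
cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import AdjacencyMatrix, ConnectivityMatrix
from .core import BehavioralRecord, BlockAnnotation, HbTimeSeries, StimulusSchedule
from .synthetic import GroundTruth

__all__ = [
    "write_subject",
    "read_subject",
    "write_dataset",
    "read_dataset",
    "write_ground_truth",
    "read_ground_truth",
    "write_connectivity",
    "write_adjacency",
    "write_edge_list",
]

_FLOAT_FMT = "%.6g"


def _matrix_to_tsv(path: Path, data: np.ndarray) -> None:
    n_channels = data.shape[0]
    header = "\t".join(str(c) for c in range(1, n_channels + 1))
    np.savetxt(path, data.T, fmt=_FLOAT_FMT, delimiter="\t", header=header, comments="")


def _matrix_from_tsv(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float).T


def write_subject(
    series: HbTimeSeries, out_dir: str | Path, record: BehavioralRecord | None = None
) -> None:
    """Write one subject's matrices, sidecar, and (optionally) events."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = series.subject_id
    _matrix_to_tsv(out_dir / f"{sid}_oxy.tsv", series.oxy)
    _matrix_to_tsv(out_dir / f"{sid}_deoxy.tsv", series.deoxy)
    sidecar = {
        "subject_id": sid,
        "sampling_rate": series.sampling_rate,
        "blocks": [[b.label, b.start, b.end] for b in series.blocks],
        "valid_channels": series.valid_channels.astype(int).tolist(),
    }
    (out_dir / f"{sid}.json").write_text(json.dumps(sidecar, indent=1))
    if record is not None:
        rows = [
            {"onset_s": t, "event_type": "stimulus", "block": record.stimuli.block}
            for t in record.stimuli.onsets
        ] + [
            {"onset_s": t, "event_type": "response", "block": record.stimuli.block}
            for t in record.responses
        ]
        events = pd.DataFrame(rows).sort_values("onset_s")
        events.to_csv(out_dir / f"{sid}_events.tsv", sep="\t", index=False, float_format="%.4f")


def read_subject(
    out_dir: str | Path, subject_id: str
) -> tuple[HbTimeSeries, BehavioralRecord | None]:
    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / f"{subject_id}.json").read_text())
    series = HbTimeSeries(
        subject_id=sidecar["subject_id"],
        sampling_rate=sidecar["sampling_rate"],
        oxy=_matrix_from_tsv(out_dir / f"{subject_id}_oxy.tsv"),
        deoxy=_matrix_from_tsv(out_dir / f"{subject_id}_deoxy.tsv"),
        blocks=tuple(BlockAnnotation(lab, s, e) for lab, s, e in sidecar["blocks"]),
        valid_channels=np.asarray(sidecar["valid_channels"], dtype=bool),
    )
    events_path = out_dir / f"{subject_id}_events.tsv"
    record = None
    if events_path.exists():
        events = pd.read_csv(events_path, sep="\t")
        stim = events[events["event_type"] == "stimulus"]
        resp = events[events["event_type"] == "response"]
        block = str(stim["block"].iloc[0]) if len(stim) else "task"
        record = BehavioralRecord(
            subject_id=subject_id,
            stimuli=StimulusSchedule(onsets=tuple(stim["onset_s"]), block=block),
            responses=tuple(sorted(resp["onset_s"])),
        )
    return series, record


def write_dataset(
    series_list: list[HbTimeSeries],
    out_dir: str | Path,
    records: list[BehavioralRecord] | None = None,
    ground_truth: GroundTruth | None = None,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {r.subject_id: r for r in records} if records else {}
    for series in series_list:
        write_subject(series, out_dir, by_id.get(series.subject_id))
    if ground_truth is not None:
        write_ground_truth(ground_truth, out_dir / "ground_truth.json")


def read_dataset(
    out_dir: str | Path,
) -> tuple[list[HbTimeSeries], list[BehavioralRecord]]:
    """Read every subject in a dataset directory (sorted by id)."""
    out_dir = Path(out_dir)
    sids = sorted(
        p.stem for p in out_dir.glob("*.json") if p.name != "ground_truth.json"
    )
    if not sids:
        raise FileNotFoundError(f"no subject sidecars found in {out_dir}")
    series_list, records = [], []
    for sid in sids:
        series, record = read_subject(out_dir, sid)
        series_list.append(series)
        if record is not None:
            records.append(record)
    return series_list, records


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, default=list))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        seed=d["seed"],
        groups=d["groups"],
        hub_channels={g: tuple(v) for g, v in d["hub_channels"].items()},
        partner_channels={g: tuple(v) for g, v in d["partner_channels"].items()},
        anti_channels={g: tuple(v) for g, v in d["anti_channels"].items()},
        planted_edges={
            g: [tuple(e) for e in v] for g, v in d["planted_edges"].items()
        },
        se_params={g: tuple(v) for g, v in d["se_params"].items()},
        artifact_channels=tuple(d["artifact_channels"]),
        coupling_strength=d["coupling_strength"],
    )


def write_connectivity(conn: ConnectivityMatrix, path: str | Path) -> None:
    """Square Fisher-z matrix as TSV with channel-id headers (NaN = missing)."""
    n = conn.n_channels
    df = pd.DataFrame(conn.values, index=range(1, n + 1), columns=range(1, n + 1))
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_adjacency(adj: AdjacencyMatrix, path: str | Path) -> None:
    n = adj.n_nodes
    df = pd.DataFrame(adj.a, index=range(1, n + 1), columns=range(1, n + 1))
    df.to_csv(path, sep="\t")


def write_edge_list(
    conn: ConnectivityMatrix, adj: AdjacencyMatrix, path: str | Path
) -> None:
    """Edge-list text: channel_i, channel_j, z, kept_flag for graph tools."""
    pairs = conn.available_pairs()
    df = pd.DataFrame(
        {
            "channel_i": pairs[:, 0] + 1,
            "channel_j": pairs[:, 1] + 1,
            "z": conn.values[pairs[:, 0], pairs[:, 1]],
            "kept": adj.a[pairs[:, 0], pairs[:, 1]].astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
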