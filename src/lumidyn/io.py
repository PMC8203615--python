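"""Plain-text readers and writers for the pipeline's exchange formats.

All concentrations are uM, times are s, bimolecular rate constants are
uM^-1 s^-1 (package-wide convention).  Formats:

* trace dataset — CSV with columns trace_id, time_s, signal[, sigma] plus a
  JSON sidecar mapping trace_id to {E0_uM, S0_uM, observable, replicate};
* plate — long CSV with columns well_id, role, time_s, signal plus the
  injection time in a JSON sidecar (or as an argument);
* labelled matrices (segment correlations, difference matrices) — CSV with a
  header row and an index column;
* segments / regions — JSON list of {name, start, end} (1-based inclusive);
* residue/segment mapping — two-column TSV (label_a, label_b);
* per-residue profiles and bottleneck series — one- or two-column CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anm import DifferenceMatrix, SegmentCcorMatrix, SegmentSet
from .fitting import Trace, TraceDataset
from .screening import PlateReading, Well

__all__ = [
    "write_trace_dataset", "read_trace_dataset",
    "write_plate", "read_plate",
    "write_matrix", "read_matrix",
    "read_segments", "write_segments",
    "read_mapping", "write_mapping",
    "read_profile",
]


def write_trace_dataset(dataset: TraceDataset, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    frames = []
    meta = {}
    for tr in dataset:
        df = pd.DataFrame({"trace_id": tr.trace_id, "time_s": tr.time,
                           "signal": tr.signal})
        if tr.sigma is not None:
            df["sigma"] = tr.sigma
        frames.append(df)
        meta[tr.trace_id] = {"E0_uM": tr.E0, "S0_uM": tr.S0,
                             "observable": tr.observable, "replicate": tr.replicate}
    pd.concat(frames).to_csv(csv_path, index=False)
    csv_path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_trace_dataset(csv_path: str | Path) -> TraceDataset:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".meta.json").read_text())
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        m = meta[str(tid)]
        traces.append(Trace(
            trace_id=str(tid), time=grp["time_s"].to_numpy(),
            signal=grp["signal"].to_numpy(),
            sigma=grp["sigma"].to_numpy() if "sigma" in grp else None,
            E0=float(m["E0_uM"]), S0=float(m["S0_uM"]),
            observable=m.get("observable", "LUMINESCENCE_CUMULATIVE"),
            replicate=int(m.get("replicate", 0)),
        ))
    return TraceDataset(traces=traces)


def write_plate(plate: PlateReading, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    rows = []
    for w in plate.wells:
        for t, s in zip(plate.time, w.signal):
            rows.append((w.well_id, w.role, t, s))
    pd.DataFrame(rows, columns=["well_id", "role", "time_s", "signal"]).to_csv(
        csv_path, index=False
    )
    csv_path.with_suffix(".meta.json").write_text(json.dumps({
        "injection_time_s": plate.injection_time,
        "settle_delay_s": plate.settle_delay,
    }))


def read_plate(csv_path: str | Path, injection_time: float | None = None) -> PlateReading:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix(".meta.json")
    settle = 0.2
    if injection_time is None:
        meta = json.loads(meta_path.read_text())
        injection_time = float(meta["injection_time_s"])
        settle = float(meta.get("settle_delay_s", 0.2))
    time = np.sort(df["time_s"].unique())
    wells = []
    for (wid, role), grp in df.groupby(["well_id", "role"], sort=False):
        grp = grp.sort_values("time_s")
        if not np.array_equal(grp["time_s"].to_numpy(), time):
            raise ValueError(f"well {wid} is not on the shared time grid")
        wells.append(Well(well_id=str(wid), role=str(role),
                          signal=grp["signal"].to_numpy()))
    return PlateReading(time=time, wells=wells,
                        injection_time=injection_time, settle_delay=settle)


def write_matrix(m: SegmentCcorMatrix | DifferenceMatrix, path: str | Path) -> None:
    pd.DataFrame(m.matrix, index=m.labels, columns=m.labels).to_csv(path)


def read_matrix(path: str | Path) -> SegmentCcorMatrix:
    df = pd.read_csv(path, index_col=0)
    return SegmentCcorMatrix(labels=[str(c) for c in df.columns],
                             matrix=df.to_numpy(dtype=float))


def read_segments(path: str | Path) -> SegmentSet:
    return SegmentSet.from_records(json.loads(Path(path).read_text()))


def write_segments(segments: SegmentSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        [{"name": s.name, "start": s.start, "end": s.end} for s in segments],
        indent=1,
    ))


def read_mapping(path: str | Path) -> dict[str, str]:
    """Two-column TSV: label in structure A -> label in structure B."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split("\t")
        out[a] = b
    return out


def write_mapping(mapping: dict[str, str], path: str | Path) -> None:
    Path(path).write_text("\n".join(f"{a}\t{b}" for a, b in mapping.items()) + "\n")


def read_profile(path: str | Path, column: str | None = None) -> np.ndarray:
    """One-column (or named-column) per-residue/per-frame value series."""
    df = pd.read_csv(path)
    if column is None:
        column = df.columns[-1]
    return df[column].to_numpy(dtype=float)
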