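"""Plain-text I/O: METS files, dataset manifests, interval and result tables.

Everything is delimited text (CSV) plus small JSON sidecars, so datasets and
results round-trip losslessly and stay diffable.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .detection import R2Landscape, SyncIntervalRecord
from .motion_energy import MotionEnergySeries
from .synthetic_data import DyadSequence, GeneratorParams, IntervalSpec

__all__ = [
    "write_mets",
    "read_mets",
    "write_dataset",
    "read_dataset",
    "write_intervals",
    "read_intervals",
    "write_landscape",
    "write_result_table",
    "read_result_table",
]


def write_mets(series: MotionEnergySeries, path: str | Path) -> None:
    """Write one METS as ``frame,value`` CSV with a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"frame": np.arange(len(series)), "value": series.values})
    df.to_csv(path, index=False)
    meta = {
        "fps": series.fps,
        "roi_area": series.roi_area,
        "person_role": series.person_role,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_mets(path: str | Path) -> MotionEnergySeries:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return MotionEnergySeries(
        values=df["value"].to_numpy(float),
        fps=meta.get("fps", 25.0),
        roi_area=meta.get("roi_area"),
        person_role=meta.get("person_role"),
    )


def write_dataset(
    dataset: Sequence[DyadSequence],
    directory: str | Path,
    params: Optional[GeneratorParams] = None,
) -> Path:
    """Write a dataset manifest plus one METS file per person and dyad."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for dyad in dataset:
        ref = dyad.reference
        rows.append(
            {
                "id": dyad.id,
                "condition": dyad.condition,
                "sync_label": dyad.sync_label,
                "n_frames": dyad.n_frames,
                "ref_start": ref.start if ref else "",
                "ref_end": ref.end if ref else "",
                "construction_lag": (
                    ref.construction_lag
                    if ref and ref.construction_lag is not None
                    else ""
                ),
            }
        )
        write_mets(dyad.a, directory / f"{dyad.id}_a.csv")
        write_mets(dyad.b, directory / f"{dyad.id}_b.csv")
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if params is not None:
        (directory / "generator_params.json").write_text(
            json.dumps(asdict(params), indent=1)
        )
    return manifest


def read_dataset(directory: str | Path) -> List[DyadSequence]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    dataset = []
    for _, row in manifest.iterrows():
        ref = None
        if row["ref_start"] == row["ref_start"] and str(row["ref_start"]) != "":
            lag = row.get("construction_lag")
            has_lag = lag == lag and str(lag) != ""
            ref = IntervalSpec(
                start=int(row["ref_start"]),
                end=int(row["ref_end"]),
                construction_lag=int(lag) if has_lag else None,
            )
        dataset.append(
            DyadSequence(
                id=row["id"],
                condition=row["condition"],
                sync_label=row["sync_label"],
                a=read_mets(directory / f"{row['id']}_a.csv"),
                b=read_mets(directory / f"{row['id']}_b.csv"),
                reference=ref,
            )
        )
    return dataset


def write_intervals(
    intervals: Sequence[SyncIntervalRecord],
    path: str | Path,
    sequence_id: str = "",
    condition: str = "",
    method: str = "",
) -> None:
    """Interval table: sequence_id, condition, method, start, end, lag, mean_r2."""
    rows = [
        {
            "sequence_id": sequence_id,
            "condition": condition,
            "method": method,
            "start_frame": iv.start,
            "end_frame": iv.end,
            "lag_frames": iv.lag,
            "mean_r2": iv.mean_r2,
        }
        for iv in intervals
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "condition", "method",
            "start_frame", "end_frame", "lag_frames", "mean_r2",
        ],
    ).to_csv(path, index=False)


def read_intervals(path: str | Path) -> List[SyncIntervalRecord]:
    df = pd.read_csv(path)
    return [
        SyncIntervalRecord(
            start=int(r["start_frame"]),
            end=int(r["end_frame"]),
            lag=float(r["lag_frames"]),
            mean_r2=float(r["mean_r2"]),
        )
        for _, r in df.iterrows()
    ]


def write_landscape(landscape: R2Landscape, path: str | Path) -> None:
    """Debug dump: dense r2 matrix with time/lag header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# time_grid: " + " ".join(map(str, landscape.time_grid)) + "\n")
        fh.write("# lag_grid: " + " ".join(map(str, landscape.lag_grid)) + "\n")
        np.savetxt(fh, landscape.r2, fmt="%.6g")


def write_result_table(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False)


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
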