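"""Plain-text I/O: electropherogram CSVs with JSON metadata sidecars,
study manifests, and the peaks table."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .peaks import Peak
from .simulate import Electropherogram

EG_COLUMNS = ("time_min", "signal_mau")
PEAK_COLUMNS = (
    "run_id",
    "apex_time_min",
    "height_mau",
    "raw_area",
    "corrected_area",
    "width_half_height_min",
    "plate_number",
    "asymmetry",
)


def write_electropherogram(eg: Electropherogram, path: str | Path) -> None:
    """Write one run as `time_min,signal_mau` CSV plus a `.meta.json` sidecar."""
    path = Path(path)
    pd.DataFrame({"time_min": eg.time, "signal_mau": eg.signal}).to_csv(path, index=False)
    sidecar = path.with_suffix("").with_suffix(".meta.json")
    with open(sidecar, "w") as fh:
        json.dump(eg.metadata, fh, indent=1, sort_keys=True)


def read_electropherogram(path: str | Path) -> Electropherogram:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:2]) != list(EG_COLUMNS):
        raise ValueError(f"{path}: expected columns {EG_COLUMNS}, got {list(df.columns)}")
    sidecar = path.with_suffix("").with_suffix(".meta.json")
    metadata = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            metadata = json.load(fh)
    return Electropherogram(
        time=df["time_min"].to_numpy(float),
        signal=df["signal_mau"].to_numpy(float),
        metadata=metadata,
    )


def write_study(
    runs: Sequence[Electropherogram], outdir: str | Path, prefix: str = "run"
) -> pd.DataFrame:
    """Write a study: one CSV per run plus a `manifest.csv` index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, eg in enumerate(runs, start=1):
        fname = f"{prefix}_{i:03d}.csv"
        write_electropherogram(eg, outdir / fname)
        rows.append(
            {
                "run_id": i,
                "sample_label": eg.metadata.get("sample_label", f"{prefix}_{i}"),
                "nominal_conc_ug_ml": eg.metadata.get("nominal_conc_ug_ml", np.nan),
                "file": fname,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def read_study(manifest_path: str | Path) -> list[tuple[dict, Electropherogram]]:
    """Read a manifest and its runs; yields (manifest row dict, run) pairs."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    out = []
    for _, row in manifest.iterrows():
        eg = read_electropherogram(manifest_path.parent / row["file"])
        out.append((row.to_dict(), eg))
    return out


def peaks_frame(run_ids: Sequence, peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "run_id": rid,
                "apex_time_min": p.apex_time,
                "height_mau": p.height,
                "raw_area": p.raw_area,
                "corrected_area": p.corrected_area,
                "width_half_height_min": p.width_half_height,
                "plate_number": p.plate_number,
                "asymmetry": p.asymmetry,
            }
            for rid, p in zip(run_ids, peaks)
        ],
        columns=list(PEAK_COLUMNS),
    )
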