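"""Readers and writers for the pipeline's on-disk formats.

Movies are channel-major multi-page TIFFs (2, T, H, W) in 16-bit; spine
ROIs a JSON list of polygons with 0-based pixel vertices; trial traces a
long-format CSV (mouse, dendrite, odor, trial, frame, F) or an HDF5 file
with the same hierarchy; ground truth a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .contact import SpineROI
from .synth import CalciumDataset, ContactMovie

__all__ = [
    "write_contact_movie",
    "read_contact_movie",
    "write_rois",
    "read_rois",
    "write_traces_csv",
    "read_traces_csv",
    "write_traces_hdf5",
    "read_traces_hdf5",
]


def write_contact_movie(path: str | Path, movie: ContactMovie) -> None:
    """Write a two-channel (dendrite, microglia-mask) stack as 16-bit TIFF."""
    stack = np.stack(
        [movie.dendrite.astype(np.uint16), movie.microglia_mask.astype(np.uint16)]
    )
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",
        planarconfig="separate",
        metadata={"axes": "CTYX"},
    )


def read_contact_movie(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back (dendrite stack, binary microglia mask stack)."""
    stack = tifffile.imread(str(path))
    if stack.ndim != 4 or stack.shape[0] != 2:
        raise ValueError("expected a channel-major (2, T, H, W) stack")
    return stack[0], stack[1].astype(bool)


def write_rois(path: str | Path, spines: list[SpineROI]) -> None:
    payload = [
        {
            "spine_id": s.spine_id,
            "class": s.spine_class,
            "plane_index": s.plane_index,
            "polygon": s.polygon.tolist(),
        }
        for s in spines
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path: str | Path) -> list[SpineROI]:
    payload = json.loads(Path(path).read_text())
    return [
        SpineROI(
            spine_id=d["spine_id"],
            spine_class=d["class"],
            polygon=np.asarray(d["polygon"], dtype=float),
            plane_index=int(d.get("plane_index", 0)),
        )
        for d in payload
    ]


_TRACE_COLS = ["mouse", "dendrite", "odor", "trial", "frame", "F"]


def traces_to_frame(ds: CalciumDataset) -> pd.DataFrame:
    rows = []
    for (mouse, dend, odor, trial), f in ds.traces.items():
        rows.append(
            pd.DataFrame(
                {
                    "mouse": mouse,
                    "dendrite": dend,
                    "odor": odor,
                    "trial": trial,
                    "frame": np.arange(f.size),
                    "F": f,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_traces_csv(path: str | Path, ds: CalciumDataset) -> None:
    traces_to_frame(ds).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> dict[tuple[str, str, str, int], np.ndarray]:
    df = pd.read_csv(path)
    missing = set(_TRACE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    out = {}
    for (mouse, dend, odor, trial), sub in df.groupby(
        ["mouse", "dendrite", "odor", "trial"], sort=True
    ):
        out[(str(mouse), str(dend), str(odor), int(trial))] = (
            sub.sort_values("frame")["F"].to_numpy(dtype=float)
        )
    return out


def write_traces_hdf5(path: str | Path, ds: CalciumDataset) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["frame_rate_hz"] = ds.frame_rate_hz
        h5.attrs["baseline_s"] = ds.baseline_s
        for (mouse, dend, odor, trial), f in ds.traces.items():
            h5.create_dataset(f"{mouse}/{dend}/{odor}/{trial}", data=f)


def read_traces_hdf5(path: str | Path) -> dict[tuple[str, str, str, int], np.ndarray]:
    out = {}
    with h5py.File(path, "r") as h5:

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                mouse, dend, odor, trial = name.split("/")
                out[(mouse, dend, odor, int(trial))] = obj[()]

        h5.visititems(visit)
    return out
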