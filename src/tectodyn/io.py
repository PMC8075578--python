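"""Readers and writers for the pipeline's on-disk formats.

Trace matrices travel as CSV (header row of frame times) and HDF5; positions
and stimulus logs as CSV; ground truth as JSON; movies as multi-page TIFF;
correlation matrices, rasters and pattern sets as HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import tifffile

from .synthetic import GroundTruth, SimulationConfig, StimulusLog, SyntheticDataset

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_traces_h5",
    "read_traces_h5",
    "write_movie",
    "read_movie",
    "save_dataset",
    "load_dataset",
    "write_matrix_h5",
    "read_matrix_h5",
]


# ---------------------------------------------------------------------------
# trace matrices
# ---------------------------------------------------------------------------


def write_traces_csv(path, traces: np.ndarray, frame_rate_hz: float) -> None:
    times = np.arange(traces.shape[1]) / frame_rate_hz
    pd.DataFrame(traces, columns=times).to_csv(path, index=False)


def read_traces_csv(path):
    df = pd.read_csv(path)
    times = np.asarray(df.columns, dtype=float)
    return df.to_numpy(dtype=float), times


def write_traces_h5(path, traces: np.ndarray, frame_rate_hz: float,
                    name: str = "traces") -> None:
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset(name, data=np.asarray(traces, dtype=float))
        d.attrs["frame_rate_hz"] = frame_rate_hz


def read_traces_h5(path, name: str = "traces"):
    with h5py.File(path, "r") as fh:
        d = fh[name]
        return d[()], float(d.attrs["frame_rate_hz"])


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------


def write_movie(path, movie: np.ndarray) -> None:
    """Write a movie as a 16-bit multi-page TIFF (values clipped/rounded)."""
    data = np.clip(np.round(np.asarray(movie)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


def save_dataset(ds: SyntheticDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_traces_csv(out / "traces.csv", ds.traces, ds.frame_rate_hz)
    write_traces_h5(out / "traces.h5", ds.traces, ds.frame_rate_hz)
    pd.DataFrame(
        {
            "neuron_id": np.arange(ds.n_neurons),
            "x_um": ds.positions[:, 0],
            "y_um": ds.positions[:, 1],
        }
    ).to_csv(out / "positions.csv", index=False)
    pd.DataFrame(ds.neuropil_contour, columns=["x_um", "y_um"]).to_csv(
        out / "neuropil_contour.csv", index=False
    )
    ds.stimulus_log.to_csv(out / "stimulus_log.csv")
    ds.ground_truth.to_json(out / "ground_truth.json")
    meta = {
        "frame_rate_hz": ds.frame_rate_hz,
        "sa_end_frame": int(ds.sa_end_frame),
        "config": ds.config.to_dict(),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def load_dataset(in_dir) -> SyntheticDataset:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    traces, _fps = read_traces_h5(src / "traces.h5")
    pos = pd.read_csv(src / "positions.csv")[["x_um", "y_um"]].to_numpy()
    contour = pd.read_csv(src / "neuropil_contour.csv").to_numpy()
    log = StimulusLog.from_csv(src / "stimulus_log.csv")
    gt = GroundTruth.from_json(src / "ground_truth.json")
    return SyntheticDataset(
        traces=traces,
        positions=pos,
        neuropil_contour=contour,
        stimulus_log=log,
        frame_rate_hz=meta["frame_rate_hz"],
        sa_end_frame=meta["sa_end_frame"],
        ground_truth=gt,
        config=SimulationConfig.from_dict(meta["config"]),
    )


# ---------------------------------------------------------------------------
# generic matrices
# ---------------------------------------------------------------------------


def write_matrix_h5(path, **arrays) -> None:
    with h5py.File(path, "w") as fh:
        for name, arr in arrays.items():
            fh.create_dataset(name, data=np.asarray(arr))


def read_matrix_h5(path, *names):
    with h5py.File(path, "r") as fh:
        out = tuple(fh[n][()] for n in names)
    return out[0] if len(out) == 1 else out
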