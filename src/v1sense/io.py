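"""Plain-text and TIFF I/O for traces, events, piezo and movies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .synthgen import PiezoRecording
from .traces import EventTrainSet, TraceSet


def write_traces_csv(path, traces: TraceSet) -> None:
    """CSV with a time_s column and one column per neuron (raw F)."""
    df = pd.DataFrame(traces.F.T, columns=[str(i) for i in traces.neuron_ids])
    df.insert(0, "time_s", traces.times)
    df.to_csv(path, index=False)


def read_traces_csv(path) -> TraceSet:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("need at least two samples to infer the sampling rate")
    f = 1.0 / float(np.median(np.diff(t)))
    cols = [c for c in df.columns if c != "time_s"]
    return TraceSet(F=df[cols].to_numpy().T, f=f, neuron_ids=np.array(cols))


def write_events_csv(path, events: EventTrainSet) -> None:
    """Binary neurons × frames matrix, one row per neuron."""
    pd.DataFrame(events.B, index=events.neuron_ids).to_csv(path, header=False)


def read_events_csv(path, f: float) -> EventTrainSet:
    df = pd.read_csv(path, header=None, index_col=0)
    return EventTrainSet(B=df.to_numpy(), f=f, neuron_ids=df.index.to_numpy())


def write_piezo_csv(path, piezo: PiezoRecording) -> None:
    t = np.arange(piezo.voltage.size) / piezo.fs
    pd.DataFrame({"time_s": t, "volts": piezo.voltage}).to_csv(path, index=False)


def read_piezo_csv(path) -> PiezoRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return PiezoRecording(voltage=df["volts"].to_numpy(), fs=round(fs, 6))


def write_movie_tiff(path, movie: np.ndarray) -> None:
    tifffile.imwrite(path, movie)


def read_movie_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_positions_csv(path, positions: np.ndarray, group_ids=None) -> None:
    df = pd.DataFrame(positions, columns=["x_um", "y_um"])
    df.insert(0, "id", np.arange(len(df)))
    if group_ids is not None:
        df["group"] = np.asarray(group_ids)
    df.to_csv(path, index=False)


def read_positions_csv(path):
    df = pd.read_csv(path)
    pos = df[["x_um", "y_um"]].to_numpy()
    groups = df["group"].to_numpy() if "group" in df.columns else None
    return pos, groups
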