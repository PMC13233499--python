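"""Recording and epoch persistence (HDF5 + events TSV)."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .signal import Epochs
from .synth import Recording

_EVENT_COLS = [
    "onset_s", "run", "trial", "sequence", "slot", "class_id", "stream",
    "is_target", "target",
]


def write_recording(recording: Recording, path) -> None:
    """HDF5 with datasets ``data`` (channels x samples, microvolts) and
    ``fs_hz``/``channel_labels`` attributes; events in a sibling ``.events.tsv``."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip", compression_opts=4)
        f.attrs["fs_hz"] = recording.fs_hz
        f.attrs["channel_labels"] = [str(c) for c in recording.channel_labels]
    recording.events.to_csv(path.with_suffix(".events.tsv"), sep="\t", index=False)


def read_recording(path) -> Recording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs_hz"])
        labels = [str(c) for c in f.attrs["channel_labels"]]
    events_path = path.with_suffix(".events.tsv")
    events = pd.read_csv(events_path, sep="\t") if events_path.exists() else pd.DataFrame(
        columns=_EVENT_COLS
    )
    return Recording(data=data, fs_hz=fs, channel_labels=labels, events=events)


def write_epochs(epochs: Epochs, path) -> None:
    """HDF5 with the epoch array, window attributes and a metadata table
    mirroring the events-TSV columns."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=4)
        f.attrs["tmin_s"] = epochs.tmin_s
        f.attrs["tmax_s"] = epochs.tmax_s
        f.attrs["fs_hz"] = epochs.fs_hz
        f.attrs["channel_labels"] = [str(c) for c in epochs.channel_labels]
    epochs.metadata.to_csv(path.with_suffix(".metadata.tsv"), sep="\t", index=False)


def read_epochs(path) -> Epochs:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        attrs = dict(f.attrs)
        labels = [str(c) for c in attrs["channel_labels"]]
    metadata = pd.read_csv(path.with_suffix(".metadata.tsv"), sep="\t")
    return Epochs(
        data=data,
        tmin_s=float(attrs["tmin_s"]),
        tmax_s=float(attrs["tmax_s"]),
        fs_hz=float(attrs["fs_hz"]),
        channel_labels=labels,
        metadata=metadata,
    )
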