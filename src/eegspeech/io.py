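"""Dataset container: one HDF5 file, one group per subject.

Each subject group holds the trial array, string labels, and metadata
(sampling rate, channel names, task).  A CSV label manifest can be
written alongside for quick inspection.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import TrialSet

__all__ = ["save_dataset", "load_dataset", "write_label_manifest"]


def save_dataset(path, dataset: list[TrialSet]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for trials in dataset:
            g = f.create_group(f"subjects/{trials.subject_id}")
            g.create_dataset("data", data=trials.data, compression="gzip")
            g.create_dataset(
                "labels",
                data=np.asarray([str(l) for l in trials.labels], dtype="S32"),
            )
            g.attrs["fs"] = trials.fs
            g.attrs["channel_names"] = [str(c) for c in trials.channel_names]
            g.attrs["task"] = trials.task


def load_dataset(path) -> list[TrialSet]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            g = f[f"subjects/{sid}"]
            out.append(
                TrialSet(
                    data=g["data"][...],
                    labels=np.array([l.decode() for l in g["labels"][...]]),
                    subject_id=sid,
                    fs=float(g.attrs["fs"]),
                    channel_names=tuple(g.attrs["channel_names"]),
                    task=str(g.attrs["task"]),
                )
            )
    return out


def write_label_manifest(path, dataset: list[TrialSet]) -> None:
    rows = []
    for trials in dataset:
        for i, label in enumerate(trials.labels):
            rows.append(
                dict(subject=trials.subject_id, trial=i, label=str(label),
                     task=trials.task)
            )
    pd.DataFrame(rows).to_csv(path, index=False)
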