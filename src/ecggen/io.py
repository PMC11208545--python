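"""Annotated ECG records and beat datasets, with WFDB / HDF5 / CSV I/O.

An :class:`ECGRecord` is one continuous single-channel trace in millivolts,
sampled at ``fs`` Hz, with beat annotations ``(sample_index, symbol)`` anchored
at R-peaks.  A :class:`BeatDataset` is the unit exchanged by every downstream
stage: an ``n x L`` matrix of fixed-length beats with integer class labels.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import wfdb_lite

__all__ = ["ECGRecord", "BeatDataset", "read_record", "write_dataset", "read_dataset"]


@dataclass
class ECGRecord:
    """One annotated ECG channel.

    Parameters
    ----------
    record_id : str
        Record name (e.g. ``"100"``).
    fs : float
        Sampling rate in Hz; must be positive.
    samples : ndarray
        Amplitudes in mV, one channel.
    annotations : list of (int, str)
        Beat annotations as ``(sample_index, symbol)``, strictly increasing
        indices, every index inside ``[0, len(samples))``.
    """

    record_id: str
    fs: float
    samples: np.ndarray
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        idx = [int(i) for i, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation indices must be strictly increasing")
        n = self.samples.shape[0]
        for i in idx:
            if not (0 <= i < n):
                raise ValueError(f"annotation index {i} outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])


@dataclass
class BeatDataset:
    """Fixed-length beat matrix with integer class labels.

    ``beats`` is ``(n, beat_length)``; every label lies in
    ``[0, len(class_names))``; ``provenance`` tags the origin of the beats
    (``"real"``, ``"synthetic"``, ``"mixed"``, ...).
    """

    beats: np.ndarray
    labels: np.ndarray
    class_names: list
    fs: float
    provenance: str = "real"

    def __post_init__(self):
        self.beats = np.atleast_2d(np.asarray(self.beats, dtype=np.float64))
        if self.beats.size == 0:
            self.beats = self.beats.reshape(0, self.beats.shape[-1] if self.beats.ndim > 1 else 0)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.beats.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.beats.shape[0]} beats but {self.labels.shape[0]} labels"
            )
        c = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= c):
            raise ValueError(f"labels must lie in [0, {c})")

    @property
    def n(self) -> int:
        return int(self.beats.shape[0])

    @property
    def beat_length(self) -> int:
        return int(self.beats.shape[1])

    def subset(self, indices) -> "BeatDataset":
        indices = np.asarray(indices, dtype=np.int64)
        return BeatDataset(
            self.beats[indices], self.labels[indices], list(self.class_names),
            self.fs, self.provenance,
        )

    def concat(self, other: "BeatDataset", provenance: str = "mixed") -> "BeatDataset":
        if list(other.class_names) != list(self.class_names):
            raise ValueError("class maps differ")
        if other.n and self.n and other.beat_length != self.beat_length:
            raise ValueError("beat lengths differ")
        return BeatDataset(
            np.vstack([self.beats, other.beats]) if self.n and other.n
            else (self.beats if other.n == 0 else other.beats),
            np.concatenate([self.labels, other.labels]),
            list(self.class_names), self.fs, provenance,
        )


def read_record(path, channel: int = 0) -> ECGRecord:
    """Read one channel of a WFDB record with its beat annotations.

    ``path`` is the record path without extension (``dir/100`` for
    ``100.hea/.dat/.atr``).  Non-beat annotation symbols (rhythm changes,
    signal-quality flags) are dropped; amplitudes are converted to mV using
    the header gain/baseline.
    """
    path = Path(path)
    header = wfdb_lite.read_header(path.with_suffix(".hea"))
    if not (0 <= channel < header["n_sig"]):
        raise IndexError(
            f"channel {channel} out of range for {header['n_sig']}-signal record"
        )
    sig = wfdb_lite.read_signal(path, header)  # (n_samples, n_sig) in mV
    ann_path = path.with_suffix(".atr")
    annotations = []
    if ann_path.exists():
        for idx, sym in wfdb_lite.read_annotations(ann_path):
            if sym in wfdb_lite.BEAT_SYMBOLS:
                annotations.append((int(idx), sym))
    return ECGRecord(
        record_id=header["record_name"], fs=header["fs"],
        samples=sig[:, channel], annotations=annotations,
    )


# HDF5 layout: /beats (n, L) float64, /labels (n,) int64; root attrs hold
# class_names (JSON), fs, provenance.

def write_dataset(ds: BeatDataset, path) -> None:
    """Serialize a :class:`BeatDataset` to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("beats", data=ds.beats)
        f.create_dataset("labels", data=ds.labels)
        f.attrs["class_names"] = json.dumps(list(ds.class_names))
        f.attrs["fs"] = float(ds.fs)
        f.attrs["provenance"] = ds.provenance
        f.attrs["beat_length"] = ds.beat_length


def read_dataset(path) -> BeatDataset:
    """Inverse of :func:`write_dataset`."""
    try:
        with h5py.File(path, "r") as f:
            return BeatDataset(
                beats=f["beats"][()],
                labels=f["labels"][()],
                class_names=json.loads(f.attrs["class_names"]),
                fs=float(f.attrs["fs"]),
                provenance=str(f.attrs["provenance"]),
            )
    except (OSError, KeyError) as exc:
        raise ValueError(f"not a valid beat-dataset container: {path}: {exc}") from exc


def export_csv(ds: BeatDataset, path) -> None:
    """Write beats as CSV, one beat per row, integer label as last column."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        for beat, label in zip(ds.beats, ds.labels):
            w.writerow([f"{v:.9g}" for v in beat] + [int(label)])
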