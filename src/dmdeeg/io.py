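"""Reading and writing EEG recordings, stimulus-interval tables, and feature tensors.

Recordings are kept in microvolts throughout.  Three on-disk dialects are
supported: 16-bit EDF (read through :mod:`mne`, written by a minimal internal
writer), EEGLAB ``.set`` (MATLAB v5 container, with optional ``.fdt`` sidecar),
and an internal HDF5 container used by the synthetic-cohort tools.

Feature tensors (the 50x50x12 CNN inputs) are persisted losslessly in HDF5 with
a JSON-serialized metadata attribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

GROUPS = ("AD", "FTD", "CN")

#: The 19-electrode international 10-20 montage used by the EO photostimulation
#: cohort; validated only when ``strict_montage`` is requested.
MONTAGE_10_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

TENSOR_SHAPE = (50, 50, 12)


class FormatError(ValueError):
    """Raised when a file cannot be parsed under the requested dialect."""


class SchemaError(ValueError):
    """Raised when a delimited table is missing required columns."""


@dataclass
class EEGRecording:
    """One subject's continuous multichannel EEG.

    Attributes
    ----------
    subject_id : str
        Cohort-unique identifier.
    group : str
        Diagnostic group label, one of ``AD``, ``FTD``, ``CN``.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz (500 Hz for the reference cohort).
    channel_labels : tuple of str
        Electrode labels in data row order.
    """

    subject_id: str
    group: str
    data: np.ndarray
    fs: float
    channel_labels: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match channel dimension")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class StimulusInterval:
    """Photic-stimulation on-period of one recording, in seconds."""

    subject_id: str
    onset: float
    offset: float

    def __post_init__(self):
        if not (0 <= self.onset < self.offset):
            raise ValueError(
                f"invalid interval for subject {self.subject_id}: "
                f"[{self.onset}, {self.offset}]"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def read_recording(path, format="internal", subject_id=None, group="CN",
                   strict_montage=False) -> EEGRecording:
    """Load a recording from ``path`` under the named dialect.

    Parameters
    ----------
    format : {"edf", "eeglab_set", "internal"}
    subject_id, group
        Used when the container carries no subject metadata (EDF / .set).
    strict_montage : bool
        Require the 19-label 10-20 montage.

    The sampling rate is taken from file metadata and never resampled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        rec = _read_edf(path, subject_id or path.stem, group)
    elif format == "eeglab_set":
        rec = _read_eeglab(path, subject_id or path.stem, group)
    elif format == "internal":
        rec = _read_internal(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if rec.n_channels == 0:
        raise FormatError(f"{path}: empty recording (0 channels)")
    if strict_montage:
        labels = tuple(lbl.capitalize() if lbl.islower() else lbl
                       for lbl in rec.channel_labels)
        if labels != MONTAGE_10_20:
            raise FormatError(
                f"{path}: channel labels do not match the 19-electrode "
                "10-20 montage"
            )
    return rec


def _read_edf(path, subject_id, group) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of error types
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return EEGRecording(subject_id, group, data_uv, float(raw.info["sfreq"]),
                        tuple(raw.ch_names))


def _read_eeglab(path, subject_id, group) -> EEGRecording:
    from scipy.io import loadmat

    try:
        mat = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable EEGLAB .set file ({exc})") from exc
    if "EEG" in mat:
        eeg = mat["EEG"]
    else:
        candidates = [v for k, v in mat.items() if not k.startswith("__")]
        if not candidates:
            raise FormatError(f"{path}: no EEG struct found")
        eeg = candidates[0]
    try:
        fs = float(eeg.srate)
        nbchan = int(eeg.nbchan)
        pnts = int(eeg.pnts)
        data = eeg.data
    except AttributeError as exc:
        raise FormatError(f"{path}: EEG struct missing required fields") from exc
    if isinstance(data, str):  # samples live in a .fdt sidecar, float32 column-major
        fdt = path.parent / data
        data = np.fromfile(fdt, dtype="<f4").reshape(-1, nbchan).T
    data = np.asarray(data, dtype=float).reshape(nbchan, pnts, order="F")[:, :pnts]
    labels = ()
    chanlocs = getattr(eeg, "chanlocs", None)
    if chanlocs is not None:
        try:
            labels = tuple(str(c.labels) for c in np.atleast_1d(chanlocs))
        except AttributeError:
            labels = ()
    return EEGRecording(subject_id, group, data, fs, labels)


def _read_internal(path) -> EEGRecording:
    try:
        with h5py.File(path, "r") as f:
            dset = f["data"]
            return EEGRecording(
                subject_id=dset.attrs["subject_id"],
                group=dset.attrs["group"],
                data=dset[()],
                fs=float(dset.attrs["fs"]),
                channel_labels=tuple(dset.attrs["channel_labels"]),
            )
    except (OSError, KeyError) as exc:
        raise FormatError(f"{path}: not a readable internal recording ({exc})") from exc


def write_recording(rec: EEGRecording, path, format="internal") -> None:
    """Persist a recording (internal HDF5 or 16-bit EDF)."""
    path = Path(path)
    if format == "internal":
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("data", data=rec.data)
            dset.attrs["subject_id"] = rec.subject_id
            dset.attrs["group"] = rec.group
            dset.attrs["fs"] = rec.fs
            dset.attrs["channel_labels"] = list(rec.channel_labels)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_edf(rec: EEGRecording, path) -> None:
    """Minimal EDF writer: one data record per second, 16-bit samples.

    Sufficient for fixtures and interchange; the signal is truncated to a whole
    number of 1-s records as the format requires, and quantized to the EDF
    16-bit integer range over each channel's physical min/max.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    m = rec.n_channels
    data = rec.data[:, : n_rec * fs]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def pad(s, n):
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad(f"X X X {rec.subject_id}", 80),
        pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + m)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(m), 4),
    ])
    sig = b"".join([
        b"".join(pad(lbl, 16) for lbl in rec.channel_labels),
        b"".join(pad("AgAgCl electrode", 80) for _ in range(m)),
        b"".join(pad("uV", 8) for _ in range(m)),
        b"".join(pad(f"{phys_min[i]:.4g}", 8) for i in range(m)),
        b"".join(pad(f"{phys_max[i]:.4g}", 8) for i in range(m)),
        b"".join(pad(str(dig_min), 8) for _ in range(m)),
        b"".join(pad(str(dig_max), 8) for _ in range(m)),
        b"".join(pad("", 80) for _ in range(m)),
        b"".join(pad(str(fs), 8) for _ in range(m)),
        b"".join(pad("", 32) for _ in range(m)),
    ])
    with open(path, "wb") as f:
        f.write(header + sig)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            f.write(block.tobytes())  # channel-major within each record


# ---------------------------------------------------------------------------
# stimulus-interval tables
# ---------------------------------------------------------------------------

def read_intervals(path) -> list[StimulusInterval]:
    """Read a delimited stimulus-interval table (TSV or CSV, header required).

    Required columns: ``subject_id``, ``onset``, ``offset``.  A ``group``
    column, if present, is preserved by :func:`read_interval_table` but ignored
    here.
    """
    df = read_interval_table(path)
    return [
        StimulusInterval(str(row.subject_id), float(row.onset), float(row.offset))
        for row in df.itertuples(index=False)
    ]


def read_interval_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = {"subject_id", "onset", "offset"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    bad = df.index[df["offset"] <= df["onset"]]
    if len(bad):
        raise ValueError(
            f"{path}: offset <= onset at row index {int(bad[0])}"
        )
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_intervals(intervals: Sequence[StimulusInterval], path,
                    groups=None) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(
        {
            "subject_id": [iv.subject_id for iv in intervals],
            "onset": [iv.onset for iv in intervals],
            "offset": [iv.offset for iv in intervals],
        }
    )
    if groups is not None:
        df["group"] = list(groups)
    df.to_csv(path, sep=sep, index=False)


def load_stimulus_table() -> pd.DataFrame:
    """Stimulus onset/offset table of the 88-subject EO photostimulation cohort
    (OpenNeuro ds006036), as published: one interval per subject with group
    label."""
    return read_interval_table(Path(__file__).parent / "data" / "stimulus_intervals.tsv")


# ---------------------------------------------------------------------------
# feature tensors
# ---------------------------------------------------------------------------

REQUIRED_META = ("subject_id", "group", "epoch_index", "method", "band")


def write_feature_tensor(tensor: np.ndarray, meta: dict, path) -> None:
    """Write one 50x50x12 feature tensor to HDF5, losslessly.

    ``meta`` must carry subject_id, group, epoch_index, method, and band; it is
    stored as a JSON attribute so the round trip is exact.
    """
    tensor = np.asarray(tensor)
    if tensor.shape != TENSOR_SHAPE:
        raise ValueError(f"tensor shape {tensor.shape} != {TENSOR_SHAPE}")
    missing = [k for k in REQUIRED_META if k not in meta]
    if missing:
        raise ValueError(f"metadata missing required key(s) {missing}")
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("tensor", data=tensor)
        dset.attrs["meta"] = json.dumps(meta)


def read_feature_tensor(path):
    """Read back a feature tensor and its metadata; bit-exact round trip."""
    try:
        with h5py.File(path, "r") as f:
            dset = f["tensor"]
            tensor = dset[()]
            meta = json.loads(dset.attrs["meta"])
    except (OSError, KeyError) as exc:
        raise FormatError(f"{path}: corrupted or foreign tensor container ({exc})") from exc
    if tensor.shape != TENSOR_SHAPE:
        raise FormatError(f"{path}: stored tensor has shape {tensor.shape}")
    return tensor, meta
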