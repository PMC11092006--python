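"""Data model and readers/writers for waveforms, annotations, and clinical tables.

Waveform recordings are uniformly sampled traces with a per-sample boolean
validity mask.  Missing or rejected data is always encoded through the mask,
never through sentinel values, because intracranial pressure can legitimately
be negative.  The HDF5 layout is one group per channel holding a ``samples``
dataset with ``sampling_rate`` (Hz) and ``start_time`` (seconds since the
hemorrhage) attributes; a two-column ``time,value`` CSV is accepted for small
fixtures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

CHANNELS = ("ABP", "ICP", "HR")
ANNOTATION_REASONS = ("line_failure", "evd_manipulation", "other")


class FormatError(ValueError):
    """Raised when an input file violates the declared layout."""


class ChannelNotFoundError(KeyError):
    """Raised when a requested channel is absent from a recording."""


@dataclass
class WaveformSignal:
    """One channel's uniformly sampled high-resolution trace.

    Parameters
    ----------
    channel_label : str
        One of ``ABP``, ``ICP``, ``HR``.
    sampling_rate : float
        Samples per second; pressures are expected at >= 100 Hz.
    start_time : float
        Seconds since the hemorrhage (ictus); sample ``i`` occurs at
        ``start_time + i / sampling_rate``.
    samples : ndarray
        mmHg for pressures, bpm for heart rate.
    valid : ndarray of bool
        True where the sample is retained.  Cleaning only ever flips
        True -> False.
    """

    channel_label: str
    sampling_rate: float
    start_time: float
    samples: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.channel_label not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel_label!r}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.samples.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.samples.shape:
            raise ValueError("samples and valid must have equal length")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def times(self) -> np.ndarray:
        """Time of each sample in seconds since the hemorrhage."""
        return self.start_time + np.arange(len(self.samples)) / self.sampling_rate

    def copy(self) -> "WaveformSignal":
        return WaveformSignal(
            self.channel_label,
            self.sampling_rate,
            self.start_time,
            self.samples.copy(),
            self.valid.copy(),
        )


@dataclass(frozen=True)
class AnnotationInterval:
    """A manually flagged half-open time interval ``[start, end)``."""

    channel_label: str
    start: float
    end: float
    reason: str = "other"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval end {self.end} must exceed start {self.start}")
        if self.reason not in ANNOTATION_REASONS:
            raise ValueError(f"unknown annotation reason {self.reason!r}")


@dataclass
class PatientRecord:
    """Clinical covariates and 12-month functional outcome for one patient.

    ``gose`` is the extended Glasgow Outcome Scale (1 dead .. 8 upper good
    recovery) at 12 months; ``wfns`` (1-5) and ``mfisher`` (1-4) grade
    clinical and radiological severity; ``dci`` flags delayed cerebral
    infarction.  ``monitoring_start`` is the delay (seconds since ictus)
    before high-resolution monitoring began.
    """

    patient_id: str
    age: float
    wfns: int
    mfisher: int
    dci: bool
    gose: int
    monitoring_start: float = 0.0
    rebleeding: bool | None = None
    global_edema: bool | None = None
    herniation: bool | None = None
    seizures: bool | None = None
    hydrocephalus: bool | None = None
    vasospasm: bool | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.gose) <= 8:
            raise ValueError(f"gose must be in 1..8, got {self.gose}")
        if not 1 <= int(self.wfns) <= 5:
            raise ValueError(f"wfns must be in 1..5, got {self.wfns}")
        if not 1 <= int(self.mfisher) <= 4:
            raise ValueError(f"mfisher must be in 1..4, got {self.mfisher}")
        self.gose = int(self.gose)
        self.wfns = int(self.wfns)
        self.mfisher = int(self.mfisher)


# ---------------------------------------------------------------------------
# waveform IO


def write_waveform(path, signals) -> None:
    """Write one or more signals to HDF5, one group per channel."""
    if isinstance(signals, WaveformSignal):
        signals = [signals]
    with h5py.File(path, "w") as h5:
        for sig in signals:
            grp = h5.create_group(sig.channel_label)
            grp.create_dataset("samples", data=sig.samples)
            grp.attrs["sampling_rate"] = sig.sampling_rate
            grp.attrs["start_time"] = sig.start_time


def read_waveform(path, channel_label: str) -> WaveformSignal:
    """Read one channel from an HDF5 or ``time,value`` CSV recording.

    The returned signal starts with an all-true validity mask.  For CSV
    input the sampling rate is inferred from the (required uniform) time
    spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        with h5py.File(path, "r") as h5:
            if channel_label not in h5:
                raise ChannelNotFoundError(
                    f"channel {channel_label!r} not in {path.name}"
                )
            grp = h5[channel_label]
            samples = np.asarray(grp["samples"], dtype=float)
            fs = float(grp.attrs["sampling_rate"])
            t0 = float(grp.attrs.get("start_time", 0.0))
        return WaveformSignal(channel_label, fs, t0, samples)
    return _read_waveform_csv(path, channel_label)


def _read_waveform_csv(path, channel_label: str) -> WaveformSignal:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time", "value"]:
        raise FormatError(f"{path}: expected columns time,value")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples to infer rate")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: non-uniform timestamps")
    fs = 1.0 / dt[0]
    return WaveformSignal(channel_label, fs, float(t[0]), df["value"].to_numpy(float))


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path) -> list[AnnotationInterval]:
    """Read manual artifact intervals from a ``channel,start,end,reason`` CSV.

    Returned sorted ascending by start; overlaps are permitted.
    """
    df = pd.read_csv(path)
    required = {"channel", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                AnnotationInterval(
                    str(row["channel"]),
                    float(row["start"]),
                    float(row["end"]),
                    str(row.get("reason", "other")),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} row {i + 2}: {exc}") from exc
    out.sort(key=lambda iv: iv.start)
    return out


def write_annotations(path, intervals) -> None:
    pd.DataFrame(
        [
            {
                "channel": iv.channel_label,
                "start": iv.start,
                "end": iv.end,
                "reason": iv.reason,
            }
            for iv in intervals
        ],
        columns=["channel", "start", "end", "reason"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clinical table

_BOOL_MAP = {
    "0": False, "1": True, "true": True, "false": False,
    "yes": True, "no": False, "": None, "nan": None,
}

_EVENT_FLAGS = (
    "rebleeding", "global_edema", "herniation",
    "seizures", "hydrocephalus", "vasospasm",
)


def _parse_bool(value):
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        if isinstance(value, float) and np.isnan(value):
            return None
        return bool(int(value))
    key = str(value).strip().lower()
    if key not in _BOOL_MAP:
        raise ValueError(f"cannot parse boolean from {value!r}")
    return _BOOL_MAP[key]


def read_clinical_table(path) -> list[PatientRecord]:
    """Read and validate per-patient covariates and outcome.

    Invalid rows raise ``FormatError`` naming the offending field and the
    1-based data row number.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "age", "wfns", "mfisher", "dci", "gose"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        kwargs = dict(
            patient_id=str(row["patient_id"]),
            age=float(row["age"]),
            wfns=int(row["wfns"]),
            mfisher=int(row["mfisher"]),
            dci=bool(_parse_bool(row["dci"])),
            gose=int(row["gose"]),
        )
        if "monitoring_start" in df.columns and pd.notna(row["monitoring_start"]):
            kwargs["monitoring_start"] = float(row["monitoring_start"])
        for flag in _EVENT_FLAGS:
            if flag in df.columns:
                kwargs[flag] = _parse_bool(row[flag])
        try:
            records.append(PatientRecord(**kwargs))
        except ValueError as exc:
            raise FormatError(f"{path} row {i + 2}: {exc}") from exc
    return records


def write_clinical_table(path, records) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def clinical_frame(records) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by patient_id."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("patient_id")
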