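"""Derive the seven 10-s channels used for entropy analysis.

Cleaned waveforms are reduced onto one shared 10-s grid per patient:

====  =======================================================================
ABP   mean arterial pressure (10-s mean of the ABP waveform)
SBP   systolic pressure: mean of per-beat maxima within the window
DBP   diastolic pressure: mean of per-beat minima within the window
ICP   mean intracranial pressure
AMP   ICP cardiac pulse amplitude (spectral peak-to-peak, mmHg)
CPP   cerebral perfusion pressure, ABP - ICP
HR    heart rate (10-s mean of the HR channel, or 60 x the ABP cardiac
      fundamental frequency when no HR channel was recorded)
====  =======================================================================

Averaging over 10 s removes cardiac and respiratory components, leaving the
slow-wave dynamics that the multiscale entropy analysis targets.  A window
is valid only if at least half of its samples survived cleaning; windows
that fail any derivation are marked invalid (NaN), and the resulting gap
structure is preserved for downstream use — entropy never bridges gaps
silently.

Beats for SBP/DBP are delimited deterministically by the cardiac fundamental
period estimated from the window's spectrum, rather than by peak detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleaning import _cardiac_peak
from .io import WaveformSignal

TEN_SECOND_CHANNELS = ("ABP", "SBP", "DBP", "ICP", "AMP", "CPP", "HR")
WINDOW_S = 10.0


@dataclass
class TenSecondSeries:
    """Per-patient grid of 10-s derived channels with gap structure.

    ``channels`` maps channel name to an array aligned with
    ``window_start_times``; invalid windows are NaN.
    """

    patient_id: str
    window_start_times: np.ndarray
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.window_start_times = np.asarray(self.window_start_times, dtype=float)
        if len(self.window_start_times) > 1:
            dt = np.diff(self.window_start_times)
            if not np.allclose(dt, WINDOW_S):
                raise ValueError("window grid spacing must be exactly 10 s")
        for name, values in self.channels.items():
            values = np.asarray(values, dtype=float)
            if values.shape != self.window_start_times.shape:
                raise ValueError(f"channel {name} length mismatch")
            self.channels[name] = values

    @property
    def n_windows(self) -> int:
        return len(self.window_start_times)

    def valid_mask(self, channel: str) -> np.ndarray:
        return ~np.isnan(self.channels[channel])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.window_start_times})
        for name in TEN_SECOND_CHANNELS:
            if name in self.channels:
                df[name] = self.channels[name]
        return df

    @classmethod
    def from_frame(cls, patient_id: str, df: pd.DataFrame) -> "TenSecondSeries":
        channels = {
            c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time"
        }
        return cls(patient_id, df["time"].to_numpy(dtype=float), channels)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="")

    @classmethod
    def read_csv(cls, patient_id: str, path) -> "TenSecondSeries":
        return cls.from_frame(patient_id, pd.read_csv(path))


def make_grid(signal: WaveformSignal) -> np.ndarray:
    """10-s window start times covering the whole recording."""
    n_windows = int(len(signal) / (WINDOW_S * signal.sampling_rate))
    return signal.start_time + WINDOW_S * np.arange(n_windows)


def _iter_windows(signal: WaveformSignal, grid: np.ndarray):
    step = int(round(WINDOW_S * signal.sampling_rate))
    for k, t in enumerate(grid):
        i0 = int(round((t - signal.start_time) * signal.sampling_rate))
        if i0 < 0 or i0 + step > len(signal):
            yield k, None, None
            continue
        sl = slice(i0, i0 + step)
        yield k, signal.samples[sl], signal.valid[sl]


def window_mean(signal: WaveformSignal, grid: np.ndarray, min_valid_fraction: float = 0.5) -> np.ndarray:
    """Per-window mean over valid samples; NaN when under half the window is valid."""
    out = np.full(len(grid), np.nan)
    for k, x, v in _iter_windows(signal, grid):
        if x is None or v.mean() < min_valid_fraction:
            continue
        out[k] = x[v].mean()
    return out


def _fully_valid_window(x, v, min_valid_fraction):
    # spectral estimators need contiguous data; require the whole window
    return x is not None and v.all()


def window_sbp_dbp(abp: WaveformSignal, grid: np.ndarray, cardiac_band=(0.67, 3.0),
                   min_valid_fraction: float = 0.5):
    """Systolic/diastolic pressure per window via spectral beat segmentation.

    The cardiac fundamental frequency is estimated from the window's
    spectrum; the window is cut into whole beats of that period, and SBP
    (DBP) is the mean of per-beat maxima (minima).  Windows with no cardiac
    peak, or with any invalid sample, are NaN.
    """
    fs = abp.sampling_rate
    sbp = np.full(len(grid), np.nan)
    dbp = np.full(len(grid), np.nan)
    for k, x, v in _iter_windows(abp, grid):
        if not _fully_valid_window(x, v, min_valid_fraction):
            continue
        amp, f0 = _cardiac_peak(x, fs, cardiac_band)
        if not np.isfinite(f0) or amp <= 0:
            continue
        beat_len = int(round(fs / f0))
        n_beats = len(x) // beat_len
        if n_beats < 1:
            continue
        beats = x[: n_beats * beat_len].reshape(n_beats, beat_len)
        sbp[k] = beats.max(axis=1).mean()
        dbp[k] = beats.min(axis=1).mean()
    return sbp, dbp


def window_amp(icp: WaveformSignal, grid: np.ndarray, cardiac_band=(0.67, 3.0),
               min_valid_fraction: float = 0.5) -> np.ndarray:
    """ICP cardiac pulse amplitude per window (spectral peak-to-peak, mmHg)."""
    fs = icp.sampling_rate
    out = np.full(len(grid), np.nan)
    for k, x, v in _iter_windows(icp, grid):
        if not _fully_valid_window(x, v, min_valid_fraction):
            continue
        amp, f0 = _cardiac_peak(x, fs, cardiac_band)
        if np.isfinite(f0):
            out[k] = amp
    return out


def window_hr(hr_signal: WaveformSignal | None, abp_signal: WaveformSignal | None,
              grid: np.ndarray, cardiac_band=(0.67, 3.0),
              min_valid_fraction: float = 0.5) -> np.ndarray:
    """Heart rate per window in bpm.

    A recorded HR channel takes precedence; otherwise the rate is 60 times
    the cardiac fundamental frequency of the ABP waveform.
    """
    if hr_signal is not None:
        return window_mean(hr_signal, grid, min_valid_fraction)
    if abp_signal is None:
        return np.full(len(grid), np.nan)
    fs = abp_signal.sampling_rate
    out = np.full(len(grid), np.nan)
    for k, x, v in _iter_windows(abp_signal, grid):
        if not _fully_valid_window(x, v, min_valid_fraction):
            continue
        _, f0 = _cardiac_peak(x, fs, cardiac_band)
        if np.isfinite(f0):
            out[k] = 60.0 * f0
    return out


def derive_cpp(abp_means: np.ndarray, icp_means: np.ndarray) -> np.ndarray:
    """CPP = ABP - ICP where both are valid; NaN elsewhere."""
    return np.asarray(abp_means, float) - np.asarray(icp_means, float)


def summarize_patient(patient_id: str, abp: WaveformSignal | None = None,
                      icp: WaveformSignal | None = None,
                      hr: WaveformSignal | None = None,
                      cardiac_band=(0.67, 3.0),
                      min_valid_fraction: float = 0.5) -> TenSecondSeries:
    """Build the full seven-channel 10-s series for one patient.

    Channels whose source waveform is absent (commonly ICP, monitored in
    only part of the cohort) are simply omitted, so downstream analyses run
    available-case per metric.
    """
    anchor = abp or icp or hr
    if anchor is None:
        raise ValueError("at least one waveform is required")
    grid = make_grid(anchor)
    channels: dict[str, np.ndarray] = {}
    if abp is not None:
        channels["ABP"] = window_mean(abp, grid, min_valid_fraction)
        channels["SBP"], channels["DBP"] = window_sbp_dbp(
            abp, grid, cardiac_band, min_valid_fraction
        )
    if icp is not None:
        channels["ICP"] = window_mean(icp, grid, min_valid_fraction)
        channels["AMP"] = window_amp(icp, grid, cardiac_band, min_valid_fraction)
    if abp is not None and icp is not None:
        channels["CPP"] = derive_cpp(channels["ABP"], channels["ICP"])
    hr_vals = window_hr(hr, abp, grid, cardiac_band, min_valid_fraction)
    if not np.all(np.isnan(hr_vals)):
        channels["HR"] = hr_vals
    return TenSecondSeries(patient_id, grid, channels)
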