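"""Rule-based artifact rejection for arterial and intracranial pressure.

Cleaning applies, in order: manual annotation intervals, per-sample range
rules, then windowed spectral rules on non-overlapping 10-s sections aligned
to the recording start.  Windowed rules are evaluated only on sections that
are still at least half valid, so spectral estimates never run on gap-ridden
data.  Cleaning is monotone (it only invalidates samples) and therefore
idempotent.

The per-channel rules mirror standard neuromonitoring practice:

* ABP — samples below 0 or above 300 mmHg removed; 10-s sections whose
  cardiac pulse amplitude falls below 15 mmHg removed (damped arterial line).
* ICP — samples below -20 or above 200 mmHg removed; sections with cardiac
  pulse amplitude below 0.04 mmHg removed (disconnected or open drain); and
  sections whose 95% spectral edge frequency exceeds 10 Hz removed
  (broadband high-frequency noise).

Pulse amplitude is estimated spectrally as the peak-to-peak amplitude of the
largest Fourier component in the cardiac band (0.67-3 Hz, i.e. 40-180 bpm),
which is deterministic and robust against missing beat detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationInterval, WaveformSignal


@dataclass
class CleaningConfig:
    window_s: float = 10.0
    abp_min: float = 0.0
    abp_max: float = 300.0
    abp_min_pulse_amp: float = 15.0
    icp_min: float = -20.0
    icp_max: float = 200.0
    icp_min_amp: float = 0.04
    icp_sef_limit: float = 10.0
    sef_fraction: float = 0.95
    cardiac_band: tuple[float, float] = (0.67, 3.0)
    min_window_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.abp_min < self.abp_max:
            raise ValueError("abp_min must be below abp_max")
        if not self.icp_min < self.icp_max:
            raise ValueError("icp_min must be below icp_max")
        if not 0.0 < self.sef_fraction < 1.0:
            raise ValueError("sef_fraction must lie in (0, 1)")
        lo, hi = self.cardiac_band
        if not 0.0 < lo < hi:
            raise ValueError("cardiac_band must be an increasing positive pair")


@dataclass
class CleaningReport:
    """Per-rule bookkeeping of how many samples each rule invalidated.

    ``removed_per_rule`` counts samples *newly* invalidated by each rule in
    application order, so the counts sum with the retained samples to the
    total length.
    """

    channel_label: str
    n_samples: int
    removed_per_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed_per_rule.values())

    @property
    def retained_fraction(self) -> float:
        if self.n_samples == 0:
            return 1.0
        return 1.0 - self.n_removed / self.n_samples


def apply_annotations(signal: WaveformSignal, intervals) -> WaveformSignal:
    """Invalidate every sample whose time lies in any half-open interval.

    Intervals for other channels or outside the recording are ignored.
    Returns a new signal; the input is not modified.
    """
    out = signal.copy()
    n = len(out)
    fs = out.sampling_rate
    for iv in intervals:
        if iv.channel_label != signal.channel_label:
            continue
        # sample i is at start_time + i/fs; half-open [start, end)
        i0 = int(np.ceil((iv.start - out.start_time) * fs - 1e-9))
        i1 = int(np.ceil((iv.end - out.start_time) * fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, n)
        if i0 < i1:
            out.valid[i0:i1] = False
    return out


def _cardiac_peak(window: np.ndarray, fs: float, band) -> tuple[float, float]:
    """(peak-to-peak amplitude, frequency) of the strongest in-band component."""
    n = len(window)
    x = window - window.mean()
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        return 0.0, np.nan
    mags = np.abs(spec[in_band])
    k = int(np.argmax(mags))
    # one-sided amplitude of a sinusoid is 2|X_k|/n; peak-to-peak doubles it
    amplitude = 2.0 * mags[k] / n
    return 2.0 * amplitude, float(freqs[in_band][k])


def pulse_amplitude(window: np.ndarray, sampling_rate: float, cardiac_band=(0.67, 3.0)) -> float:
    """Peak-to-peak amplitude (mmHg) of the cardiac fundamental in a window."""
    return _cardiac_peak(np.asarray(window, float), sampling_rate, cardiac_band)[0]


def cardiac_frequency(window: np.ndarray, sampling_rate: float, cardiac_band=(0.67, 3.0)) -> float:
    """Frequency (Hz) of the strongest spectral component in the cardiac band."""
    return _cardiac_peak(np.asarray(window, float), sampling_rate, cardiac_band)[1]


def spectral_edge_frequency(window: np.ndarray, sampling_rate: float, fraction: float = 0.95) -> float:
    """Smallest frequency below which ``fraction`` of the window's power lies.

    Computed from a single periodogram of the detrended window with the DC
    bin excluded.  Returns NaN for an (after detrending) all-zero window.
    """
    x = np.asarray(window, dtype=float)
    x = x - x.mean()
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2
    spec[0] = 0.0
    total = spec.sum()
    if total <= 0:
        return np.nan
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    cum = np.cumsum(spec)
    idx = int(np.searchsorted(cum, fraction * total))
    return float(freqs[min(idx, len(freqs) - 1)])


def _window_slices(n: int, fs: float, window_s: float):
    step = int(round(window_s * fs))
    for start in range(0, n - step + 1, step):
        yield slice(start, start + step)


def _apply_range_rule(signal, lo, hi, report, rule_name):
    bad = (signal.samples < lo) | (signal.samples > hi)
    newly = bad & signal.valid
    report.removed_per_rule[rule_name] = int(newly.sum())
    signal.valid[newly] = False


def _apply_window_rule(signal, config, predicate, report, rule_name):
    """Invalidate whole 10-s sections where ``predicate(window)`` is true.

    Sections less than half valid are skipped: their spectral content is
    not trustworthy and their samples are mostly gone already.
    """
    removed = 0
    for sl in _window_slices(len(signal), signal.sampling_rate, config.window_s):
        v = signal.valid[sl]
        if v.mean() < config.min_window_valid_fraction:
            continue
        if predicate(signal.samples[sl]):
            removed += int(v.sum())
            signal.valid[sl] = False
    report.removed_per_rule[rule_name] = removed


def clean_abp(signal: WaveformSignal, config: CleaningConfig | None = None):
    """Apply the arterial-pressure artifact rules; returns (signal, report)."""
    config = config or CleaningConfig()
    if signal.channel_label != "ABP":
        raise ValueError(f"clean_abp expects ABP, got {signal.channel_label}")
    out = signal.copy()
    report = CleaningReport("ABP", len(out))
    _apply_range_rule(out, config.abp_min, config.abp_max, report, "range")
    fs = out.sampling_rate

    def damped(w):
        return pulse_amplitude(w, fs, config.cardiac_band) < config.abp_min_pulse_amp

    _apply_window_rule(out, config, damped, report, "pulse_amplitude")
    return out, report


def clean_icp(signal: WaveformSignal, config: CleaningConfig | None = None):
    """Apply the intracranial-pressure artifact rules; returns (signal, report)."""
    config = config or CleaningConfig()
    if signal.channel_label != "ICP":
        raise ValueError(f"clean_icp expects ICP, got {signal.channel_label}")
    out = signal.copy()
    report = CleaningReport("ICP", len(out))
    _apply_range_rule(out, config.icp_min, config.icp_max, report, "range")
    fs = out.sampling_rate

    def low_amp(w):
        return pulse_amplitude(w, fs, config.cardiac_band) < config.icp_min_amp

    _apply_window_rule(out, config, low_amp, report, "low_amplitude")

    def hf_noise(w):
        sef = spectral_edge_frequency(w, fs, config.sef_fraction)
        return bool(np.isnan(sef)) or sef > config.icp_sef_limit

    _apply_window_rule(out, config, hf_noise, report, "sef")
    return out, report


def clean_signal(signal: WaveformSignal, config: CleaningConfig | None = None, annotations=()):
    """Annotations, then the channel's automated rules; HR gets annotations only."""
    config = config or CleaningConfig()
    out = apply_annotations(signal, annotations)
    n_annot = int((~out.valid & signal.valid).sum())
    if signal.channel_label == "ABP":
        out, report = clean_abp(out, config)
    elif signal.channel_label == "ICP":
        out, report = clean_icp(out, config)
    else:
        report = CleaningReport(signal.channel_label, len(signal))
    report.removed_per_rule = {"annotation": n_annot, **report.removed_per_rule}
    return out, report


def report_frame(reports):
    """CleaningReports as a tidy (channel, rule, samples_removed) table."""
    import pandas as pd

    rows = []
    for rep in reports:
        for rule, count in rep.removed_per_rule.items():
            rows.append(
                {"channel": rep.channel_label, "rule": rule, "samples_removed": count}
            )
    return pd.DataFrame(rows, columns=["channel", "rule", "samples_removed"])
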