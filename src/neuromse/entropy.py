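"""Sample entropy and multiscale entropy (MSE) on gapped 10-s series.

Sample entropy (SampEn) is the negative natural logarithm of the conditional
probability that two sequences matching for ``m`` consecutive points (within
tolerance ``r``, Chebyshev distance, self-matches excluded) still match when
extended by one point:

    SampEn(m, r) = -ln(A / B)

where ``B`` counts template pairs of length ``m`` that match and ``A`` counts
those that also match at length ``m + 1``.  Templates are indexed over
``1 .. n - m`` for both counts, so ``A <= B`` holds by construction and a
constant series has SampEn exactly 0.

Multiscale entropy computes SampEn over coarse-grained versions of the
series: scale tau replaces the series by non-overlapping tau-point block
averages ("step 1 — no averaging, step 2 — averaging of 2 consecutive
samples", and so on).  Scales 1..20 of a 10-s grid span 10 s to 200 s and
thereby cover the slow-wave band.  The scalar MSE metric is the trapezoidal
area under the entropy-versus-scale curve; higher values mean higher signal
complexity.

Gap handling: cleaned 10-s series contain invalid windows.  Contiguous valid
runs are treated as separate segments; templates never span a gap, matching
pairs are counted within segments only, and the counts are pooled across
segments before taking the logarithm.  The tolerance ``r`` is fixed once per
channel from the scale-1 data (default 0.15 x its standard deviation) and
reused at every scale, which makes the metric exactly invariant under affine
rescaling of the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

try:  # optional JIT acceleration; the numpy path computes identical counts
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class EntropyConfig:
    """Parameters of the multiscale entropy estimator.

    ``min_segment_windows`` drops contiguous runs shorter than one hour at
    the default 10-s grid spacing times 60 windows = 10 minutes; shorter
    runs contribute too few templates at deep scales to be informative.
    """

    m: int = 2
    r_factor: float = 0.15
    r_mode: str = "relative_sd"  # or "absolute"
    scales: tuple[int, ...] = tuple(range(1, 21))
    min_segment_windows: int = 60

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("tolerance factor must be positive")
        if self.r_mode not in {"relative_sd", "absolute"}:
            raise ValueError(f"unknown r_mode {self.r_mode!r}")
        scales = tuple(int(s) for s in self.scales)
        if not scales or scales[0] < 1 or any(
            b <= a for a, b in zip(scales, scales[1:])
        ):
            raise ValueError("scales must be strictly increasing, minimum 1")
        self.scales = scales


@dataclass(frozen=True)
class SampleEntropyCounts:
    """Matching-pair tallies behind one SampEn value."""

    A: int  # pairs matching at length m + 1
    B: int  # pairs matching at length m
    n_templates: int

    def __post_init__(self) -> None:
        if not 0 <= self.A <= self.B:
            raise ValueError("counts must satisfy 0 <= A <= B")


@dataclass
class MseResult:
    """Entropy-vs-scale curve for one channel plus its area summary."""

    channel: str
    scales: tuple[int, ...]
    values: np.ndarray  # NaN where undefined
    auc: float  # NaN unless every scale is defined
    n_windows_used: int
    r_used: float
    counts: dict[int, SampleEntropyCounts] = field(default_factory=dict)


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block averages of length ``tau``; remainder dropped."""
    x = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau == 1:
        return x.copy()
    n_blocks = len(x) // tau
    if n_blocks == 0:
        return np.empty(0)
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def _pair_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Chunked vectorised pair counting; exact integer counts."""
    n = len(x)
    n_templates = n - m
    if n_templates < 2:
        return 0, 0
    A = 0
    B = 0
    block = max(1, min(n_templates, 8_000_000 // max(n_templates, 1) + 1))
    for i0 in range(0, n_templates - 1, block):
        i1 = min(i0 + block, n_templates - 1)
        rows = np.arange(i0, i1)
        match_m = np.ones((len(rows), n_templates), dtype=bool)
        for k in range(m):
            match_m &= (
                np.abs(x[rows[:, None] + k] - x[None, k : n_templates + k]) <= r
            )
        # strictly upper-triangular part only (i < j, no self-matches)
        tri = rows[:, None] < np.arange(n_templates)[None, :]
        match_m &= tri
        B += int(match_m.sum())
        match_m &= (
            np.abs(x[rows[:, None] + m] - x[None, m : n_templates + m]) <= r
        )
        A += int(match_m.sum())
    return A, B


if _HAVE_NUMBA:

    @_njit(cache=True)
    def _pair_counts_jit(x, m, r):  # pragma: no cover - exercised via wrapper
        n = x.shape[0]
        n_templates = n - m
        A = 0
        B = 0
        for i in range(n_templates - 1):
            for j in range(i + 1, n_templates):
                ok = True
                for k in range(m):
                    if abs(x[i + k] - x[j + k]) > r:
                        ok = False
                        break
                if ok:
                    B += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        A += 1
        return A, B


def _pair_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    x = np.ascontiguousarray(x, dtype=np.float64)
    if _HAVE_NUMBA:
        return _pair_counts_jit(x, m, r)
    return _pair_counts_numpy(x, m, r)


def sample_entropy(segments, m: int = 2, r: float = 0.15):
    """Pooled-count sample entropy over contiguous gap-free segments.

    Pairs are counted within each segment (templates never span a gap) and
    the A/B tallies are pooled across segments before the logarithm, which
    keeps short segments from biasing the estimate the way averaging
    per-segment entropies would.

    Returns ``(sampen, SampleEntropyCounts)``; ``sampen`` is NaN when either
    count is zero.
    """
    if isinstance(segments, np.ndarray) and segments.ndim == 1:
        segments = [segments]
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    A = 0
    B = 0
    n_templates = 0
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if len(seg) < m + 1:
            continue
        a, b = _pair_counts(seg, m, r)
        A += a
        B += b
        n_templates += len(seg) - m
    counts = SampleEntropyCounts(A, B, n_templates)
    if A == 0 or B == 0:
        return np.nan, counts
    return float(-np.log(A / B)), counts


def valid_segments(values: np.ndarray, min_length: int = 1):
    """Contiguous non-NaN runs of at least ``min_length``, in order."""
    x = np.asarray(values, dtype=float)
    isvalid = np.isfinite(x)
    segments = []
    start = None
    for i, ok in enumerate(isvalid):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_length:
                segments.append(x[start:i])
            start = None
    if start is not None and len(x) - start >= min_length:
        segments.append(x[start:])
    return segments


def tolerance_r(segments, config: EntropyConfig) -> float:
    """Matching tolerance fixed from the scale-1 data (one r for all scales)."""
    if config.r_mode == "absolute":
        return config.r_factor
    pooled = np.concatenate(segments) if segments else np.empty(0)
    if len(pooled) < 2:
        return np.nan
    return config.r_factor * float(pooled.std())


def mse_curve(values: np.ndarray, config: EntropyConfig | None = None,
              channel: str = "", ) -> MseResult:
    """Multiscale entropy curve of one gapped 10-s channel.

    Each retained segment is coarse-grained per scale before pooled-count
    sample entropy; the tolerance is fixed from the scale-1 series.  The
    area summary is reported only when every scale is defined.
    """
    config = config or EntropyConfig()
    segments = valid_segments(values, config.min_segment_windows)
    n_used = int(sum(len(s) for s in segments))
    r = tolerance_r(segments, config)
    curve = np.full(len(config.scales), np.nan)
    counts: dict[int, SampleEntropyCounts] = {}
    if segments and np.isfinite(r) and r > 0:
        for idx, tau in enumerate(config.scales):
            grained = [coarse_grain(s, tau) for s in segments]
            value, c = sample_entropy(grained, config.m, r)
            curve[idx] = value
            counts[tau] = c
    else:
        logger.info("channel %s: no usable segments for entropy", channel or "?")
    auc = mse_auc(curve, config.scales)
    return MseResult(channel, config.scales, curve, auc, n_used, r, counts)


def mse_auc(curve: np.ndarray, scales=None) -> float:
    """Trapezoidal area under the entropy-vs-scale curve (unit scale spacing).

    NaN if any scale value is missing.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0 or np.any(~np.isfinite(curve)):
        return np.nan
    x = np.asarray(scales, dtype=float) if scales is not None else np.arange(
        1, len(curve) + 1, dtype=float
    )
    return float(np.trapezoid(curve, x))


def mse_stability(values: np.ndarray, durations_h, config: EntropyConfig | None = None,
                  channel: str = "") -> dict[float, MseResult]:
    """MSE on leading prefixes of increasing duration (hours).

    A 10-s grid has 360 windows per hour.  Prefixes shorter than the
    configured minimum segment length come back with NaN area; callers can
    report convergence as the absolute difference from the longest-duration
    value.
    """
    config = config or EntropyConfig()
    values = np.asarray(values, dtype=float)
    out: dict[float, MseResult] = {}
    for d in durations_h:
        n = int(round(d * 360))
        prefix = values[: min(n, len(values))]
        res = mse_curve(prefix, config, channel)
        if not np.isfinite(res.auc):
            logger.info(
                "channel %s: duration %.1f h yields no defined MSE", channel or "?", d
            )
        out[float(d)] = res
    return out
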