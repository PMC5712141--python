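"""Threshold-based detection of balance-assistance events from sacral acceleration.

The detector works on the Euclidean norm of the 3-axis accelerometer signal
(orientation independent).  The record mean is subtracted (removing gravity,
leaving free acceleration), stationary head/tail periods are trimmed, the
signal is smoothed with a centered moving average of width ``delta_s`` and
every smoothed sample strictly above the upper Tukey fence
``Q3 + alpha * IQR`` is marked; contiguous marked runs form detected
intervals.  Quartiles are taken from the trimmed, pre-smoothing signal by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gaitassist.timeseries_io import SessionRecording, SignalTrack

__all__ = [
    "DetectionResult",
    "DetectorParams",
    "detect",
    "free_acceleration",
    "mark_outliers",
    "moving_average",
    "resultant_acceleration",
    "trim_stationary",
    "tukey_threshold",
]


@dataclass(frozen=True)
class DetectorParams:
    """Fence height factor ``alpha`` and moving-average width ``delta_s`` (s)."""

    alpha: float = 1.0
    delta_s: float = 2.5

    def __post_init__(self) -> None:
        if not self.alpha >= 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha!r}")
        if not self.delta_s > 0:
            raise ValueError(f"delta_s must be > 0, got {self.delta_s!r}")


@dataclass(frozen=True)
class DetectionResult:
    """Detected outlier intervals plus the settings that produced them."""

    intervals: tuple[tuple[float, float], ...]
    threshold: float
    params: DetectorParams
    quartiles: tuple[float, float, float]  # (Q1, Q3, IQR)
    kept_interval: tuple[float, float]

    @property
    def n_detections(self) -> int:
        return len(self.intervals)


def resultant_acceleration(
    ax: SignalTrack, ay: SignalTrack, az: SignalTrack
) -> SignalTrack:
    """Per-sample Euclidean norm of the three axes (orientation independent)."""
    if not (ax.fs == ay.fs == az.fs and ax.n == ay.n == az.n and ax.t0 == ay.t0 == az.t0):
        raise ValueError("axis tracks must share fs, length and t0")
    norm = np.sqrt(ax.samples**2 + ay.samples**2 + az.samples**2)
    return ax.with_samples(norm)


def free_acceleration(resultant: SignalTrack) -> SignalTrack:
    """Subtract the record mean, removing the gravitational component."""
    return resultant.with_samples(resultant.samples - float(np.mean(resultant.samples)))


def _rolling_std(x: np.ndarray, w: int) -> np.ndarray:
    """Population std over a centered window of w samples, shrunk at the edges."""
    n = x.size
    half = w // 2
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    cnt = (hi - lo).astype(float)
    mean = (c1[hi] - c1[lo]) / cnt
    var = (c2[hi] - c2[lo]) / cnt - mean**2
    return np.sqrt(np.maximum(var, 0.0))


def trim_stationary(
    track: SignalTrack,
    manual: tuple[float, float] | None = None,
    *,
    window_s: float = 1.0,
    activity_fraction: float = 0.10,
) -> tuple[SignalTrack, tuple[float, float]]:
    """Cut off stationary periods before and after the movement.

    With ``manual`` bounds (seconds), exactly those samples are kept.
    Otherwise the leading/trailing region where the rolling standard
    deviation (centered ``window_s`` window) stays below
    ``activity_fraction`` of the whole-record standard deviation is
    dropped; interior samples are never removed.

    Returns the trimmed track and the kept ``(start_s, stop_s)`` interval.
    """
    if manual is not None:
        start_s, stop_s = manual
        if start_s < track.t0 or stop_s > track.t_end or stop_s < start_s:
            raise ValueError(
                f"manual bounds [{start_s}, {stop_s}] s outside track "
                f"[{track.t0}, {track.t_end}] s"
            )
        trimmed = track.slice_seconds(start_s, stop_s)
        return trimmed, (trimmed.t0, trimmed.t_end)

    w = max(int(round(window_s * track.fs)), 1)
    rstd = _rolling_std(track.samples, w)
    active = rstd >= activity_fraction * float(np.std(track.samples))
    idx = np.flatnonzero(active)
    if idx.size == 0:  # nothing qualifies as movement; keep everything
        return track, (track.t0, track.t_end)
    i0, i1 = int(idx[0]), int(idx[-1])
    trimmed = SignalTrack(track.samples[i0 : i1 + 1], track.fs, track.t0 + i0 / track.fs)
    return trimmed, (trimmed.t0, trimmed.t_end)


def window_samples(delta_s: float, fs: float) -> int:
    """Moving-average width in samples: round(delta_s * fs), forced odd."""
    w = int(round(delta_s * fs))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    return w


def moving_average(track: SignalTrack, delta_s: float) -> SignalTrack:
    """Centered moving average of width ``delta_s`` seconds.

    The window shrinks at the record edges so output length equals input
    length.
    """
    if not delta_s > 0:
        raise ValueError("delta_s must be > 0")
    w = window_samples(delta_s, track.fs)
    n = track.n
    if w > n:
        raise ValueError(f"window of {w} samples longer than record of {n} samples")
    half = w // 2
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    csum = np.concatenate(([0.0], np.cumsum(track.samples)))
    return track.with_samples((csum[hi] - csum[lo]) / (hi - lo))


def _tukey_hinges(x: np.ndarray) -> tuple[float, float]:
    """Tukey hinges: medians of the lower/upper halves (median included when n odd)."""
    s = np.sort(x)
    n = s.size
    half = (n + 1) // 2
    return float(np.median(s[:half])), float(np.median(s[n - half :]))


def tukey_threshold(
    track: SignalTrack, alpha: float, *, quantile_method: str = "linear"
) -> tuple[float, float, float, float]:
    """Upper fence ``Q3 + alpha * IQR``; returns (threshold, Q1, Q3, IQR).

    ``quantile_method`` is ``"linear"`` (interpolation between closest
    ranks) or ``"hinges"`` (Tukey hinges).
    """
    x = track.samples
    if quantile_method == "linear":
        q1, q3 = (float(q) for q in np.quantile(x, [0.25, 0.75]))
    elif quantile_method == "hinges":
        q1, q3 = _tukey_hinges(x)
    else:
        raise ValueError(f"unknown quantile_method {quantile_method!r}")
    iqr = q3 - q1
    return q3 + alpha * iqr, q1, q3, iqr


def mark_outliers(
    smoothed: SignalTrack, threshold: float
) -> tuple[tuple[float, float], ...]:
    """Intervals where the smoothed signal is strictly above the threshold.

    Contiguous supra-threshold runs merge into one interval spanning from
    the first marked sample to one sample period past the last (so even a
    single-sample run has positive width).
    """
    mask = smoothed.samples > threshold
    if not mask.any():
        return ()
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size - 1]))
    fs, t0 = smoothed.fs, smoothed.t0
    return tuple(
        (float(t0 + i / fs), float(t0 + (j + 1) / fs)) for i, j in zip(starts, ends)
    )


def detect(
    recording,
    params: DetectorParams,
    *,
    trim_manual: tuple[float, float] | None = None,
    trim_window_s: float = 1.0,
    trim_activity_fraction: float = 0.10,
    quantile_method: str = "linear",
    quartiles_on: str = "pre_smoothing",
    rectify: bool = False,
) -> DetectionResult:
    """Run the full detection pipeline on a 3-axis accelerometer stream.

    ``recording`` is a :class:`SessionRecording` or a 3-tuple of axis
    :class:`SignalTrack` objects.  ``quartiles_on`` selects whether the
    fence quartiles come from the trimmed signal before (default) or after
    moving-average smoothing; ``rectify`` smooths ``|signal|`` instead of
    the signed free acceleration.
    """
    if isinstance(recording, SessionRecording):
        tracks = recording.accel_tracks
    else:
        tracks = tuple(recording)
    base = _prepare_base(
        tracks,
        trim_manual=trim_manual,
        trim_window_s=trim_window_s,
        trim_activity_fraction=trim_activity_fraction,
        rectify=rectify,
    )
    return _detect_prepared(base, params, quantile_method=quantile_method,
                            quartiles_on=quartiles_on)


def _prepare_base(
    tracks,
    *,
    trim_manual=None,
    trim_window_s: float = 1.0,
    trim_activity_fraction: float = 0.10,
    rectify: bool = False,
) -> tuple[SignalTrack, tuple[float, float]]:
    """Parameter-independent pipeline head: norm -> demean -> trim [-> rectify]."""
    resultant = resultant_acceleration(*tracks)
    free = free_acceleration(resultant)
    trimmed, kept = trim_stationary(
        free,
        manual=trim_manual,
        window_s=trim_window_s,
        activity_fraction=trim_activity_fraction,
    )
    if rectify:
        trimmed = trimmed.with_samples(np.abs(trimmed.samples))
    return trimmed, kept


def _detect_prepared(
    base: tuple[SignalTrack, tuple[float, float]],
    params: DetectorParams,
    *,
    quantile_method: str = "linear",
    quartiles_on: str = "pre_smoothing",
) -> DetectionResult:
    trimmed, kept = base
    smoothed = moving_average(trimmed, params.delta_s)
    if quartiles_on == "pre_smoothing":
        source = trimmed
    elif quartiles_on == "post_smoothing":
        source = smoothed
    else:
        raise ValueError(f"unknown quartiles_on {quartiles_on!r}")
    threshold, q1, q3, iqr = tukey_threshold(
        source, params.alpha, quantile_method=quantile_method
    )
    intervals = mark_outliers(smoothed, threshold)
    return DetectionResult(
        intervals=intervals,
        threshold=threshold,
        params=params,
        quartiles=(q1, q3, iqr),
        kept_interval=kept,
    )
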