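"""Characterization of annotated balance-assistance events from force data.

Pipeline per session: zero-phase low-pass filtering of each force channel,
baseline removal over a static window, left-minus-right net force per body
axis, then per-event peak force (absolute value, per axis and in % body
weight), duration and rectified ML impulse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from gaitassist.timeseries_io import (
    AXES,
    AssistAnnotation,
    SessionRecording,
    SignalTrack,
)

__all__ = [
    "EventMetrics",
    "characterize_session",
    "event_metrics",
    "lowpass",
    "remove_baseline",
    "resultant_force",
    "summarize_cohort",
]

STANDARD_GRAVITY = 9.81  # m/s^2, used for % body weight


@dataclass(frozen=True)
class EventMetrics:
    """Force characteristics of one assistance event.

    ``peak_force_n``/``peak_force_pct_bw``/``impulse_ns`` are ``None`` when
    the event hit no force sensor (off-sensor location) and its force
    characteristics could not be captured.
    """

    peak_force_n: dict[str, float] | None
    peak_force_pct_bw: dict[str, float] | None
    duration_s: float
    impulse_ns: float | None
    location: str
    sensors_hit: str

    @property
    def available(self) -> bool:
        return self.peak_force_n is not None


def lowpass(track: SignalTrack, order: int = 2, cutoff_hz: float = 5.0) -> SignalTrack:
    """Butterworth low-pass, applied forward-backward (zero phase lag)."""
    if not 0 < cutoff_hz < track.fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={track.fs / 2} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=track.fs, output="sos")
    return track.with_samples(signal.sosfiltfilt(sos, track.samples))


def remove_baseline(track: SignalTrack, static_interval: tuple[float, float]) -> SignalTrack:
    """Subtract the mean over a static (no-contact) interval from every sample."""
    start_s, stop_s = static_interval
    if stop_s - start_s < 0.1:
        raise ValueError("static interval must span at least 0.1 s")
    if start_s < track.t0 or stop_s > track.t_end:
        raise ValueError(
            f"static interval [{start_s}, {stop_s}] s outside track "
            f"[{track.t0}, {track.t_end}] s"
        )
    baseline = float(np.mean(track.slice_seconds(start_s, stop_s).samples))
    return track.with_samples(track.samples - baseline)


def resultant_force(
    left: Mapping[str, SignalTrack], right: Mapping[str, SignalTrack]
) -> dict[str, SignalTrack]:
    """Net two-hand force per body axis: ``left(t) - right(t)``.

    Both sensors are assumed expressed in a common body frame (positive ML =
    push toward the patient's right), so opposing pushes cancel.
    """
    if set(left) != set(right):
        raise ValueError("left and right must carry the same axes")
    net = {}
    for axis in left:
        l, r = left[axis], right[axis]
        if l.fs != r.fs or l.n != r.n or l.t0 != r.t0:
            raise ValueError(f"axis {axis!r}: left/right tracks differ in fs, length or t0")
        net[axis] = l.with_samples(l.samples - r.samples)
    return net


def event_metrics(
    net: Mapping[str, SignalTrack],
    annotation: AssistAnnotation,
    body_mass_kg: float,
    gravity_mps2: float = STANDARD_GRAVITY,
) -> EventMetrics:
    """Peak force per axis, duration and rectified ML impulse of one event.

    Peaks are absolute values irrespective of push direction; impulse is the
    trapezoidal integral of ``|net_ml|`` over the closed event interval.
    """
    if not body_mass_kg > 0:
        raise ValueError("body_mass_kg must be > 0")
    duration = annotation.stop_s - annotation.start_s
    if annotation.sensors_hit == "none":
        return EventMetrics(
            peak_force_n=None,
            peak_force_pct_bw=None,
            duration_s=duration,
            impulse_ns=None,
            location=annotation.location,
            sensors_hit=annotation.sensors_hit,
        )
    peaks: dict[str, float] = {}
    for axis in AXES:
        segment = net[axis].slice_seconds(annotation.start_s, annotation.stop_s)
        peaks[axis] = float(np.max(np.abs(segment.samples)))
    ml = net["ml"].slice_seconds(annotation.start_s, annotation.stop_s)
    impulse = float(np.trapezoid(np.abs(ml.samples), dx=1.0 / ml.fs))
    bw = body_mass_kg * gravity_mps2
    return EventMetrics(
        peak_force_n=peaks,
        peak_force_pct_bw={axis: peaks[axis] / bw * 100.0 for axis in AXES},
        duration_s=duration,
        impulse_ns=impulse,
        location=annotation.location,
        sensors_hit=annotation.sensors_hit,
    )


def characterize_session(
    rec: SessionRecording,
    annotations: Sequence[AssistAnnotation],
    *,
    filter_order: int = 2,
    cutoff_hz: float = 5.0,
    static_window: tuple[float, float] | None = None,
    gravity_mps2: float = STANDARD_GRAVITY,
) -> pd.DataFrame:
    """Per-event force characteristics for one session, as a table.

    ``static_window`` defaults to the first 0.5 s of the force record (a
    static, no-contact condition precedes each measurement).  Off-sensor
    events produce rows with NaN force columns.
    """
    if not rec.has_force:
        raise ValueError("recording has no force tracks")
    ref = rec.force_left["ml"]
    if static_window is None:
        static_window = (ref.t0, ref.t0 + 0.5)

    def _prep(tracks: Mapping[str, SignalTrack]) -> dict[str, SignalTrack]:
        return {
            axis: remove_baseline(
                lowpass(tr, order=filter_order, cutoff_hz=cutoff_hz), static_window
            )
            for axis, tr in tracks.items()
        }

    net = resultant_force(_prep(rec.force_left), _prep(rec.force_right))
    rows = []
    for ann in annotations:
        m = event_metrics(net, ann, rec.body_mass_kg, gravity_mps2=gravity_mps2)
        row: dict[str, object] = {
            "start_s": ann.start_s,
            "stop_s": ann.stop_s,
            "duration_s": m.duration_s,
            "location": m.location,
            "sensors_hit": m.sensors_hit,
            "impulse_ns": m.impulse_ns if m.available else np.nan,
        }
        for axis in AXES:
            row[f"peak_{axis}_n"] = m.peak_force_n[axis] if m.available else np.nan
            row[f"peak_{axis}_pct_bw"] = (
                m.peak_force_pct_bw[axis] if m.available else np.nan
            )
        rows.append(row)
    columns = (
        ["start_s", "stop_s", "duration_s", "location", "sensors_hit"]
        + [f"peak_{axis}_n" for axis in AXES]
        + [f"peak_{axis}_pct_bw" for axis in AXES]
        + ["impulse_ns"]
    )
    return pd.DataFrame(rows, columns=columns)


def summarize_cohort(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR across patients for each numeric metric column.

    Rows are per-patient aggregates (typically means over that patient's
    events); patients lacking force-sensor events contribute NaN and are
    excluded column-wise.
    """
    numeric = per_patient.select_dtypes(include=[np.number])
    if numeric.dropna(how="all").empty:
        raise ValueError("no patients with available metrics")
    median = numeric.median(skipna=True)
    iqr = numeric.quantile(0.75) - numeric.quantile(0.25)
    return pd.DataFrame({"median": median, "iqr": iqr}).T
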