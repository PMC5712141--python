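"""Domain types, file I/O and cross-system synchronization.

File formats
------------
Signal files are plain CSV with a header row, preceded by an optional block
of ``# key: value`` comment lines carrying session metadata (body mass,
walking-direction axis, companion force file).  Columns are
``t,ax,ay,az`` for the sacral accelerometer plus, optionally,
``flx,fly,flz,frx,fry,frz`` for the left/right pelvis force sensors, all in
SI units.  When the force stream is sampled at a different rate than the
accelerometer it lives in a companion ``<stem>_force.csv`` file with columns
``t,flx,...,frz``.

Annotation files are CSV (``start_s,stop_s,location,sensors_hit``) or a JSON
array of objects with the same keys.

Time convention: continuous seconds with ``t = 0`` at the synchronization
instant; event intervals are closed ``[start, stop]``.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AXES",
    "LOCATIONS",
    "SENSORS_HIT",
    "AnnotationFormatError",
    "AssistAnnotation",
    "ChannelSchema",
    "MissingChannelError",
    "NonUniformTimeError",
    "SessionRecording",
    "SignalFormatError",
    "SignalTrack",
    "SyncPeakNotFoundError",
    "align_and_trim",
    "detect_sync_peak",
    "read_annotations",
    "read_signals",
    "shift_annotations",
    "write_annotations",
    "write_signals",
]

#: body-frame force axes: medio-lateral, anterior-posterior, superior-inferior
AXES = ("ml", "ap", "si")
LOCATIONS = ("iliac_crest", "trunk", "shoulder", "other")
SENSORS_HIT = ("both", "one", "none")

#: relative tolerance on the sampling interval of the CSV time column
TIME_UNIFORMITY_RTOL = 1e-6


class SignalFormatError(ValueError):
    """Malformed signal file."""


class NonUniformTimeError(SignalFormatError):
    """Time column is not uniformly sampled; carries the offending row index."""

    def __init__(self, index: int, dt: float, expected: float):
        self.index = index
        super().__init__(
            f"non-uniform time column at row {index}: dt={dt:g} s, expected {expected:g} s"
        )


class MissingChannelError(SignalFormatError):
    """A required channel column is absent."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"missing required channel column {column!r}")


class SyncPeakNotFoundError(RuntimeError):
    """No synchronization peak above the prominence floor."""


class AnnotationFormatError(ValueError):
    """Malformed annotation record; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"annotation row {row}: {message}")


@dataclass(frozen=True)
class SignalTrack:
    """One uniformly sampled scalar channel.

    The time of sample ``i`` is ``t0 + i / fs``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs!r}")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Time span from the first to the last sample."""
        return (self.n - 1) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, t0: float | None = None) -> "SignalTrack":
        return SignalTrack(samples, self.fs, self.t0 if t0 is None else t0)

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.fs))

    def slice_seconds(self, start_s: float, stop_s: float) -> "SignalTrack":
        """Samples whose times fall in the closed interval [start_s, stop_s]."""
        if stop_s < start_s:
            raise ValueError("stop_s < start_s")
        t = self.times()
        eps = 0.5 / self.fs * 1e-6
        mask = (t >= start_s - eps) & (t <= stop_s + eps)
        if not mask.any():
            raise ValueError(
                f"interval [{start_s}, {stop_s}] s contains no samples of track "
                f"spanning [{self.t0}, {self.t_end}] s"
            )
        i0 = int(np.flatnonzero(mask)[0])
        return SignalTrack(self.samples[mask], self.fs, self.t0 + i0 / self.fs)


@dataclass(frozen=True)
class AssistAnnotation:
    """Ground-truth balance-assistance event."""

    start_s: float
    stop_s: float
    location: str = "iliac_crest"
    sensors_hit: str = "both"

    def __post_init__(self) -> None:
        if not self.start_s >= 0:
            raise ValueError(f"start_s must be >= 0, got {self.start_s!r}")
        if not self.stop_s > self.start_s:
            raise ValueError(
                f"stop_s ({self.stop_s!r}) must be > start_s ({self.start_s!r})"
            )
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}, got {self.location!r}")
        if self.sensors_hit not in SENSORS_HIT:
            raise ValueError(
                f"sensors_hit must be one of {SENSORS_HIT}, got {self.sensors_hit!r}"
            )
        # off-sensor events by definition register on no force sensor
        if (self.sensors_hit == "none") != (self.location != "iliac_crest"):
            raise ValueError(
                "sensors_hit must be 'none' exactly when location != 'iliac_crest' "
                f"(got location={self.location!r}, sensors_hit={self.sensors_hit!r})"
            )

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


ForceTriplet = Mapping[str, SignalTrack]


def _check_triplet(tracks: Mapping[str, SignalTrack], what: str) -> None:
    if set(tracks) != set(AXES):
        raise ValueError(f"{what} must have axes {AXES}, got {sorted(tracks)}")


@dataclass
class SessionRecording:
    """Synchronized sacral accelerometer and pelvis force-sensor streams.

    Accelerometer tracks stay in the sensor frame (the detector is
    orientation independent); force tracks are keyed by body axis
    (``ml``/``ap``/``si``) with positive ML meaning a push toward the
    patient's right.  Accelerometer and force streams may run at different
    sampling rates — evaluation works in seconds.
    """

    accel_x: SignalTrack
    accel_y: SignalTrack
    accel_z: SignalTrack
    force_left: dict[str, SignalTrack] | None = None
    force_right: dict[str, SignalTrack] | None = None
    body_mass_kg: float = 70.0
    walking_direction_axis: str = "x"

    def __post_init__(self) -> None:
        ax, ay, az = self.accel_x, self.accel_y, self.accel_z
        if not (ax.fs == ay.fs == az.fs and ax.n == ay.n == az.n and ax.t0 == ay.t0 == az.t0):
            raise ValueError("accelerometer tracks must share fs, length and t0")
        if (self.force_left is None) != (self.force_right is None):
            raise ValueError("force_left and force_right must both be present or both absent")
        if self.force_left is not None:
            _check_triplet(self.force_left, "force_left")
            _check_triplet(self.force_right, "force_right")
            tracks = list(self.force_left.values()) + list(self.force_right.values())
            ref = tracks[0]
            for tr in tracks[1:]:
                if not (tr.fs == ref.fs and tr.n == ref.n and tr.t0 == ref.t0):
                    raise ValueError("force tracks must share fs, length and t0")
        if not self.body_mass_kg > 0:
            raise ValueError(f"body_mass_kg must be > 0, got {self.body_mass_kg!r}")

    @property
    def accel_tracks(self) -> tuple[SignalTrack, SignalTrack, SignalTrack]:
        return (self.accel_x, self.accel_y, self.accel_z)

    @property
    def has_force(self) -> bool:
        return self.force_left is not None

    @property
    def accel_fs(self) -> float:
        return self.accel_x.fs

    @property
    def force_fs(self) -> float | None:
        return None if self.force_left is None else self.force_left["ml"].fs


@dataclass(frozen=True)
class ChannelSchema:
    """Column naming and sensor-to-body axis mapping for signal CSV files."""

    time: str = "t"
    accel: tuple[str, str, str] = ("ax", "ay", "az")
    force_left: tuple[str, str, str] = ("flx", "fly", "flz")
    force_right: tuple[str, str, str] = ("frx", "fry", "frz")
    #: body axis carried by each sensor axis (x, y, z); the sensor x axis is
    #: aligned with the walking direction, i.e. anterior-posterior
    axis_order: tuple[str, str, str] = ("ap", "ml", "si")


def _parse_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _check_uniform(t: np.ndarray) -> float:
    """Validate constant sampling interval; return it. 1-indexed rows in errors."""
    if t.size < 2:
        raise SignalFormatError("signal file needs at least 2 rows")
    dt = np.diff(t)
    ref = float(np.median(dt))
    if not ref > 0:
        raise SignalFormatError("time column must be strictly increasing")
    bad = np.flatnonzero(np.abs(dt - ref) > TIME_UNIFORMITY_RTOL * ref)
    if bad.size:
        i = int(bad[0])
        raise NonUniformTimeError(index=i + 1, dt=float(dt[i]), expected=ref)
    return ref


def _read_force_frame(
    df: pd.DataFrame, schema: ChannelSchema
) -> tuple[dict[str, SignalTrack], dict[str, SignalTrack]]:
    t = df[schema.time].to_numpy(dtype=float)
    dt = _check_uniform(t)
    fs = 1.0 / dt
    left: dict[str, SignalTrack] = {}
    right: dict[str, SignalTrack] = {}
    for cols, out in ((schema.force_left, left), (schema.force_right, right)):
        for col, axis in zip(cols, schema.axis_order):
            if col not in df.columns:
                raise MissingChannelError(col)
            out[axis] = SignalTrack(df[col].to_numpy(dtype=float), fs, float(t[0]))
    return left, right


def read_signals(path: str | Path, schema: ChannelSchema | None = None) -> SessionRecording:
    """Load a session from CSV (plus an optional companion force file)."""
    schema = schema or ChannelSchema()
    path = Path(path)
    meta = _parse_meta(path)
    df = pd.read_csv(path, comment="#")
    if schema.time not in df.columns:
        raise MissingChannelError(schema.time)
    t = df[schema.time].to_numpy(dtype=float)
    dt = _check_uniform(t)
    fs = 1.0 / dt
    accel = []
    for col in schema.accel:
        if col not in df.columns:
            raise MissingChannelError(col)
        accel.append(SignalTrack(df[col].to_numpy(dtype=float), fs, float(t[0])))

    force_left = force_right = None
    inline = all(c in df.columns for c in schema.force_left + schema.force_right)
    if inline:
        force_left, force_right = _read_force_frame(df, schema)
    else:
        force_path = None
        if "force_file" in meta:
            force_path = path.parent / meta["force_file"]
        else:
            candidate = path.with_name(path.stem + "_force.csv")
            if candidate.exists():
                force_path = candidate
        if force_path is not None:
            fdf = pd.read_csv(force_path, comment="#")
            if schema.time not in fdf.columns:
                raise MissingChannelError(schema.time)
            force_left, force_right = _read_force_frame(fdf, schema)

    return SessionRecording(
        accel_x=accel[0],
        accel_y=accel[1],
        accel_z=accel[2],
        force_left=force_left,
        force_right=force_right,
        body_mass_kg=float(meta.get("body_mass_kg", 70.0)),
        walking_direction_axis=meta.get("walking_direction_axis", "x"),
    )


def _meta_block(rec: SessionRecording, extra: Mapping[str, str] | None = None) -> str:
    lines = [
        f"# body_mass_kg: {rec.body_mass_kg!r}",
        f"# walking_direction_axis: {rec.walking_direction_axis}",
    ]
    for key, value in (extra or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_signals(
    rec: SessionRecording, path: str | Path, schema: ChannelSchema | None = None
) -> Path:
    """Write a session to CSV; ``read_signals`` round-trips it exactly.

    Force streams sampled on the accelerometer grid are written inline;
    otherwise they go to a companion ``<stem>_force.csv`` file referenced
    from the metadata header.
    """
    schema = schema or ChannelSchema()
    path = Path(path)
    accel = rec.accel_tracks
    frame = {schema.time: accel[0].times()}
    for col, tr in zip(schema.accel, accel):
        frame[col] = tr.samples

    inline_force = (
        rec.has_force
        and rec.force_fs == rec.accel_fs
        and rec.force_left["ml"].n == accel[0].n
        and rec.force_left["ml"].t0 == accel[0].t0
    )
    extra: dict[str, str] = {}
    if inline_force:
        for cols, tracks in (
            (schema.force_left, rec.force_left),
            (schema.force_right, rec.force_right),
        ):
            for col, axis in zip(cols, schema.axis_order):
                frame[col] = tracks[axis].samples
    elif rec.has_force:
        force_name = path.stem + "_force.csv"
        extra["force_file"] = force_name
        ftrack = rec.force_left["ml"]
        fframe = {schema.time: ftrack.times()}
        for cols, tracks in (
            (schema.force_left, rec.force_left),
            (schema.force_right, rec.force_right),
        ):
            for col, axis in zip(cols, schema.axis_order):
                fframe[col] = tracks[axis].samples
        with open(path.parent / force_name, "w") as fh:
            pd.DataFrame(fframe).to_csv(fh, index=False)

    with open(path, "w") as fh:
        fh.write(_meta_block(rec, extra))
        pd.DataFrame(frame).to_csv(fh, index=False)
    return path


def detect_sync_peak(
    force_track: SignalTrack,
    search_window_s: float,
    prominence_factor: float = 5.0,
) -> float:
    """Time (s) of the synchronization spike: the absolute-value maximum
    within the initial search window.

    The spike must rise strictly above ``prominence_factor`` times the
    track's median absolute value, otherwise :class:`SyncPeakNotFoundError`
    is raised.
    """
    if not 0 < search_window_s <= force_track.duration_s + 1.0 / force_track.fs:
        raise ValueError("search window must be positive and within the track extent")
    n_win = min(force_track.n, int(round(search_window_s * force_track.fs)) + 1)
    window = np.abs(force_track.samples[:n_win])
    idx = int(np.argmax(window))
    floor = prominence_factor * float(np.median(np.abs(force_track.samples)))
    if not window[idx] > floor:
        raise SyncPeakNotFoundError(
            f"no sync peak: max |F| = {window[idx]:g} N within the first "
            f"{search_window_s:g} s is not above the floor {floor:g} N"
        )
    return force_track.t0 + idx / force_track.fs


def align_and_trim(rec: SessionRecording, sync_s: float) -> SessionRecording:
    """Re-base force tracks so the sync instant maps to ``t = 0``.

    Force samples before the sync instant are discarded; the accelerometer
    stream is untouched (its recording was triggered at the sync instant).
    """
    if not rec.has_force:
        return rec
    ref = rec.force_left["ml"]
    if not ref.t0 <= sync_s <= ref.t_end:
        raise ValueError(f"sync time {sync_s} s outside force record [{ref.t0}, {ref.t_end}] s")
    n_drop = int(round((sync_s - ref.t0) * ref.fs))

    def _shift(tr: SignalTrack) -> SignalTrack:
        return SignalTrack(tr.samples[n_drop:], tr.fs, tr.t0 + n_drop / tr.fs - sync_s)

    return replace(
        rec,
        force_left={axis: _shift(tr) for axis, tr in rec.force_left.items()},
        force_right={axis: _shift(tr) for axis, tr in rec.force_right.items()},
    )


def shift_annotations(
    annotations: Sequence[AssistAnnotation], sync_s: float
) -> list[AssistAnnotation]:
    """Express annotations in the post-alignment time base (sync instant -> 0)."""
    return [
        replace(a, start_s=a.start_s - sync_s, stop_s=a.stop_s - sync_s) for a in annotations
    ]


_ANNOTATION_FIELDS = ("start_s", "stop_s", "location", "sensors_hit")


def _annotation_from_record(row: int, record: Mapping) -> AssistAnnotation:
    try:
        return AssistAnnotation(
            start_s=float(record["start_s"]),
            stop_s=float(record["stop_s"]),
            location=str(record["location"]),
            sensors_hit=str(record["sensors_hit"]),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise AnnotationFormatError(row, str(exc)) from exc


def read_annotations(path: str | Path) -> list[AssistAnnotation]:
    """Load annotations from CSV or JSON, sorted by start time."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text() or "[]")
    else:
        text = path.read_text()
        if not text.strip():
            return []
        df = pd.read_csv(io.StringIO(text), comment="#")
        records = df.to_dict(orient="records")
    annotations = [_annotation_from_record(i, rec) for i, rec in enumerate(records)]
    return sorted(annotations, key=lambda a: (a.start_s, a.stop_s))


def write_annotations(annotations: Sequence[AssistAnnotation], path: str | Path) -> Path:
    path = Path(path)
    records = [a.to_dict() for a in sorted(annotations, key=lambda a: (a.start_s, a.stop_s))]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        pd.DataFrame(records, columns=_ANNOTATION_FIELDS).to_csv(path, index=False)
    return path
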