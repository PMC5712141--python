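"""Seeded simulator of therapist-assisted gait sessions.

Generates a gait-like sacral acceleration stream (gravity offset, two
sinusoidal harmonics, white noise) with sparse assistance episodes of
sustained elevated acceleration, plus matching two-hand force-sensor
profiles (raised-cosine pulses, left hand dominant) and ground-truth
annotations.  Every draw is controlled by the config seed, so identical
configs produce bitwise-identical sessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from gaitassist.timeseries_io import (
    AXES,
    AssistAnnotation,
    SessionRecording,
    SignalTrack,
)

__all__ = ["SimConfig", "simulate_cohort", "simulate_session"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated session.

    Event peak force and duration are log-normal so their *medians* match
    the configured targets.  ``event_boost_mps2`` is the sustained extra
    acceleration magnitude during an assistance episode; it must clear the
    upper Tukey fence of the gait signal once diluted by the detector's
    moving average, so it is much larger than the gait noise floor.
    """

    duration_s: float = 60.0
    accel_fs: float = 60.0
    force_fs: float = 100.0
    step_freq_hz: float = 1.6
    gait_amp_mps2: float = 1.5
    noise_sd_mps2: float = 0.3
    n_events: int = 3
    min_separation_s: float = 5.0
    event_duration_median_s: float = 1.1
    event_duration_sigma: float = 0.4
    min_event_duration_s: float = 0.5
    event_boost_mps2: float = 20.0
    force_peak_ml_median_n: float = 15.9
    force_peak_sigma: float = 0.5
    secondary_hand_fraction: float = 0.3
    p_both: float = 0.48
    p_one: float = 0.30
    p_other: float = 0.22
    body_mass_kg: float = 84.0
    gravity_mps2: float = 9.81
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_s", "accel_fs", "force_fs", "step_freq_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        probs = (self.p_both, self.p_one, self.p_other)
        if min(probs) < 0 or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("location probabilities must be non-negative and sum to 1")
        if not 0 <= self.secondary_hand_fraction < 1:
            raise ValueError("secondary_hand_fraction must be in [0, 1)")
        if self.n_events and self.n_events * self.min_separation_s >= self.duration_s:
            raise ValueError(
                "n_events * min_separation_s must be smaller than duration_s"
            )


def _draw_event_times(
    rng: np.random.Generator, cfg: SimConfig, max_tries: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Event starts (pairwise gaps >= min_separation_s) and durations."""
    durations = np.exp(
        rng.normal(np.log(cfg.event_duration_median_s), cfg.event_duration_sigma, cfg.n_events)
    )
    dur_cap = max(cfg.min_separation_s - 0.5, cfg.min_event_duration_s)
    durations = np.clip(durations, cfg.min_event_duration_s, dur_cap)
    margin = 1.0
    for _ in range(max_tries):
        starts = np.sort(
            rng.uniform(margin, cfg.duration_s - margin - durations.max(), cfg.n_events)
        )
        if cfg.n_events < 2 or np.diff(starts).min() >= cfg.min_separation_s:
            return starts, durations
    raise RuntimeError(
        f"could not place {cfg.n_events} events with separation "
        f"{cfg.min_separation_s} s in {cfg.duration_s} s"
    )


def _pulse(t: np.ndarray, start: float, stop: float, kind: str) -> np.ndarray:
    """Unit-peak envelope supported on [start, stop]: Hann or flat-topped Tukey."""
    out = np.zeros_like(t)
    mask = (t >= start) & (t <= stop)
    if not mask.any():
        return out
    phase = (t[mask] - start) / (stop - start)
    if kind == "hann":
        out[mask] = 0.5 - 0.5 * np.cos(2 * np.pi * phase)
    else:  # sustained plateau with cosine ramps
        n = int(mask.sum())
        out[mask] = windows.tukey(n, alpha=0.4) if n > 1 else 1.0
    return out


def simulate_session(
    cfg: SimConfig,
) -> tuple[SessionRecording, list[AssistAnnotation]]:
    """One session: (recording, ground-truth annotations)."""
    rng = np.random.default_rng(cfg.seed)
    n_a = int(round(cfg.duration_s * cfg.accel_fs))
    t_a = np.arange(n_a) / cfg.accel_fs
    n_f = int(round(cfg.duration_s * cfg.force_fs))
    t_f = np.arange(n_f) / cfg.force_fs

    w_step = 2 * np.pi * cfg.step_freq_hz
    amp = cfg.gait_amp_mps2
    ax = 0.5 * amp * np.sin(w_step * t_a) + rng.normal(0, cfg.noise_sd_mps2, n_a)
    ay = 0.5 * amp * np.sin(w_step * t_a + np.pi / 2) + rng.normal(
        0, cfg.noise_sd_mps2, n_a
    )
    # vertical axis carries gravity and the dominant harmonic at twice the
    # step frequency (one peak per single-leg support)
    az = (
        cfg.gravity_mps2
        + amp * np.sin(2 * w_step * t_a)
        + rng.normal(0, cfg.noise_sd_mps2, n_a)
    )

    force = {
        side: {axis: np.zeros(n_f) for axis in AXES} for side in ("left", "right")
    }
    annotations: list[AssistAnnotation] = []

    if cfg.n_events:
        starts, durations = _draw_event_times(rng, cfg)
        kinds = rng.choice(
            ("both", "one", "other"), size=cfg.n_events, p=(cfg.p_both, cfg.p_one, cfg.p_other)
        )
        for start, duration, kind in zip(starts, durations, kinds):
            stop = start + duration
            # sustained magnitude boost on the gravity-carrying axis so the
            # acceleration norm is elevated for the whole episode
            az += cfg.event_boost_mps2 * _pulse(t_a, start, stop, "tukey")

            if kind == "other":
                location = str(rng.choice(("trunk", "shoulder")))
                sensors_hit = "none"
            else:
                location = "iliac_crest"
                sensors_hit = kind
                net_peak = np.exp(
                    rng.normal(np.log(cfg.force_peak_ml_median_n), cfg.force_peak_sigma)
                )
                left_peak = net_peak / (1.0 - cfg.secondary_hand_fraction)
                envelope = _pulse(t_f, start, stop, "hann")
                force["left"]["ml"] += left_peak * envelope
                force["left"]["ap"] += 0.14 * left_peak * envelope
                force["left"]["si"] += 0.12 * left_peak * envelope
                if kind == "both":
                    right_peak = cfg.secondary_hand_fraction * left_peak
                    force["right"]["ml"] += right_peak * envelope
                    force["right"]["ap"] += 0.14 * right_peak * envelope
                    force["right"]["si"] += 0.12 * right_peak * envelope
            annotations.append(
                AssistAnnotation(
                    start_s=float(start),
                    stop_s=float(stop),
                    location=location,
                    sensors_hit=sensors_hit,
                )
            )

    rec = SessionRecording(
        accel_x=SignalTrack(ax, cfg.accel_fs),
        accel_y=SignalTrack(ay, cfg.accel_fs),
        accel_z=SignalTrack(az, cfg.accel_fs),
        force_left={axis: SignalTrack(force["left"][axis], cfg.force_fs) for axis in AXES},
        force_right={axis: SignalTrack(force["right"][axis], cfg.force_fs) for axis in AXES},
        body_mass_kg=cfg.body_mass_kg,
    )
    return rec, annotations


def simulate_cohort(
    n_patients: int,
    cfg: SimConfig | None = None,
    seed: int = 0,
    *,
    body_mass_mean_kg: float = 84.0,
    body_mass_sd_kg: float = 7.2,
) -> list[tuple[SessionRecording, list[AssistAnnotation]]]:
    """Simulate ``n_patients`` independent sessions with per-patient seeds.

    Body masses are drawn around the cohort defaults (84 +/- 7.2 kg); the
    per-patient seeds derive deterministically from ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    template = cfg or SimConfig()
    root = np.random.SeedSequence(seed)
    mass_rng = np.random.default_rng(root.spawn(1)[0])
    masses = np.clip(
        mass_rng.normal(body_mass_mean_kg, body_mass_sd_kg, n_patients), 45.0, 150.0
    )
    child_seeds = root.generate_state(n_patients)
    sessions = []
    for mass, child in zip(masses, child_seeds):
        patient_cfg = dataclasses.replace(
            template, seed=int(child), body_mass_kg=float(mass)
        )
        sessions.append(simulate_session(patient_cfg))
    return sessions
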