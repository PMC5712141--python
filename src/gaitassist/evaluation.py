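"""Scoring of detections against annotated events, and parameter tuning.

Detections are matched one-to-one to annotations with a temporal tolerance
(overlapping intervals have distance 0; otherwise the gap between nearest
endpoints counts, and pairs further apart than the tolerance never match).
Matched pairs are true positives, unmatched detections false positives,
unmatched annotations false negatives.  PPV = TP/(TP+FP)*100 and
TPR = TP/(TP+FN)*100; group rows pool raw counts before scoring.

The (alpha, delta) grid search maximizes min(PPV, TPR) with ties broken by
PPV+TPR, then smaller delta, then smaller alpha, and reports the full
plateau of maximizers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gaitassist.assist_detector import (
    DetectorParams,
    _prepare_base,
    detect,
    mark_outliers,
    moving_average,
    tukey_threshold,
)
from gaitassist.timeseries_io import AssistAnnotation, SessionRecording

__all__ = [
    "ConfusionCounts",
    "GridSearchResult",
    "grid_search",
    "interval_distance",
    "match_events",
    "pool_counts",
    "ppv",
    "round_pct",
    "split_validation",
    "summarize_demographics",
    "tpr",
]

DEFAULT_TOLERANCE_S = 0.5
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.5, 3.0 + 1e-9, 0.1), 10))
DEFAULT_DELTA_GRID = tuple(np.round(np.arange(0.5, 3.0 + 1e-9, 0.01), 10))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn, self.fp + other.fp)


def ppv(c: ConfusionCounts) -> float | None:
    """Positive predictive value in percent; None when no detections exist."""
    if c.tp + c.fp == 0:
        return None
    return c.tp / (c.tp + c.fp) * 100.0


def tpr(c: ConfusionCounts) -> float | None:
    """True positive rate in percent; None when no annotations exist."""
    if c.tp + c.fn == 0:
        return None
    return c.tp / (c.tp + c.fn) * 100.0


def round_pct(value: float | None) -> int | None:
    """Nearest integer, halves away from zero (reported percentages)."""
    if value is None:
        return None
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


def pool_counts(counts: Iterable[ConfusionCounts]) -> ConfusionCounts:
    """Element-wise sum over trials/patients (empty input pools to zeros)."""
    total = ConfusionCounts()
    for c in counts:
        total = total + c
    return total


def interval_distance(
    detection: tuple[float, float], annotation: tuple[float, float]
) -> float:
    """0 for overlapping intervals, else the gap between nearest endpoints."""
    d_on, d_off = detection
    a_on, a_off = annotation
    if d_on <= a_off and a_on <= d_off:
        return 0.0
    return max(a_on - d_off, d_on - a_off)


def match_events(
    detections: Sequence[tuple[float, float]],
    annotations: Sequence[AssistAnnotation | tuple[float, float]],
    tol_s: float = DEFAULT_TOLERANCE_S,
) -> tuple[ConfusionCounts, list[tuple[int, int, float]]]:
    """Greedy one-to-one matching of detections to annotations.

    Candidate pairs within ``tol_s`` are matched in increasing distance
    order (ties: earlier annotation, then earlier detection).  Returns the
    confusion counts and the matched ``(detection_idx, annotation_idx,
    distance)`` pairs.
    """
    if tol_s < 0:
        raise ValueError("tol_s must be >= 0")
    ann_spans = [
        (a.start_s, a.stop_s) if isinstance(a, AssistAnnotation) else (float(a[0]), float(a[1]))
        for a in annotations
    ]
    candidates = []
    for ai, span in enumerate(ann_spans):
        for di, det in enumerate(detections):
            dist = interval_distance(det, span)
            if dist <= tol_s:
                candidates.append((dist, ai, di))
    candidates.sort()
    matched_ann: set[int] = set()
    matched_det: set[int] = set()
    pairing: list[tuple[int, int, float]] = []
    for dist, ai, di in candidates:
        if ai in matched_ann or di in matched_det:
            continue
        matched_ann.add(ai)
        matched_det.add(di)
        pairing.append((di, ai, dist))
    tp = len(pairing)
    counts = ConfusionCounts(
        tp=tp, fn=len(ann_spans) - tp, fp=len(detections) - tp
    )
    return counts, sorted(pairing)


@dataclass(frozen=True)
class GridSearchResult:
    """Full (alpha, delta) score table plus the optimal plateau."""

    table: pd.DataFrame
    optimal_set: tuple[tuple[float, float], ...]
    best: tuple[float, float]
    objective: tuple[float, float]  # (min(PPV, TPR), PPV + TPR) at the optimum

    @property
    def best_params(self) -> DetectorParams:
        alpha, delta = self.best
        return DetectorParams(alpha=alpha, delta_s=delta)


def _objective_key(p: float | None, t: float | None) -> tuple[float, float]:
    if p is None or t is None or math.isnan(p) or math.isnan(t):
        return (-math.inf, -math.inf)
    return (min(p, t), p + t)


def _select_plateau(table: pd.DataFrame) -> tuple[tuple, tuple[float, float]]:
    """Maximizers of (min(PPV,TPR), PPV+TPR); best = smallest delta, then alpha."""
    keys = [_objective_key(p, t) for p, t in zip(table["ppv"], table["tpr"])]
    best_key = max(keys)
    plateau = [
        (float(row.alpha), float(row.delta_s))
        for key, row in zip(keys, table.itertuples())
        if key == best_key
    ]
    plateau.sort(key=lambda ad: (ad[1], ad[0]))
    return tuple(plateau), best_key


def grid_search(
    sessions: Sequence[tuple],
    alpha_grid: Sequence[float] | None = None,
    delta_grid: Sequence[float] | None = None,
    *,
    tol_s: float = DEFAULT_TOLERANCE_S,
    detector_kwargs: Mapping | None = None,
) -> GridSearchResult:
    """Evaluate every (alpha, delta) pair over a set of annotated sessions.

    ``sessions`` is a sequence of ``(recording, annotations)`` pairs where
    ``recording`` is a :class:`SessionRecording` or a 3-tuple of
    accelerometer tracks.  Counts are pooled over sessions at each grid
    point before PPV/TPR are computed.

    The alpha-independent (and, for the default pre-smoothing quartiles,
    delta-independent) pipeline stages are computed once per session, which
    makes the full default grid (26 x 251 points) tractable; the result is
    identical to calling :func:`gaitassist.assist_detector.detect` point by
    point.
    """
    if not sessions:
        raise ValueError("need at least one session")
    alphas = tuple(alpha_grid) if alpha_grid is not None else DEFAULT_ALPHA_GRID
    deltas = tuple(delta_grid) if delta_grid is not None else DEFAULT_DELTA_GRID
    kwargs = dict(detector_kwargs or {})
    quantile_method = kwargs.pop("quantile_method", "linear")
    quartiles_on = kwargs.pop("quartiles_on", "pre_smoothing")

    prepared = []
    for recording, annotations in sessions:
        tracks = (
            recording.accel_tracks
            if isinstance(recording, SessionRecording)
            else tuple(recording)
        )
        prepared.append((_prepare_base(tracks, **kwargs), annotations))

    records = []
    for delta in deltas:
        per_session = []
        for (trimmed, _kept), annotations in prepared:
            smoothed = moving_average(trimmed, delta)
            source = trimmed if quartiles_on == "pre_smoothing" else smoothed
            _, _q1, q3, iqr = tukey_threshold(
                source, 0.0, quantile_method=quantile_method
            )
            per_session.append((smoothed, q3, iqr, annotations))
        for alpha in alphas:
            pooled = ConfusionCounts()
            for smoothed, q3, iqr, annotations in per_session:
                threshold = q3 + alpha * iqr
                intervals = mark_outliers(smoothed, threshold)
                counts, _ = match_events(intervals, annotations, tol_s=tol_s)
                pooled = pooled + counts
            p, t = ppv(pooled), tpr(pooled)
            records.append(
                {
                    "alpha": alpha,
                    "delta_s": delta,
                    "tp": pooled.tp,
                    "fn": pooled.fn,
                    "fp": pooled.fp,
                    "ppv": np.nan if p is None else p,
                    "tpr": np.nan if t is None else t,
                }
            )
    table = pd.DataFrame.from_records(records)
    plateau, best_key = _select_plateau(table)
    return GridSearchResult(
        table=table, optimal_set=plateau, best=plateau[0], objective=best_key
    )


def _score_rows(
    per_patient: Mapping[str, ConfusionCounts]
) -> pd.DataFrame:
    """Per-patient rows plus a pooled group row, PPV/TPR as rounded percents."""
    rows = []
    for pid, counts in per_patient.items():
        rows.append(
            {
                "patient": pid,
                "tp": counts.tp,
                "fn": counts.fn,
                "fp": counts.fp,
                "ppv_pct": round_pct(ppv(counts)),
                "tpr_pct": round_pct(tpr(counts)),
            }
        )
    group = pool_counts(per_patient.values())
    rows.append(
        {
            "patient": "group_total",
            "tp": group.tp,
            "fn": group.fn,
            "fp": group.fp,
            "ppv_pct": round_pct(ppv(group)),
            "tpr_pct": round_pct(tpr(group)),
        }
    )
    return pd.DataFrame(rows, columns=["patient", "tp", "fn", "fp", "ppv_pct", "tpr_pct"])


def split_validation(
    sessions: Mapping[str, tuple],
    dev_ids: Sequence[str],
    val_ids: Sequence[str],
    *,
    alpha_fixed: float = 1.0,
    alpha_grid: Sequence[float] | None = None,
    delta_grid: Sequence[float] | None = None,
    tol_s: float = DEFAULT_TOLERANCE_S,
    detector_kwargs: Mapping | None = None,
) -> dict:
    """Tune (alpha, delta) on a development subset, score a validation subset.

    The grid search runs on ``dev_ids``; ``alpha_fixed`` (a constant chosen
    within the optimal plateau) and the plateau's delta are then applied to
    every validation session.  Returns the chosen parameters, the dev grid
    result and per-patient/group score tables for both subsets.
    """
    dev_ids, val_ids = list(dev_ids), list(val_ids)
    overlap = set(dev_ids) & set(val_ids)
    if overlap and set(dev_ids) != set(val_ids):
        raise ValueError(f"dev and validation ids overlap: {sorted(overlap)}")
    missing = [pid for pid in dev_ids + val_ids if pid not in sessions]
    if missing:
        raise KeyError(f"unknown session ids: {missing}")

    dev_result = grid_search(
        [sessions[pid] for pid in dev_ids],
        alpha_grid,
        delta_grid,
        tol_s=tol_s,
        detector_kwargs=detector_kwargs,
    )
    delta_s = dev_result.best[1]
    params = DetectorParams(alpha=alpha_fixed, delta_s=delta_s)

    def _score(ids: Sequence[str]) -> pd.DataFrame:
        per_patient = {}
        for pid in ids:
            recording, annotations = sessions[pid]
            result = detect(recording, params, **dict(detector_kwargs or {}))
            counts, _ = match_events(result.intervals, annotations, tol_s=tol_s)
            per_patient[pid] = counts
        return _score_rows(per_patient)

    return {
        "params": {"alpha": params.alpha, "delta_s": params.delta_s},
        "dev_grid": dev_result,
        "dev_table": _score(dev_ids),
        "validation_table": _score(val_ids),
    }


def summarize_demographics(patients: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1), median and IQR for each numeric column.

    With a single patient the SD row is NaN (undefined).
    """
    numeric = patients.select_dtypes(include=[np.number])
    if numeric.shape[1] == 0:
        raise ValueError("no numeric columns to summarize")
    mean = numeric.mean()
    sd = numeric.std(ddof=1) if len(numeric) >= 2 else mean * np.nan
    median = numeric.median()
    iqr = numeric.quantile(0.75) - numeric.quantile(0.25)
    return pd.DataFrame({"mean": mean, "sd": sd, "median": median, "iqr": iqr}).T
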