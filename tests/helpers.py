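"""Independent naive-loop oracles used to cross-check the vectorized pipeline.

Everything here is deliberately written with plain Python loops and textbook
formulas, sharing no code with the package under test.
"""

from __future__ import annotations

import math


def naive_quantile(values, q):
    """Linear interpolation between closest ranks (textbook type-7)."""
    s = sorted(values)
    n = len(s)
    if n == 1:
        return s[0]
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def naive_moving_average(x, w):
    """Centered mean over a w-sample window clipped to the record ends."""
    n = len(x)
    half = w // 2
    out = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out.append(sum(x[lo:hi]) / (hi - lo))
    return out


def naive_window_samples(delta_s, fs):
    w = max(int(round(delta_s * fs)), 1)
    if w % 2 == 0:
        w += 1
    return w


def naive_rolling_std(x, w):
    n = len(x)
    half = w // 2
    out = []
    for i in range(n):
        seg = x[max(0, i - half) : min(n, i + half + 1)]
        m = sum(seg) / len(seg)
        out.append(math.sqrt(sum((v - m) ** 2 for v in seg) / len(seg)))
    return out


def naive_detect(ax, ay, az, fs, alpha, delta_s, *, trim_window_s=1.0, trim_frac=0.10):
    """Loop-based reimplementation of the full detection pipeline.

    Returns (intervals, threshold, (q1, q3, iqr), kept_start_index).
    """
    n = len(ax)
    norm = [math.sqrt(ax[i] ** 2 + ay[i] ** 2 + az[i] ** 2) for i in range(n)]
    mean = sum(norm) / n
    free = [v - mean for v in norm]

    overall_mean = sum(free) / n
    overall_std = math.sqrt(sum((v - overall_mean) ** 2 for v in free) / n)
    w_trim = max(int(round(trim_window_s * fs)), 1)
    rstd = naive_rolling_std(free, w_trim)
    active = [s >= trim_frac * overall_std for s in rstd]
    if any(active):
        i0 = active.index(True)
        i1 = n - 1 - active[::-1].index(True)
    else:
        i0, i1 = 0, n - 1
    trimmed = free[i0 : i1 + 1]

    q1 = naive_quantile(trimmed, 0.25)
    q3 = naive_quantile(trimmed, 0.75)
    iqr = q3 - q1
    threshold = q3 + alpha * iqr

    w = naive_window_samples(delta_s, fs)
    smoothed = naive_moving_average(trimmed, w)

    intervals = []
    run_start = None
    for i, v in enumerate(smoothed):
        if v > threshold and run_start is None:
            run_start = i
        elif v <= threshold and run_start is not None:
            intervals.append((run_start, i - 1))
            run_start = None
    if run_start is not None:
        intervals.append((run_start, len(smoothed) - 1))
    t0 = i0 / fs
    spans = [(t0 + a / fs, t0 + (b + 1) / fs) for a, b in intervals]
    return spans, threshold, (q1, q3, iqr), i0


def naive_match(detections, annotations, tol):
    """Greedy one-to-one matching by increasing inter-interval distance."""

    def dist(d, a):
        if d[0] <= a[1] and a[0] <= d[1]:
            return 0.0
        return max(a[0] - d[1], d[0] - a[1])

    pairs = sorted(
        (dist(d, a), ai, di)
        for ai, a in enumerate(annotations)
        for di, d in enumerate(detections)
        if dist(d, a) <= tol
    )
    used_a, used_d = set(), set()
    tp = 0
    for _, ai, di in pairs:
        if ai in used_a or di in used_d:
            continue
        used_a.add(ai)
        used_d.add(di)
        tp += 1
    return tp, len(annotations) - tp, len(detections) - tp
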