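"""Independent brute-force reference implementations.

Deliberately naive (explicit loops, no shared code with the package) so
they pin the semantics of the detector primitives and the matching rule.
"""

from __future__ import annotations

import numpy as np


def brute_moving_variance(x, w: int):
    """Sample variance (n-1) of every length-w window, one explicit loop each."""
    x = np.asarray(x, dtype=float)
    out = []
    for k in range(len(x) - w + 1):
        win = x[k : k + w]
        m = win.sum() / w
        out.append(((win - m) ** 2).sum() / (w - 1))
    return np.array(out)


def brute_peaks(v, threshold: float):
    """Strict local maxima above threshold; plateaus report their first sample.

    A plateau is a run of equal values bounded on both sides by strictly
    smaller values; runs touching either end of the series are not peaks.
    """
    v = np.asarray(v, dtype=float)
    n = len(v)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < n - 1 and v[i - 1] < v[i] and v[j + 1] < v[i] and v[i] > threshold:
            peaks.append(i)
        i = j + 1
    return np.array(peaks, dtype=int)


def brute_groups(times, min_interval: float):
    """Split a sorted peak-time list at every gap strictly above the interval."""
    groups, current = [], []
    for t in times:
        if current and t - current[-1] > min_interval:
            groups.append(current)
            current = []
        current.append(t)
    if current:
        groups.append(current)
    return groups


def brute_extent_integral(v, t, peak_indices, threshold: float):
    """(duration, trapezoid area) over the supra-threshold runs holding the peaks."""
    v = np.asarray(v, dtype=float)
    runs = []
    start = None
    for i, val in enumerate(v):
        if val > threshold and start is None:
            start = i
        if val <= threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(v)))
    used = []
    for p in peak_indices:
        for run in runs:
            if run[0] <= p < run[1] and run not in used:
                used.append(run)
    first = min(r[0] for r in used)
    last = max(r[1] for r in used) - 1
    area = 0.0
    for a, b in used:
        for i in range(a, b - 1):
            area += 0.5 * (v[i] + v[i + 1]) * (t[i + 1] - t[i])
    return t[last] - t[first], area


def brute_match(detection_times, events):
    """Exhaustive earliest-detection-per-event matching.

    ``events`` are (start, end) windows, non-excluded.  Returns a dict of
    TP/FP/FN/TN.  A detection inside several windows goes to the window
    whose start is nearest the detection time (ties to the earlier start).
    """
    detection_times = sorted(detection_times)
    events = sorted(events)
    if not detection_times and not events:
        return {"tp": 0, "fp": 0, "fn": 0, "tn": 1}
    assigned: dict[int, list[float]] = {}
    fp = 0
    for dt in detection_times:
        containing = [k for k, (s, e) in enumerate(events) if s <= dt <= e]
        if not containing:
            fp += 1
            continue
        best = None
        for k in containing:
            key = (abs(dt - events[k][0]), events[k][0])
            if best is None or key < best[0]:
                best = (key, k)
        assigned.setdefault(best[1], []).append(dt)
    tp = fn = 0
    for k in range(len(events)):
        hits = assigned.get(k, [])
        if hits:
            tp += 1
            fp += len(hits) - 1
        else:
            fn += 1
    return {"tp": tp, "fp": fp, "fn": fn, "tn": 0}
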