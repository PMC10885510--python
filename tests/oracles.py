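"""Independent brute-force oracles used to cross-check the event detectors.

These re-derive events by direct per-sample enumeration with explicit Python
loops, sharing no code with the implementation.
"""

import numpy as np


def brute_binary(time, x, inverted=False):
    target = 0.0 if inverted else 1.0
    n = len(time)
    events = []
    i = 0
    while i < n:
        if np.isfinite(x[i]) and x[i] == target:
            j = i
            while j + 1 < n and np.isfinite(x[j + 1]) and x[j + 1] == target:
                j += 1
            end = time[j + 1] if j + 1 < n else time[-1]
            if end > time[i]:
                events.append((float(time[i]), float(end)))
            i = j + 1
        else:
            i += 1
    return events


def brute_binned(time, t0, L, tol=1e-9):
    t_first, t_last = time[0], time[-1]
    events = []
    k = 0
    while True:
        start, end = t0 + k * L, t0 + (k + 1) * L
        if end > t_last + tol:
            break
        if start >= t_first - tol:
            events.append((float(start), float(end)))
        k += 1
    return events


def brute_peaks(time, x, L, k):
    n = len(time)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        if not np.isfinite(x[i]):
            continue
        window = [x[j] for j in range(n)
                  if abs(time[j] - time[i]) <= L / 2 and np.isfinite(x[j])]
        m = len(window)
        if m < 2:
            continue
        mean = sum(window) / m
        var = sum((v - mean) ** 2 for v in window) / (m - 1)
        flagged[i] = x[i] > mean + k * np.sqrt(var)
    events = []
    i = 0
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            end = time[j + 1] if j + 1 < n else time[-1]
            if end > time[i]:
                events.append((float(time[i]), float(end)))
            i = j + 1
        else:
            i += 1
    return events


def as_pairs(events):
    return [(ev.start_s, ev.end_s) for ev in events]
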