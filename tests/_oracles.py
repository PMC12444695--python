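"""Independent brute-force oracles used to cross-check the implementation.

Each oracle re-derives the expected behaviour from the rule definition by
direct enumeration or simulation, deliberately avoiding the package's
own code paths and data structures.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_detect(t, a, p, angle_thresh=2.0, pitch_thresh=2.0, dwell=10.0):
    """Enumerate every candidate onset and test its dwell window directly.

    Baseline-reset semantics: a candidate at index i is an event iff the
    first sample j with t[j] - t[i] >= dwell exists and every sample in
    (i, j] deviates from the baseline by more than both thresholds.
    Returns a list of (onset_t, confirmed_t) pairs.
    """
    n = len(t)
    if n == 0:
        return []
    events = []
    base_a, base_p = a[0], p[0]

    def above(k):
        return abs(a[k] - base_a) > angle_thresh and abs(p[k] - base_p) > pitch_thresh

    i = 1
    while i < n:
        if not above(i):
            i += 1
            continue
        jstar = None
        for j in range(i + 1, n):
            if t[j] - t[i] >= dwell:
                jstar = j
                break
        if jstar is None:
            # recording ends inside the dwell: no later onset can confirm either
            break
        window = list(range(i + 1, jstar + 1))
        fails = [k for k in window if not above(k)]
        if not fails:
            events.append((t[i], t[jstar]))
            base_a, base_p = a[jstar], p[jstar]
            i = jstar + 1
        else:
            i = fails[0]
    return events


def oracle_alert_times(onsets, duration, threshold):
    """Second-by-second immobility simulation (integer schedules only).

    Evaluates the left-limit time-since-last-movement at every integer
    second and fires an alert at each upward crossing of the threshold.
    Independent route from interval enumeration.
    """
    onsets = np.asarray(sorted(onsets), dtype=int)
    t = np.arange(0, int(duration) + 1)
    if onsets.size:
        idx = np.searchsorted(onsets, t, side="left")  # onsets strictly before t
        last = np.where(idx > 0, onsets[np.maximum(idx - 1, 0)], 0)
    else:
        last = np.zeros_like(t)
    tsm = t - last
    firing = tsm >= threshold
    crossings = np.nonzero(firing[1:] & ~firing[:-1])[0] + 1
    if firing.size and firing[0]:
        crossings = np.concatenate([[0], crossings])
    return t[crossings].tolist()


def oracle_tsl(onsets, t):
    """Linear-scan time since last movement."""
    best = 0.0
    for o in onsets:
        if o <= t and o > best:
            best = o
    return t - (best if any(o <= t for o in onsets) else 0.0)


def oracle_video(com, shift_thresh, sustain_frames):
    """Brute-force landmark movement counting on a center-of-mass track.

    Returns onset *indices* into the track.
    """
    n = len(com)
    onsets = []
    base = com[0]
    i = 1
    while i < n:
        window = [
            math.dist(com[k], base) > shift_thresh
            for k in range(i, min(i + sustain_frames, n))
        ]
        if not window[0]:
            i += 1
            continue
        if len(window) == sustain_frames and all(window):
            onsets.append(i)
            base = com[i + sustain_frames - 1]
            i = i + sustain_frames
        else:
            first_fail = window.index(False) if False in window else len(window)
            i = i + max(first_fail, 1)
    return onsets


def oracle_window_maxima(t, mags, window):
    """Direct per-window scan of magnitude maxima."""
    rel = [x - t[0] for x in t]
    n_win = int(rel[-1] // window) + 1
    out = []
    for k in range(n_win):
        vals = [m for x, m in zip(rel, mags) if k * window <= x < (k + 1) * window]
        out.append(max(vals))
    return out


def oracle_tail_start(angle, pitch, window, eps):
    """Backward scan for the first sample of the maximal quiet terminal run."""
    n = len(angle)
    w = int(window)
    if n < w:
        return n
    for end in range(n - 1, w - 2, -1):
        sa = np.std(angle[end - w + 1 : end + 1])
        sp = np.std(pitch[end - w + 1 : end + 1])
        if not (sa < eps and sp < eps):
            if end == n - 1:
                return n  # tail not quiet at all
            return end - w + 2
    return 0


def random_stream(rng, n=None, gaps=False):
    """A jagged random tilt stream exercising many detector code paths.

    Mix of plateaus, small jitter, large sustained jumps, and brief
    spikes; optional irregular sampling gaps.
    """
    if n is None:
        n = int(rng.integers(50, 1500))
    if gaps:
        dt = rng.choice([1, 1, 1, 1, 1, 2, 3, 30], size=n - 1)
        t = np.concatenate([[0.0], np.cumsum(dt)]).astype(float)
    else:
        t = np.arange(n, dtype=float)
    steps = rng.choice(
        [0.0, 0.0, 0.0, 0.0, 0.3, -0.3, 3.0, -3.0, 6.0, -6.0],
        size=(2, n),
    )
    angle = np.clip(np.cumsum(steps[0]), -60, 60)
    pitch = np.clip(np.cumsum(steps[1]), -60, 60)
    # occasional short spikes
    for _ in range(int(rng.integers(0, 6))):
        s = int(rng.integers(0, n))
        L = int(rng.integers(1, 8))
        angle[s : s + L] += rng.choice([-5.0, 5.0])
        pitch[s : s + L] += rng.choice([-5.0, 5.0])
    return t, np.clip(angle, -90, 90), np.clip(pitch, -90, 90)
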