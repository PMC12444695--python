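"""Repositioning detection and motion-intensity statistics.

The detector implements a threshold-and-dwell rule on the two tilt axes:
a repositioning is registered only when *both* angle and pitch deviate by
strictly more than their thresholds (default 2 degrees each) from the
last registered position, and the deviation is sustained for a minimum
dwell of elapsed time (default 10 s).  The dwell filters out transient
disturbances — a bump against the bed — that do not constitute a change
of position.

Semantics are baseline-reset: the reference position starts at the first
sample and is reset to the sensor values at each confirmed event, so slow
rolls that never produce a large sample-to-sample difference are still
detected.  The event timestamp is the candidate onset (when the movement
physically happened); the confirmation time is retained for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sensor_io import SensorRecording


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds for the repositioning detector.

    angle_thresh, pitch_thresh : degrees, strict (">" not ">=")
    dwell : seconds of elapsed time the deviation must persist
    max_gap : optional strict mode — a candidate containing an
        inter-sample gap longer than ``max_gap`` seconds is discarded.
        ``None`` (default) confirms across gaps when samples on both
        sides remain above threshold.
    """

    angle_thresh: float = 2.0
    pitch_thresh: float = 2.0
    dwell: float = 10.0
    max_gap: float | None = None

    def __post_init__(self) -> None:
        if self.angle_thresh <= 0 or self.pitch_thresh <= 0 or self.dwell <= 0:
            raise ValueError("detector thresholds and dwell must be strictly positive")


@dataclass(frozen=True)
class MovementEvent:
    """A confirmed sustained repositioning."""

    onset_t: float
    confirmed_t: float
    d_angle: float
    d_pitch: float


@dataclass
class IntensitySummary:
    """Per-window maxima of acceleration magnitude and their summaries."""

    window_maxima: list  # (window index, max magnitude) pairs
    mean_magnitude: float
    max_magnitude: float


def detect_movements(rec: SensorRecording, cfg: DetectorConfig | None = None) -> list[MovementEvent]:
    """Detect sustained dual-axis repositioning events.

    Scans the stream once.  A candidate opens at the first sample whose
    angle *and* pitch deviations from the baseline both exceed their
    thresholds; it is confirmed at the first subsequent sample at least
    ``dwell`` elapsed seconds after onset, provided every intervening
    sample (and the confirming one) stayed above both thresholds.  On
    confirmation the baseline resets to that sample and scanning resumes;
    a drop below either threshold inside the dwell discards the candidate
    and scanning resumes from the failing sample with the old baseline.

    Empty recordings and recordings shorter than the dwell yield no events.
    """
    cfg = cfg or DetectorConfig()
    n = rec.n_samples
    if n < 2 or rec.duration < cfg.dwell:
        return []
    t = rec.t.tolist()
    a = rec.angle.tolist()
    p = rec.pitch.tolist()
    at, pt, dwell, max_gap = cfg.angle_thresh, cfg.pitch_thresh, cfg.dwell, cfg.max_gap
    events: list[MovementEvent] = []
    base_a, base_p = a[0], p[0]
    i = 1
    while i < n:
        if abs(a[i] - base_a) > at and abs(p[i] - base_p) > pt:
            onset = t[i]
            j = i + 1
            confirmed = -1
            while j < n:
                if max_gap is not None and t[j] - t[j - 1] > max_gap:
                    break
                if not (abs(a[j] - base_a) > at and abs(p[j] - base_p) > pt):
                    break
                if t[j] - onset >= dwell:
                    confirmed = j
                    break
                j += 1
            if confirmed >= 0:
                events.append(
                    MovementEvent(onset, t[j], a[j] - base_a, p[j] - base_p)
                )
                base_a, base_p = a[j], p[j]
                i = j + 1
            else:
                i = max(j, i + 1)
        else:
            i += 1
    return events


def movement_rate(n_events: int, duration_hours: float) -> float:
    """Movements per hour: event count divided by recording duration."""
    if duration_hours <= 0:
        raise ValueError("duration must be positive")
    return n_events / duration_hours


def magnitude(ax, ay, az=None):
    """Euclidean norm of the three acceleration components, in g.

    Accepts either three scalars/arrays or a single sample-like object
    with ``ax``, ``ay``, ``az`` attributes.
    """
    if ay is None and az is None:
        s = ax
        ax, ay, az = s.ax, s.ay, s.az
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(ay)) and np.all(np.isfinite(az))):
        raise ValueError("acceleration components must be finite")
    m = np.sqrt(ax * ax + ay * ay + az * az)
    return float(m) if m.ndim == 0 else m


def magnitudes(rec: SensorRecording) -> np.ndarray:
    """Per-sample acceleration magnitude for a whole recording."""
    return magnitude(rec.ax, rec.ay, rec.az)


def intensity_summary(
    rec: SensorRecording, window: float = 600.0, include_partial: bool = True
) -> IntensitySummary:
    """Per-window maxima of acceleration magnitude.

    Windows are half-open ``[k*window, (k+1)*window)`` in elapsed time
    from the first sample.  ``mean_magnitude`` is the arithmetic mean of
    the per-window maxima (the average maximal movement intensity per
    window); ``max_magnitude`` is the overall maximum.  The trailing
    partial window is included by default.
    """
    if rec.n_samples == 0:
        raise ValueError("recording is empty")
    mags = magnitudes(rec)
    rel = rec.t - rec.t[0]
    k = np.floor(rel / window).astype(int)
    n_win = int(k[-1]) + 1
    maxima = np.full(n_win, -np.inf)
    np.maximum.at(maxima, k, mags)
    if not include_partial and n_win > 1:
        # the final window is partial unless it spans a full `window`
        if rel[-1] + 1.0 / rec.nominal_rate < n_win * window:
            maxima = maxima[:-1]
            n_win -= 1
    pairs = [(int(i), float(m)) for i, m in enumerate(maxima)]
    return IntensitySummary(pairs, float(np.mean(maxima)), float(np.max(maxima)))


def bin_counts(onsets: Sequence[float], bin: float = 60.0, duration: float | None = None) -> np.ndarray:
    """Count event onsets in half-open time bins of width ``bin`` seconds.

    Bins are ``[k*bin, (k+1)*bin)`` over ``[0, duration]``; an onset at
    exactly ``duration`` is assigned to the final bin so the total count
    is always conserved.
    """
    onsets = np.asarray(list(onsets), dtype=float)
    if duration is None:
        duration = float(onsets.max()) if onsets.size else bin
    n_bins = max(int(np.ceil(duration / bin)), 1)
    counts = np.zeros(n_bins, dtype=int)
    if onsets.size:
        if onsets.min() < 0 or onsets.max() > duration:
            raise ValueError("onsets must lie within [0, duration]")
        idx = np.minimum((onsets // bin).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1)
    return counts


def onsets(events: Iterable[MovementEvent]) -> np.ndarray:
    """Extract sorted onset times from a sequence of events."""
    return np.asarray(sorted(e.onset_t for e in events), dtype=float)


def write_events(events: Sequence[MovementEvent], path, patient_id: str) -> None:
    """Write events as JSON lines (``.jsonl``) or CSV (any other suffix)."""
    rows = [
        {
            "patient_id": patient_id,
            "onset_t": e.onset_t,
            "confirmed_t": e.confirmed_t,
            "d_angle": e.d_angle,
            "d_pitch": e.d_pitch,
        }
        for e in events
    ]
    if str(path).endswith(".jsonl"):
        with open(path, "w") as fh:
            for r in rows:
                fh.write(json.dumps(r) + "\n")
    else:
        cols = ["patient_id", "onset_t", "confirmed_t", "d_angle", "d_pitch"]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    if str(path).endswith(".jsonl"):
        with open(path) as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
        return pd.DataFrame(rows)
    return pd.read_csv(path, float_precision="round_trip")
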