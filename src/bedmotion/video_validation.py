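"""Video-landmark movement counting and sensor-vs-video agreement.

During bench validation, subjects are filmed while the mattress sensor
records.  A pose-estimation pipeline reduces each video frame to named
body landmarks (both shoulders, both hips, nose) with coordinates
normalised to frame width.  This module consumes those landmark series —
not raw video — and mirrors the sensor's threshold-and-dwell rule on the
body's center of mass: a movement is counted when the center of mass is
displaced from its baseline by more than a fraction of the frame width
(default 2.5%) and the displacement is sustained for a minimum number of
consecutive frames (default 15).

Agreement between modalities is quantified per subject by the Pearson
correlation of 60-s binned movement counts, then aggregated across
subjects on the Fisher z scale (atanh), with the mean and its 95% CI
mapped back to r space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_LANDMARKS = (
    "left_shoulder", "right_shoulder", "left_hip", "right_hip", "nose",
)


@dataclass
class LandmarkSeries:
    """Per-frame pose landmark coordinates for one filmed subject.

    ``coords`` maps each required landmark name to an (n_frames, 2) array
    of (x, y) positions in units of frame width; ``frames`` holds the
    strictly increasing frame indices; NaN marks a missing landmark.
    """

    subject_id: str
    fps: float
    frames: np.ndarray
    coords: dict

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        if self.frames.size > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        missing = [lm for lm in REQUIRED_LANDMARKS if lm not in self.coords]
        if missing:
            raise ValueError(f"missing required landmark(s): {missing}")
        self.coords = {k: np.asarray(v, dtype=float) for k, v in self.coords.items()}

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)


@dataclass
class AgreementResult:
    """Cross-subject agreement: per-subject r, Fisher-aggregated mean, CI."""

    per_subject_r: list
    mean_r: float
    ci95: tuple

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.mean_r <= hi):
            raise ValueError("CI must bracket the mean correlation")


def center_of_mass(frame_landmarks: Mapping[str, tuple]) -> tuple[float, float]:
    """Unweighted mean position of the five required landmarks."""
    pts = np.array([frame_landmarks[lm] for lm in REQUIRED_LANDMARKS], dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("all required landmarks must be present and finite")
    c = pts.mean(axis=0)
    return float(c[0]), float(c[1])


def center_of_mass_series(series: LandmarkSeries) -> tuple[np.ndarray, np.ndarray]:
    """Center-of-mass track; frames missing any landmark are skipped (logged).

    Returns (valid frame indices, (m, 2) center positions).
    """
    stack = np.stack([series.coords[lm] for lm in REQUIRED_LANDMARKS], axis=0)
    valid = np.all(np.isfinite(stack), axis=(0, 2))
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.warning("%s: skipped %d frame(s) with missing landmarks", series.subject_id, n_skipped)
    return series.frames[valid], stack[:, valid, :].mean(axis=0)


def detect_video_movements(
    series: LandmarkSeries,
    shift_thresh: float = 0.025,
    sustain_frames: int = 15,
) -> list[float]:
    """Movement onsets (seconds) from sustained center-of-mass shifts.

    Baseline-reset semantics mirroring the sensor detector: a candidate
    opens at the first frame whose Euclidean center-of-mass displacement
    from baseline exceeds ``shift_thresh`` (fraction of frame width) and
    is confirmed when the displacement stays above threshold for
    ``sustain_frames`` consecutive valid frames (onset frame included);
    the baseline then resets to the center at the confirming frame.
    """
    if series.fps <= 0:
        raise ValueError("fps must be positive")
    frames, com = center_of_mass_series(series)
    n = frames.size
    if n < sustain_frames:
        return []
    onsets: list[float] = []
    base = com[0]
    i = 1
    while i < n:
        if np.hypot(*(com[i] - base)) > shift_thresh:
            j = i
            run = 0
            confirmed = -1
            while j < n and np.hypot(*(com[j] - base)) > shift_thresh:
                run += 1
                if run >= sustain_frames:
                    confirmed = j
                    break
                j += 1
            if confirmed >= 0:
                onsets.append(float(frames[i]) / series.fps)
                base = com[confirmed]
                i = confirmed + 1
            else:
                i = max(j, i + 1)
        else:
            i += 1
    return onsets


def pearson_agreement(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson r between two equally binned count series.

    Returns NaN (with a log message) when either series has zero
    variance, where the coefficient is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("pearson_agreement: zero-variance series, r undefined")
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def fisher_aggregate(
    rs: Sequence[float],
    bin_counts: Sequence[int] | None = None,
    clamp: bool = False,
) -> AgreementResult:
    """Aggregate per-subject correlations on the Fisher z scale.

    Each r is mapped with z = atanh(r); the mean and its 95% CI
    (mean z +/- 1.96 * sd(z)/sqrt(k), sample sd) are mapped back with
    tanh.  With ``bin_counts`` given, inverse-variance pooling with
    per-subject standard error 1/sqrt(n - 3) is used instead — more
    stable for very small numbers of subjects.  ``clamp`` clips |r| = 1
    (perfect agreement on finite data) to 1 - 1e-7 instead of rejecting.
    """
    rs = [float(r) for r in rs]
    if len(rs) < 2:
        raise ValueError("need at least 2 subjects to aggregate")
    if any(abs(r) >= 1 for r in rs):
        if not clamp:
            raise ValueError(
                "correlation of magnitude 1 has infinite Fisher z; "
                "pass clamp=True to clip to 1 - 1e-7"
            )
        rs = [float(np.clip(r, -1 + 1e-7, 1 - 1e-7)) for r in rs]
    z = np.arctanh(rs)
    if bin_counts is not None:
        w = np.asarray(bin_counts, dtype=float) - 3.0
        if np.any(w <= 0):
            raise ValueError("inverse-variance pooling needs bin counts > 3")
        mean_z = float(np.sum(w * z) / np.sum(w))
        se = 1.0 / np.sqrt(np.sum(w))
    else:
        mean_z = float(np.mean(z))
        se = float(np.std(z, ddof=1) / np.sqrt(len(rs)))
    lo, hi = np.tanh(mean_z - 1.96 * se), np.tanh(mean_z + 1.96 * se)
    return AgreementResult(rs, float(np.tanh(mean_z)), (float(lo), float(hi)))


def read_landmarks(path, fps: float, subject_id: str | None = None, delimiter: str = ",") -> LandmarkSeries:
    """Read a ``frame,landmark,x,y`` delimited landmark file."""
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    for col in ("frame", "landmark", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"landmark file missing column {col!r}")
    frames = np.sort(df["frame"].unique())
    pos = {f: i for i, f in enumerate(frames)}
    coords = {lm: np.full((frames.size, 2), np.nan) for lm in REQUIRED_LANDMARKS}
    for lm, sub in df.groupby("landmark"):
        if lm not in coords:
            continue
        rows = sub["frame"].map(pos).to_numpy()
        coords[lm][rows, 0] = sub["x"].to_numpy()
        coords[lm][rows, 1] = sub["y"].to_numpy()
    sid = subject_id if subject_id is not None else _stem(path)
    return LandmarkSeries(sid, fps, frames, coords)


def write_landmarks(series: LandmarkSeries, path, delimiter: str = ",") -> None:
    rows = []
    for lm in REQUIRED_LANDMARKS:
        xy = series.coords[lm]
        for f, (x, y) in zip(series.frames, xy):
            rows.append((int(f), lm, x, y))
    df = pd.DataFrame(rows, columns=["frame", "landmark", "x", "y"])
    df.sort_values(["frame", "landmark"]).to_csv(path, sep=delimiter, index=False)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
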