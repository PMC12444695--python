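"""Synthetic sensor streams, cohorts, and paired landmark series.

Every stage of the toolkit is testable without patient data: this module
plants a known ground truth — repositioning onsets, sub-dwell transients,
discharge tails, covariate–mobility correlations, paired video landmark
shifts — and emits data in exactly the dialects the I/O layer reads.

The generator models a 1 Hz tilt stream as a piecewise-constant level on
each axis (baseline 0°) plus Gaussian sensor jitter.  A planted
repositioning is a simultaneous sustained step on both axes; a transient
"spike" is the same step reverting within less than the detector dwell,
so a correct detector must ignore it.  The acceleration channel rests at
1 g on the z axis (gravity) with short bursts at each event, which keeps
the motion-intensity statistics on a realistic scale.  Poisson event
onsets are thinned to a minimum inter-event gap of dwell + 5 s so the
planted truth is unambiguous.

Defaults describe a typical monitored inpatient stay: 10 h of recording
at 10 movements/hour with 5° repositioning steps, 0.1° sensor noise, and
5 sub-dwell transients per hour; cohorts of 44 patients whose movement
rates follow a lognormal law with median 7.2 movements/hour and whose
BMI–rate Spearman correlation is planted at 0.24.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sensor_io import SensorRecording
from .video_validation import REQUIRED_LANDMARKS, LandmarkSeries

DWELL = 10.0  # detector dwell the generator guarantees margins against
MIN_GAP = DWELL + 5.0

_LANDMARK_OFFSETS = {
    "nose": (0.0, -0.12),
    "left_shoulder": (-0.07, -0.05),
    "right_shoulder": (0.07, -0.05),
    "left_hip": (-0.06, 0.08),
    "right_hip": (0.06, 0.08),
}


class GenerationError(RuntimeError):
    """The requested stream spec cannot be realised (e.g. too dense)."""


@dataclass(frozen=True)
class StreamSpec:
    """Ground-truth parameters for one synthetic sensor stream."""

    duration_h: float = 10.0
    event_rate: float = 10.0        # movements per hour
    event_step: float = 5.0         # degrees, on both axes
    spike_rate: float = 5.0         # sub-dwell transients per hour
    spike_duration: float = 3.0     # seconds, strictly < dwell
    noise_sd: float = 0.1           # degrees
    accel_burst: float = 0.5        # g added at events
    accel_noise_sd: float = 0.02    # g
    discharge_tail_h: float = 0.0   # flat empty-bed tail appended
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spike_duration >= DWELL:
            raise ValueError("spikes must revert in under the detector dwell")


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth parameters for a synthetic patient cohort."""

    n_patients: int = 44
    rho_bmi_rate: float = 0.24      # planted Spearman correlation
    rate_median: float = 7.2        # movements/hour, lognormal median
    rate_log_sigma: float = 0.75
    bmi_median: float = 28.5        # kg/m^2, lognormal median
    bmi_log_sigma: float = 0.18
    duration_median_h: float = 20.0
    duration_log_sigma: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("cohort needs at least 2 patients")
        if not -1 < self.rho_bmi_rate < 1:
            raise ValueError("planted rho must lie in (-1, 1)")


def _place_onsets(rng, n_samples: int, n_events: int, margin: float) -> np.ndarray:
    """Sorted integer onsets with pairwise gaps >= MIN_GAP, away from ends.

    Uses the uniform-spacing transform: sorted draws from a shrunken
    interval plus a deterministic offset of i * MIN_GAP, which yields a
    uniform sample conditioned on the minimum-gap constraint.
    """
    lo, hi = int(margin), n_samples - 1 - int(margin)
    if n_events == 0:
        return np.empty(0, dtype=int)
    gap = int(MIN_GAP)
    span = hi - lo - (n_events - 1) * gap
    if span <= 0:
        raise GenerationError("event rate too high for stream duration")
    cand = np.sort(rng.integers(lo, lo + span + 1, size=n_events))
    return cand + gap * np.arange(n_events)


def gen_sensor_stream(
    spec: StreamSpec, patient_id: str = "synthetic"
) -> tuple[SensorRecording, np.ndarray]:
    """Generate one 1 Hz stream; returns (recording, planted onset times)."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_h * 3600)) + 1
    onsets = _place_onsets(
        rng, n, rng.poisson(spec.event_rate * spec.duration_h), margin=DWELL + 5
    )

    angle = np.zeros(n)
    pitch = np.zeros(n)
    levels = {"angle": 0.0, "pitch": 0.0}
    for T in onsets:
        for name, arr in (("angle", angle), ("pitch", pitch)):
            sign = rng.choice((-1.0, 1.0))
            if abs(levels[name] + sign * spec.event_step) > 30.0:
                sign = -sign
            arr[T:] += sign * spec.event_step
            levels[name] += sign * spec.event_step

    # sub-dwell transients, kept clear of every event's dwell window
    n_spikes = rng.poisson(spec.spike_rate * spec.duration_h)
    spike_len = int(round(spec.spike_duration))
    spikes: list[int] = []
    guard = MIN_GAP
    tries = 0
    while len(spikes) < n_spikes and tries < 50 * max(n_spikes, 1):
        tries += 1
        s = int(rng.integers(1, n - spike_len - 1))
        if onsets.size and np.min(np.abs(onsets - s)) <= guard:
            continue
        if any(abs(s - q) <= spike_len + 2 for q in spikes):
            continue
        spikes.append(s)
    for s in spikes:
        sgn = rng.choice((-1.0, 1.0))
        angle[s : s + spike_len] += sgn * spec.event_step
        pitch[s : s + spike_len] += sgn * spec.event_step

    if spec.noise_sd > 0:
        angle = angle + rng.normal(0.0, spec.noise_sd, n)
        pitch = pitch + rng.normal(0.0, spec.noise_sd, n)

    ax = rng.normal(0.0, spec.accel_noise_sd, n)
    ay = rng.normal(0.0, spec.accel_noise_sd, n)
    az = 1.0 + rng.normal(0.0, spec.accel_noise_sd, n)
    for T in onsets:
        ax[T : T + 3] += spec.accel_burst

    if spec.discharge_tail_h > 0:
        m = int(round(spec.discharge_tail_h * 3600))
        angle = np.concatenate([angle, np.full(m, angle[-1])])
        pitch = np.concatenate([pitch, np.full(m, pitch[-1])])
        ax = np.concatenate([ax, np.full(m, ax[-1])])
        ay = np.concatenate([ay, np.full(m, ay[-1])])
        az = np.concatenate([az, np.full(m, az[-1])])
        n += m

    t = np.arange(n, dtype=float)
    rec = SensorRecording(
        patient_id, t,
        np.clip(angle, -90, 90), np.clip(pitch, -90, 90),
        ax, ay, az,
    )
    return rec, onsets.astype(float)


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict[str, StreamSpec]]:
    """Generate a covariate table plus per-patient stream specs.

    BMI and the true movement rate share a Gaussian copula whose Pearson
    parameter ``2 sin(pi * rho_s / 6)`` plants the requested Spearman
    correlation exactly at the population level; both marginals are
    lognormal.  Other covariates follow plausible inpatient
    distributions and are independent of mobility.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    r = 2.0 * np.sin(np.pi * spec.rho_bmi_rate / 6.0)
    z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
    u = stats.norm.cdf(z)
    bmi = spec.bmi_median * np.exp(spec.bmi_log_sigma * stats.norm.ppf(u[:, 0]))
    rate = spec.rate_median * np.exp(spec.rate_log_sigma * stats.norm.ppf(u[:, 1]))

    braden_w = (0.05, 0.15, 0.35, 0.45)
    sub = rng.choice([1, 2, 3, 4], size=(n, 6), p=braden_w)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "age": np.clip(np.round(rng.normal(63, 17, n)), 18, 100).astype(int),
            "sex": rng.choice(["F", "M"], size=n),
            "bmi": np.round(bmi, 1),
            "comorbid_count": rng.poisson(8.8, n),
            "braden_total": sub.sum(axis=1),
            "braden_sensory": sub[:, 0],
            "braden_activity": sub[:, 1],
            "braden_mobility": sub[:, 2],
            "service": rng.choice(
                ["medicine", "cardiology", "surgery"], size=n, p=[0.45, 0.35, 0.20]
            ),
        }
    )
    dur = spec.duration_median_h * np.exp(rng.normal(0, spec.duration_log_sigma, n))
    dur = np.clip(dur, 1.5, 53.0)
    truths = {
        row.patient_id: StreamSpec(
            duration_h=float(dur[i]),
            event_rate=float(rate[i]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i, row in enumerate(df.itertuples())
    }
    return df, truths


def gen_landmark_pair(
    stream_truth: Sequence[float],
    duration_s: float,
    fps: float = 15.0,
    disp_step: float = 0.05,
    jitter_sd: float = 0.003,
    subject_id: str = "synthetic",
    seed: int = 0,
) -> LandmarkSeries:
    """Landmark series sharing an event schedule with a sensor stream.

    The body's center of mass steps by ``disp_step`` (fraction of frame
    width) at each planted onset, staying within the central region of
    the frame; each landmark carries independent Gaussian jitter.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fps)) + 1
    frames = np.arange(n_frames)
    com = np.zeros((n_frames, 2))
    pos = np.array([0.5, 0.5])
    onset_frames = [int(round(T * fps)) for T in sorted(stream_truth)]
    next_idx = 0
    for f in range(n_frames):
        if next_idx < len(onset_frames) and f == onset_frames[next_idx]:
            theta = rng.uniform(0, 2 * np.pi)
            step = disp_step * np.array([np.cos(theta), np.sin(theta)])
            cand = pos + step
            pos = pos - step if np.any(np.abs(cand - 0.5) > 0.2) else cand
            next_idx += 1
        com[f] = pos
    coords = {
        lm: com + np.asarray(off) + rng.normal(0, jitter_sd, (n_frames, 2))
        for lm, off in _LANDMARK_OFFSETS.items()
    }
    return LandmarkSeries(subject_id, fps, frames, coords)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2^31) from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
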