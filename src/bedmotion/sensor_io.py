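"""Reading, validation, and cleaning of raw mattress-sensor streams.

A bedside sensor samples mattress tilt at a nominal 1 Hz and reports two
tilt axes — ``angle`` (X-axis) and ``pitch`` (Y-axis), both in degrees —
plus the three acceleration components in units of g.  This module owns
the on-disk dialect for those logs, the cohort table of patient
covariates, and the two cleaning steps applied before any analysis:

* truncation of the "discharge tail", the terminal stretch of exactly
  flat readings left behind when the bed is empty after discharge, and
* exclusion of recordings shorter than a minimum duration.

Timestamps are elapsed seconds from recording start.  Gaps (missing
seconds) are preserved, never interpolated; downstream dwell logic works
in elapsed time so gaps do not corrupt event detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SENSOR_COLUMNS = ("t", "angle", "pitch", "ax", "ay", "az")

COHORT_COLUMNS = (
    "patient_id", "age", "sex", "bmi", "comorbid_count",
    "braden_total", "braden_sensory", "braden_activity", "braden_mobility",
    "service",
)


class SensorFormatError(ValueError):
    """A sensor log does not conform to the expected column layout."""


class SensorDataError(ValueError):
    """A sensor log parses but violates a data invariant (e.g. time order)."""


class SensorSample(NamedTuple):
    """One 1 Hz reading: elapsed time, tilt on both axes, acceleration."""

    t: float
    angle: float
    pitch: float
    ax: float
    ay: float
    az: float


@dataclass
class Dialect:
    """Column mapping and parsing options for delimited sensor logs.

    ``columns`` maps the six canonical field names to the header names in
    the file.  ``time`` is either ``"seconds"`` (elapsed seconds, the
    canonical form) or ``"iso"`` (ISO-8601 wall-clock timestamps, converted
    to elapsed seconds from the first row on read).
    """

    delimiter: str = ","
    columns: dict = field(default_factory=lambda: {c: c for c in SENSOR_COLUMNS})
    time: str = "seconds"


@dataclass
class SensorRecording:
    """One patient's ordered tilt/acceleration stream.

    Columns are stored as 1-D float arrays of equal length.  Invariants
    (checked on construction): strictly increasing ``t``; finite angle and
    pitch within [-90, 90].
    """

    patient_id: str
    t: np.ndarray
    angle: np.ndarray
    pitch: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    nominal_rate: float = 1.0

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, c), dtype=float) for c in SENSOR_COLUMNS]
        n = arrays[0].shape[0]
        if any(a.shape != (n,) for a in arrays):
            raise SensorDataError("all sensor columns must be 1-D and equal length")
        for name, a in zip(SENSOR_COLUMNS, arrays):
            setattr(self, name, a)
        if n > 1:
            dt = np.diff(self.t)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise SensorDataError(
                    f"timestamps not strictly increasing at row {bad[0] + 1} "
                    f"(t={self.t[bad[0] + 1]!r} after t={self.t[bad[0]]!r})"
                )
        for axis in ("angle", "pitch"):
            v = getattr(self, axis)
            if v.size and (not np.all(np.isfinite(v)) or np.any(np.abs(v) > 90)):
                raise SensorDataError(f"{axis} values must be finite and within [-90, 90]")

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration(self) -> float:
        """Recording span in seconds (last t minus first t); 0 if < 2 samples."""
        return float(self.t[-1] - self.t[0]) if self.n_samples >= 2 else 0.0

    @property
    def duration_hours(self) -> float:
        return self.duration / 3600.0

    def sample(self, i: int) -> SensorSample:
        return SensorSample(*(float(getattr(self, c)[i]) for c in SENSOR_COLUMNS))

    def slice(self, start: int, stop: int) -> "SensorRecording":
        return SensorRecording(
            self.patient_id,
            *(getattr(self, c)[start:stop].copy() for c in SENSOR_COLUMNS),
            nominal_rate=self.nominal_rate,
        )


def read_stream(path, dialect: Dialect | None = None, patient_id: str | None = None) -> SensorRecording:
    """Read and validate a delimited sensor log.

    Rows with any non-finite value are dropped (count logged).  Missing
    columns raise :class:`SensorFormatError`; non-monotone timestamps
    raise :class:`SensorDataError` naming the first offending row.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.delimiter, float_precision="round_trip")
    missing = [c for c in SENSOR_COLUMNS if dialect.columns[c] not in df.columns]
    if missing:
        raise SensorFormatError(f"missing column(s) {missing} in {path}")
    df = df.rename(columns={v: k for k, v in dialect.columns.items()})[list(SENSOR_COLUMNS)]
    if dialect.time == "iso":
        ts = pd.to_datetime(df["t"])
        df["t"] = (ts - ts.iloc[0]).dt.total_seconds()
    df = df.apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(df.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with non-finite values", path, n_dropped)
        df = df[finite]
    pid = patient_id if patient_id is not None else _infer_patient_id(path)
    return SensorRecording(pid, *(df[c].to_numpy(dtype=float) for c in SENSOR_COLUMNS))


def _infer_patient_id(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_stream(rec: SensorRecording, path, dialect: Dialect | None = None) -> None:
    """Write a recording in the canonical dialect (exact float round trip)."""
    dialect = dialect or Dialect()
    df = pd.DataFrame({dialect.columns[c]: getattr(rec, c) for c in SENSOR_COLUMNS})
    df.to_csv(path, sep=dialect.delimiter, index=False)


def truncate_discharge_tail(
    rec: SensorRecording,
    window: float = 300.0,
    eps: float = 0.01,
    min_tail: float = 1800.0,
) -> SensorRecording:
    """Drop the terminal empty-bed segment of a recording.

    Identifies the maximal terminal run in which every right-aligned
    rolling window of ``window`` samples (1 Hz nominal, so seconds) has a
    standard deviation below ``eps`` degrees in *both* angle and pitch.
    The run is removed only if it spans at least ``min_tail`` seconds;
    otherwise the recording is returned unchanged.  Idempotent on any
    recording whose retained portion carries normal sensor noise.
    """
    n = rec.n_samples
    w = int(round(window))
    if n < w or n == 0:
        return rec
    std_a = pd.Series(rec.angle).rolling(w).std(ddof=0).to_numpy()
    std_p = pd.Series(rec.pitch).rolling(w).std(ddof=0).to_numpy()
    ok = (std_a < eps) & (std_p < eps)  # window ending at i is quiet
    bad = np.nonzero(~ok[w - 1:])[0]
    if bad.size == 0:
        start = 0
    else:
        last_bad_end = bad[-1] + (w - 1)
        if last_bad_end == n - 1:
            return rec  # tail is not quiet at all
        start = last_bad_end - w + 2  # first sample whose every window is quiet
    if start >= n:
        return rec
    tail_span = rec.t[-1] - rec.t[start]
    if tail_span < min_tail:
        return rec
    logger.info(
        "%s: truncated %.0f s discharge tail (%d samples)",
        rec.patient_id, tail_span, n - start,
    )
    return rec.slice(0, start)


def exclude_short(
    recs: Sequence[SensorRecording], min_hours: float = 1.0
) -> tuple[list[SensorRecording], list[SensorRecording]]:
    """Partition recordings into (kept, excluded) by duration.

    A recording is excluded when it spans strictly less than ``min_hours``
    (a recording of exactly the minimum is kept).  Order is preserved and
    samples are never modified.
    """
    kept, excluded = [], []
    for rec in recs:
        (kept if rec.duration_hours >= min_hours else excluded).append(rec)
    return kept, excluded


def read_cohort(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a cohort covariate table; validates the canonical columns."""
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SensorFormatError(f"cohort table missing column(s) {missing}")
    sub = df[["braden_sensory", "braden_activity", "braden_mobility"]]
    if ((sub < 1) | (sub > 4)).any().any():
        raise SensorDataError("Braden sub-scores must lie in [1, 4]")
    if (df["bmi"] <= 0).any():
        raise SensorDataError("BMI must be positive")
    return df


def write_cohort(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False)
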