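"""Retrospective immobility alerting and the time-since-last-movement matrix.

Hospital repositioning protocols call for turning at-risk patients at
least every four hours.  This module simulates the notifications such a
protocol would have produced from the detected movement record: an alert
fires when a patient accumulates a continuous movement-free interval of
at least the threshold (default 4 h = 14 400 s), and re-arms only after a
subsequent movement.  The immobility clock starts at recording start, so
a patient who never moves still alerts.

The block matrix aggregates time-since-last-movement into 15-minute
blocks per patient — the data behind the cohort immobility heat map.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import json

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Alert:
    """A simulated immobility notification."""

    patient_id: str
    trigger_t: float
    index: int  # 1-based ordinal within the patient


def time_since_last_movement(onsets: Sequence[float], t: float) -> float:
    """Seconds elapsed at time ``t`` since the latest movement onset <= t.

    With no prior movement the clock runs from recording start (time 0).
    """
    if t < 0:
        raise ValueError("t must lie within the recording span (t >= 0)")
    onsets = sorted(onsets)
    i = bisect_right(onsets, t)
    last = onsets[i - 1] if i > 0 else 0.0
    return t - last


def simulate_alerts(
    onsets: Sequence[float],
    duration: float,
    threshold: float = 14400.0,
    patient_id: str = "",
) -> list[Alert]:
    """One alert per maximal movement-free interval of length >= threshold.

    Intervals are delimited by recording start, each movement onset, and
    recording end.  The alert triggers at interval start + threshold.  No
    interval produces more than one alert; a further alert requires an
    intervening movement followed by another qualifying interval.
    """
    onsets = sorted(float(o) for o in onsets)
    if onsets and (onsets[0] < 0 or onsets[-1] > duration):
        raise ValueError("onsets must lie within [0, duration]")
    bounds = [0.0] + onsets + [float(duration)]
    alerts: list[Alert] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s >= threshold:
            alerts.append(Alert(patient_id, s + threshold, len(alerts) + 1))
    return alerts


def immobility_matrix(
    cohort_onsets: Mapping[str, Sequence[float]],
    durations: Mapping[str, float],
    block: float = 900.0,
) -> pd.DataFrame:
    """Mean time-since-last-movement per patient per time block.

    Rows are patients, columns block start times in seconds.  Entry
    ``(p, k)`` is the mean of time-since-last-movement over the integer
    seconds in ``[k*block, min((k+1)*block, duration_p))``.  Blocks past a
    patient's recording end are NaN.
    """
    n_blocks = max(int(np.ceil(durations[p] / block)) for p in cohort_onsets)
    cols = [int(k * block) for k in range(n_blocks)]
    rows = {}
    for pid, ons in cohort_onsets.items():
        dur = int(np.floor(durations[pid]))
        t = np.arange(dur, dtype=float)
        ons_arr = np.asarray(sorted(ons), dtype=float)
        if ons_arr.size:
            idx = np.searchsorted(ons_arr, t, side="right")
            last = np.where(idx > 0, ons_arr[np.maximum(idx - 1, 0)], 0.0)
        else:
            last = np.zeros_like(t)
        tsl = t - last
        vals = np.full(n_blocks, np.nan)
        for k in range(n_blocks):
            lo, hi = int(k * block), min(int((k + 1) * block), dur)
            if hi > lo:
                vals[k] = tsl[lo:hi].mean()
        rows[pid] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def alert_blocks(alerts: Sequence[Alert], block: float = 900.0) -> dict[str, list[int]]:
    """Map each patient to the block indices in which its alerts trigger."""
    out: dict[str, list[int]] = {}
    for a in alerts:
        out.setdefault(a.patient_id, []).append(int(a.trigger_t // block))
    return out


def write_alerts(alerts: Sequence[Alert], path) -> None:
    with open(path, "w") as fh:
        for a in alerts:
            fh.write(
                json.dumps({"patient_id": a.patient_id, "trigger_t": a.trigger_t, "index": a.index})
                + "\n"
            )


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index_label="patient_id")


def plot_heatmap(matrix: pd.DataFrame, alerts: Sequence[Alert] = (), block: float = 900.0, path=None):
    """Render the immobility matrix as a heat map, asterisks at alerts.

    Thin presentation layer; the CSV matrix is the canonical artifact.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 0.3 * len(matrix) + 2))
    hours = matrix.to_numpy() / 3600.0
    im = ax.imshow(hours, aspect="auto", cmap="inferno", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="time since last movement (h)")
    row_of = {pid: i for i, pid in enumerate(matrix.index)}
    for pid, blocks in alert_blocks(alerts, block).items():
        for b in blocks:
            if pid in row_of and b < matrix.shape[1]:
                ax.text(b, row_of[pid], "*", ha="center", va="center", color="cyan")
    ax.set_yticks(range(len(matrix)), matrix.index)
    ax.set_xlabel(f"{int(block)}-s block index")
    ax.set_ylabel("patient")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
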