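"""Run configuration shared by the command-line pipeline.

Defaults are the deployed algorithm's operating point: 2° angle and 2°
pitch thresholds with a 10 s dwell, a 4 h immobility alert threshold,
60 s validation bins, 10-minute intensity windows, 15-minute heat-map
blocks, 10 000 permutations and 1 000 bootstrap resamples.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    angle_thresh: float = 2.0
    pitch_thresh: float = 2.0
    dwell: float = 10.0
    alert_threshold: float = 14400.0
    bin: float = 60.0
    intensity_window: float = 600.0
    block: float = 900.0
    n_perm: int = 10000
    n_boot: int = 1000
    tail_window: float = 300.0
    tail_eps: float = 0.01
    tail_min: float = 1800.0
    min_hours: float = 1.0
    fps: float = 15.0
    shift_thresh: float = 0.025
    sustain_frames: int = 15

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        """Build from an optional YAML file; keyword overrides win."""
        values = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(data) - known
            if unknown:
                raise ValueError(f"unknown config key(s): {sorted(unknown)}")
            values.update(data)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict:
        return asdict(self)
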