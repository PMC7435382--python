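"""Timestamped physical signal containers.

A trace is a pair of equal-length arrays (times in seconds, values in a
physical unit) plus sampling metadata.  Pressure is carried in pascals,
airflow in litres per second with expiration positive.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Trace", "PressureTrace", "FlowTrace", "ConditionedPair"]


@dataclass
class Trace:
    """A uniformly- or irregularly-sampled scalar time series."""

    times: np.ndarray
    values: np.ndarray
    sample_rate: float | None = None
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("trace times and values must be 1-D arrays")
        if self.times.size != self.values.size:
            raise ValueError(
                f"length mismatch: {self.times.size} times vs {self.values.size} values"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError(f"trace times must be strictly increasing (label={self.label!r})")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def with_values(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class PressureTrace(Trace):
    units: str = "Pa"


@dataclass
class FlowTrace(Trace):
    units: str = "L/s"


@dataclass
class ConditionedPair:
    """Offset-corrected differential pressure and reference flow on a shared grid.

    ``dp`` is the smoothed inside-minus-outside mask pressure (Pa) and
    ``flow`` the offset-corrected reference flow (L/s); both live on the
    uniform ``grid_times`` (default spacing 10 ms).  These are the (x, y)
    samples the calibration models are fitted on.
    """

    grid_times: np.ndarray
    dp: np.ndarray
    flow: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid_times = np.asarray(self.grid_times, dtype=float)
        self.dp = np.asarray(self.dp, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if not (self.grid_times.size == self.dp.size == self.flow.size):
            raise ValueError("conditioned pair arrays must have equal lengths")

    def __len__(self) -> int:
        return int(self.grid_times.size)
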