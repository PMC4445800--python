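"""Uniformly sampled motion time series.

A :class:`Trace` is the common currency between the simulator, the motion
tracker and the period estimator: a strictly increasing, uniformly spaced
time grid in hours and one value per time point (vertical motion, in
pixels per frame step, or arbitrary simulated units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trace", "read_trace_csv", "write_trace_csv"]

#: Minimum number of samples for a trace to be analyzable at all.
MIN_SAMPLES = 8

#: Relative tolerance on time-grid uniformity.
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled time series.

    Parameters
    ----------
    times
        Sample times in hours, strictly increasing with a constant step
        equal to ``sampling_interval`` minutes.
    values
        One finite value per time point.
    sampling_interval
        Sampling interval in minutes.
    plant_id
        Optional identifier carried through the pipeline.
    """

    times: np.ndarray
    values: np.ndarray
    sampling_interval: float
    plant_id: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size < MIN_SAMPLES:
            raise ValueError(
                f"trace needs at least {MIN_SAMPLES} samples, got {times.size}"
            )
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(times)):
            raise ValueError("trace contains non-finite entries")
        step_h = self.sampling_interval / 60.0
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(diffs, step_h, rtol=_GRID_RTOL, atol=1e-9):
            raise ValueError(
                "time grid is not uniform at the stated sampling interval"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration_hours(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def step_hours(self) -> float:
        return self.sampling_interval / 60.0

    def with_values(self, values: np.ndarray) -> "Trace":
        """Copy of this trace with the same grid and new values."""
        return Trace(self.times, values, self.sampling_interval, self.plant_id)


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    """Write a trace as a two-column CSV (time_hours, value)."""
    df = pd.DataFrame({"time_hours": trace.times, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.10g")


def read_trace_csv(
    path: str | Path,
    sampling_interval: float | None = None,
    plant_id: str | None = None,
) -> Trace:
    """Read a two-column trace CSV.

    When ``sampling_interval`` is omitted it is inferred from the time grid.
    """
    df = pd.read_csv(path)
    if not {"time_hours", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_hours,value")
    times = df["time_hours"].to_numpy(dtype=float)
    if sampling_interval is None:
        if times.size < 2:
            raise ValueError(f"{path}: cannot infer sampling interval")
        sampling_interval = float(np.median(np.diff(times)) * 60.0)
    if plant_id is None:
        plant_id = Path(path).stem
    return Trace(times, df["value"].to_numpy(dtype=float), sampling_interval, plant_id)
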