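"""Summaries of cooking time-temperature logs.

Two metrics explain how a cooking method exposes the tissue to the window
in which endogenous pectinmethylesterase is active (roughly 50-80 degC) and
to the inactivating range above it:

* ``traverse_time`` — minutes spent climbing from 40 to 80 degC (first
  upward crossings, linearly interpolated between the 10-s samples);
* ``time_above`` — total interpolated minutes spent above a threshold
  (default 80 degC), summed over all supra-threshold intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TemperatureProfile", "traverse_time", "time_above"]


@dataclass(frozen=True)
class TemperatureProfile:
    """A uniformly sampled temperature log (time in s, temperature in degC)."""

    time: np.ndarray
    temp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        T = np.asarray(self.temp, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "temp", T)
        if t.ndim != 1 or t.shape != T.shape or t.size < 2:
            raise ValueError("time and temp must be equally long 1-D arrays")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling cadence must be uniform")


def _first_upward_crossing(profile: TemperatureProfile, threshold: float) -> float:
    """Time (s) of the first upward crossing of ``threshold``.

    A profile that starts at or above the threshold is taken to cross it at
    the first sample (a step to the plateau therefore has zero traverse time).
    """
    T = profile.temp
    t = profile.time
    if T[0] >= threshold:
        return float(t[0])
    below = T[:-1] < threshold
    reaches = T[1:] >= threshold
    idx = np.flatnonzero(below & reaches)
    if idx.size == 0:
        raise ValueError(f"profile never crosses {threshold} degC upward")
    i = int(idx[0])
    frac = (threshold - T[i]) / (T[i + 1] - T[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def traverse_time(profile: TemperatureProfile, T_low: float = 40.0, T_high: float = 80.0) -> float:
    """Minutes between the first upward crossings of T_low and T_high."""
    if T_high <= T_low:
        raise ValueError("T_high must exceed T_low")
    t_low = _first_upward_crossing(profile, T_low)
    t_high = _first_upward_crossing(profile, T_high)
    return (t_high - t_low) / 60.0


def time_above(profile: TemperatureProfile, T: float = 80.0) -> float:
    """Total minutes with temperature above ``T``, interpolating at crossings.

    All supra-threshold intervals are summed, so oscillating profiles are
    handled; a profile that never exceeds ``T`` returns 0.
    """
    t = profile.time
    temp = profile.temp
    total = 0.0
    for i in range(t.size - 1):
        T0, T1 = temp[i], temp[i + 1]
        dt = t[i + 1] - t[i]
        if T0 > T and T1 > T:
            total += dt
        elif T0 > T and T1 <= T:
            total += dt * (T0 - T) / (T0 - T1)
        elif T0 <= T and T1 > T:
            total += dt * (T1 - T) / (T1 - T0)
    return float(total / 60.0)
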