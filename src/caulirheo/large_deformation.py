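"""Macroscopic texture descriptors from uniaxial compression curves.

Cooked floret compression to 50% deformation produces a yield-free,
upward-concave load-displacement curve (strain hardening).  Two descriptors
summarize it: stiffness (N/mm), the load at 0.5 deformation divided by the
maximum displacement, and strain energy release (N mm), the integral of the
load over displacement from the preload threshold to 0.5 deformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CompressionCurve", "stiffness", "strain_energy_release"]

_DEFORMATION_TOL = 1e-6


@dataclass(frozen=True)
class CompressionCurve:
    """Load vs displacement for one specimen.

    ``height_mm`` is the initial specimen height, needed to map displacement
    to the deformation fraction d/height; the test protocol stops loading at
    0.5 deformation, so the final displacement should correspond to it.
    """

    displacement: np.ndarray  # mm, increasing from 0
    load: np.ndarray  # N
    height_mm: float
    preload: float = 5.0  # N

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.load, dtype=float)
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "load", f)
        if d.ndim != 1 or d.shape != f.shape or d.size < 2:
            raise ValueError("displacement and load must be equally long 1-D arrays")
        if d[0] != 0 or np.any(np.diff(d) <= 0):
            raise ValueError("displacement must be strictly increasing from 0")
        if np.any(f < 0):
            raise ValueError("load must be nonnegative")
        if not self.height_mm > 0:
            raise ValueError("height_mm must be positive")

    def deformation_at(self, d) -> np.ndarray:
        """Deformation fraction of the initial height at displacement d."""
        return np.asarray(d, dtype=float) / self.height_mm


def _require_half_deformation(curve: CompressionCurve) -> None:
    if curve.deformation_at(curve.displacement[-1]) < 0.5 - _DEFORMATION_TOL:
        raise ValueError(
            "curve does not reach 0.5 deformation "
            f"(max {float(curve.deformation_at(curve.displacement[-1])):.3f})"
        )


def stiffness(curve: CompressionCurve) -> float:
    """Load at 0.5 deformation (the maximum displacement) over that displacement, N/mm."""
    _require_half_deformation(curve)
    return float(curve.load[-1] / curve.displacement[-1])


def strain_energy_release(curve: CompressionCurve) -> float:
    """Trapezoidal integral of load over displacement, N mm.

    Integration starts at the first sample at or above the preload (the
    sub-preload region is instrument seating, not tissue response) and ends
    at 0.5 deformation.
    """
    _require_half_deformation(curve)
    above = np.flatnonzero(curve.load >= curve.preload)
    if above.size == 0:
        raise ValueError(f"load never reaches the preload of {curve.preload} N")
    i0 = int(above[0])
    if i0 >= curve.displacement.size - 1:
        raise ValueError("no integrable range above the preload")
    return float(np.trapezoid(curve.load[i0:], curve.displacement[i0:]))
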