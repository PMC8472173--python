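"""Microstructure-related descriptors derived from creep/recovery curves.

Five groups of quantities summarize a fitted creep test:

* ``Ur`` — integrated compliance (s/kPa), the area under J(t) from 0 to load
  removal; a cumulative softening measure.
* ``JR`` — total reversible compliance J0 + sum Ji (kPa^-1).
* compliance fractions J0/Ur, sum Ji/Ur, JN/Ur — relative elastic,
  viscoelastic and plastic contributions (reported as literal ratios with
  their mixed units).
* ``ERA`` — elastic recovery ability, 100 (Jmax - Jeq)/Jmax in percent:
  100 means the microstructure recovers its elasticity completely after
  unloading, 0 means the deformation is entirely permanent.
* ``EPR`` — elastic-to-viscoplastic ratio (J0 + sum Ji)/JN, a score for the
  prevalence of cell-wall loosening over cell-to-cell separation.

``E0 = 1/J0`` (kPa) and ``EtaN = 1/JN`` (kPa s) are reciprocal moduli used
as supplementary variables in the multivariate stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .creep_model import BurgersParams, CreepCurve, CreepFit

__all__ = [
    "DescriptorSet",
    "integrated_compliance",
    "reversible_compliance",
    "compliance_fractions",
    "recovery_extremes",
    "elastic_recovery_ability",
    "elastic_plastic_ratio",
    "derived_moduli",
    "compute_descriptors",
]


@dataclass(frozen=True)
class DescriptorSet:
    Ur: float  # s/kPa
    JR: float  # kPa^-1
    fractions: tuple[float, float, float]  # (J0/Ur, sum Ji/Ur, JN/Ur)
    Jmax: float  # kPa^-1
    Jeq: float  # kPa^-1
    ERA: float  # %
    EPR: float  # score
    E0: float  # kPa
    EtaN: float  # kPa s

    def __post_init__(self) -> None:
        if not self.Ur > 0:
            raise ValueError("Ur must be positive")
        if not 0.0 <= self.ERA <= 100.0:
            raise ValueError(f"ERA must be within [0, 100], got {self.ERA}")
        if self.Jeq > self.Jmax:
            raise ValueError("Jeq cannot exceed Jmax")


def integrated_compliance(curve: CreepCurve) -> float:
    """Trapezoidal integral of J(t) over the loading segment [0, t_unload]."""
    t = curve.loading_time
    J = curve.loading_compliance
    if t.size < 2:
        raise ValueError("loading segment too short to integrate")
    return float(np.trapezoid(J, t))


def reversible_compliance(params: BurgersParams) -> float:
    """JR = J0 + sum of the retarded compliances (independent of the RTi)."""
    return float(params.J0 + params.sum_Ji)


def compliance_fractions(params: BurgersParams, Ur: float) -> tuple[float, float, float]:
    """Relative elastic, viscoelastic and plastic contributions to softening."""
    if not Ur > 0:
        raise ValueError("Ur must be positive")
    return (params.J0 / Ur, params.sum_Ji / Ur, params.JN / Ur)


def recovery_extremes(curve: CreepCurve, tail_fraction: float = 0.05) -> tuple[float, float]:
    """(Jmax, Jeq): peak compliance under load and the equilibrium deformation.

    Jeq is the mean compliance over the final ``tail_fraction`` of the
    recovery segment (averaging suppresses sampling noise at the "end of the
    recovery step").
    """
    if not curve.loading_mask.any():
        raise ValueError("curve has no loading segment")
    rec = curve.recovery_compliance
    if rec.size == 0:
        raise ValueError("curve has no recovery segment; Jeq is undefined")
    Jmax = float(curve.loading_compliance.max())
    n_tail = max(int(np.ceil(tail_fraction * rec.size)), 1)
    Jeq = float(rec[-n_tail:].mean())
    return Jmax, Jeq


def elastic_recovery_ability(Jmax: float, Jeq: float) -> float:
    """ERA = 100 (Jmax - Jeq)/Jmax, in percent of recovered elasticity."""
    if not Jmax > 0:
        raise ValueError("Jmax must be positive")
    if Jeq < 0 or Jeq > Jmax:
        raise ValueError(
            f"Jeq={Jeq} outside [0, Jmax={Jmax}]; check the loading/recovery segmentation"
        )
    return float(100.0 * (Jmax - Jeq) / Jmax)


def elastic_plastic_ratio(params: BurgersParams) -> float:
    """EPR = (J0 + sum Ji)/JN."""
    if params.JN == 0:
        raise ValueError("EPR is infinite for JN = 0 (no viscoplastic flow)")
    return float((params.J0 + params.sum_Ji) / params.JN)


def derived_moduli(params: BurgersParams) -> tuple[float, float]:
    """(E0, EtaN) = (1/J0, 1/JN), the reciprocal instantaneous modulus and
    steady-state viscosity."""
    if params.J0 == 0 or params.JN == 0:
        raise ValueError("E0/EtaN undefined for zero J0 or JN")
    return float(1.0 / params.J0), float(1.0 / params.JN)


def compute_descriptors(curve: CreepCurve, fit: CreepFit) -> DescriptorSet:
    """Assemble the full descriptor set for one specimen."""
    Ur = integrated_compliance(curve)
    JR = reversible_compliance(fit.params)
    fractions = compliance_fractions(fit.params, Ur)
    Jmax, Jeq = recovery_extremes(curve)
    Jeq = min(max(Jeq, 0.0), Jmax)  # guard tiny noise excursions at the tail
    ERA = elastic_recovery_ability(Jmax, Jeq)
    EPR = elastic_plastic_ratio(fit.params)
    E0, EtaN = derived_moduli(fit.params)
    return DescriptorSet(
        Ur=Ur, JR=JR, fractions=fractions, Jmax=Jmax, Jeq=Jeq, ERA=ERA, EPR=EPR, E0=E0, EtaN=EtaN
    )
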