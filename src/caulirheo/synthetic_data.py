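"""Synthetic instrument and chemistry data for the full analysis pipeline.

Real creep rigs, texture analyzers, temperature loggers and chromatography
produce the inputs this package consumes; none of those measurements are
redistributable, so this module generates statistically faithful stand-ins:

* creep/recovery compliance curves following the tailored Burgers model
  under the study's 100 N / 600 s hold + 600 s recovery schedule;
* strain-hardening (power-law) compression curves to 0.5 deformation;
* first-order-approach heating profiles for boiling (B), steaming (S) and
  sous-vide (SV), sampled every 10 s, with rise rates calibrated so the
  40->80 degC traverse matches the reported 1.83 / 2.67 / 5.5 min ordering;
* a joined study dataset: per-replicate ERA drawn from a first-order decay
  trajectory, a V-shaped EPR companion trajectory (minimum at 10 min of
  heating), bounded increasing water uptake, and sterol/tocopherol totals
  linearly linked to (ERA, EPR) with multiplicative noise.  Ground-truth
  parameters are returned alongside for recovery tests.

All generators are deterministic under a fixed seed.  Noise is
multiplicative Gaussian (CV-parameterized) throughout, because instrument
displacement error scales with the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .creep_model import BurgersParams, CreepCurve
from .large_deformation import CompressionCurve
from .softening_kinetics import DecayFit, eval_decay
from .thermal_profiles import TemperatureProfile

__all__ = [
    "GeneratorConfig",
    "LoadSchedule",
    "StudyDataset",
    "gen_creep_curve",
    "gen_compression_curve",
    "gen_temperature_profile",
    "gen_study_dataset",
    "rise_rate_for_traverse",
    "burgers_for_condition",
    "standard_creep_suite",
    "default_kinetics",
    "default_link",
]

VARIETIES = ("Depurple", "Cheddar")
METHODS = ("B", "S", "SV")

# plateau temperatures (degC) and 40->80 degC traverse targets (min) per method
_PLATEAU_C = {"B": 98.0, "S": 96.0, "SV": 85.0}
_TRAVERSE_MIN = {"B": 1.83, "S": 2.67, "SV": 5.5}


class GeneratorConfig(BaseModel):
    """Study design and noise levels for the synthetic dataset."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    varieties: tuple[str, ...] = VARIETIES
    methods: tuple[str, ...] = METHODS
    times_min: tuple[float, ...] = (0.0, 10.0, 25.0, 40.0)
    replicates_rheology: int = 6
    replicates_chemistry: int = 3
    noise_cv_creep: float = 0.005
    noise_cv_descriptor: float = 0.02
    noise_cv_chemistry: float = 0.05

    @field_validator("times_min")
    @classmethod
    def _times_ok(cls, v):
        if any(t < 0 for t in v):
            raise ValueError("times_min must be nonnegative")
        if list(v) != sorted(v):
            raise ValueError("times_min must be sorted")
        return v

    @field_validator("noise_cv_creep", "noise_cv_descriptor", "noise_cv_chemistry")
    @classmethod
    def _noise_ok(cls, v):
        if v < 0:
            raise ValueError("noise CV must be >= 0")
        return v

    @field_validator("replicates_rheology", "replicates_chemistry")
    @classmethod
    def _reps_ok(cls, v):
        if v < 1:
            raise ValueError("replicate counts must be >= 1")
        return v


@dataclass(frozen=True)
class LoadSchedule:
    """Creep test schedule: constant-stress hold then zero-stress recovery."""

    hold_s: float = 600.0
    recovery_s: float = 600.0
    step_s: float = 1.0
    stress_kPa: float = 40.0

    def __post_init__(self) -> None:
        if self.hold_s <= 0 or self.recovery_s <= 0:
            raise ValueError("hold and recovery durations must be positive")
        if self.step_s <= 0:
            raise ValueError("sampling step must be positive")


def gen_creep_curve(
    params: BurgersParams,
    schedule: LoadSchedule = LoadSchedule(),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> CreepCurve:
    """Simulate one creep/recovery test.

    The hold segment follows the Burgers compliance exactly; on unloading the
    elastic branch J0 recoils instantly, each Kelvin-Voigt branch relaxes
    with its own relaxation time, and the plastic offset JN * t_unload
    persists indefinitely:

        J(t_unload + tau) = sum_i Ji (1 - e^(-t_unload/RTi)) e^(-tau/RTi)
                            + JN * t_unload

    Multiplicative Gaussian noise of coefficient of variation ``noise_cv``
    is applied pointwise.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    t_load = np.arange(0.0, schedule.hold_s + schedule.step_s / 2, schedule.step_s)
    if t_load[-1] < schedule.hold_s:
        t_load = np.append(t_load, schedule.hold_s)
    J_load = np.full_like(t_load, params.J0)
    for Ji, RTi in params.elements:
        J_load = J_load + Ji * (1.0 - np.exp(-t_load / RTi))
    J_load = J_load + params.JN * t_load

    t_rec = np.arange(
        schedule.hold_s + schedule.step_s,
        schedule.hold_s + schedule.recovery_s + schedule.step_s / 2,
        schedule.step_s,
    )
    tau = t_rec - schedule.hold_s
    J_rec = np.full_like(t_rec, params.JN * schedule.hold_s)
    for Ji, RTi in params.elements:
        J_rec = J_rec + Ji * (1.0 - np.exp(-schedule.hold_s / RTi)) * np.exp(-tau / RTi)

    time = np.concatenate([t_load, t_rec])
    J = np.concatenate([J_load, J_rec])
    segment = np.concatenate(
        [np.full(t_load.size, "loading"), np.full(t_rec.size, "recovery")]
    )
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        J = J * (1.0 + rng.normal(0.0, noise_cv, size=J.size))
    return CreepCurve(
        time=time,
        compliance=J,
        t_unload=schedule.hold_s,
        segment=segment,
        stress_kPa=schedule.stress_kPa,
    )


def gen_compression_curve(
    stiffness_target: float,
    hardening_exponent: float,
    max_displacement: float,
    seed: int = 0,
    noise_cv: float = 0.0,
    step_mm: float = 0.1,
    preload: float = 5.0,
) -> CompressionCurve:
    """Simulate a strain-hardening compression curve to 0.5 deformation.

    load(d) = c d^p with the prefactor chosen so that
    load(max_displacement)/max_displacement equals ``stiffness_target``;
    ``hardening_exponent`` p >= 1 guarantees upward concavity.  The specimen
    height is set to twice the maximum displacement so the final sample sits
    exactly at 0.5 deformation.  Noise is multiplicative and the noisy curve
    is rectified to remain nondecreasing.
    """
    if hardening_exponent < 1:
        raise ValueError("hardening_exponent must be >= 1 (decreasing load otherwise)")
    if max_displacement <= 0 or stiffness_target <= 0:
        raise ValueError("stiffness_target and max_displacement must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    c = stiffness_target * max_displacement ** (1.0 - hardening_exponent)
    d = np.arange(0.0, max_displacement + step_mm / 2, step_mm)
    if d[-1] < max_displacement:
        d = np.append(d, max_displacement)
    load = c * d**hardening_exponent
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        load = load * (1.0 + rng.normal(0.0, noise_cv, size=load.size))
        load = np.maximum.accumulate(np.maximum(load, 0.0))
    return CompressionCurve(
        displacement=d, load=load, height_mm=2.0 * max_displacement, preload=preload
    )


def rise_rate_for_traverse(
    plateau_C: float,
    traverse_min: float,
    T_low: float = 40.0,
    T_high: float = 80.0,
) -> float:
    """Rate (min^-1) of a first-order heating profile with the given
    low-to-high traverse time: r = ln((P - T_low)/(P - T_high)) / traverse."""
    if plateau_C <= T_high:
        raise ValueError("plateau must exceed the upper threshold")
    if traverse_min <= 0:
        raise ValueError("traverse_min must be positive")
    return math.log((plateau_C - T_low) / (plateau_C - T_high)) / traverse_min


def gen_temperature_profile(
    method: str | None = None,
    duration_min: float = 25.0,
    plateau_C: float | None = None,
    rise_rate: float | None = None,
    seed: int = 0,
    T0: float = 20.0,
    noise_sd: float = 0.0,
) -> TemperatureProfile:
    """Simulate a cooking log T(t) = P - (P - T0) exp(-r t), sampled every 10 s.

    Per-method defaults give plateaus of 98/96/85 degC for B/S/SV and rise
    rates calibrated to the 1.83/2.67/5.5-min 40->80 degC traverse ordering
    (boiling fastest).  ``rise_rate=inf`` steps to the plateau at the first
    sample after t=0.
    """
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    if plateau_C is None:
        if method not in _PLATEAU_C:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        plateau_C = _PLATEAU_C[method]
    if plateau_C <= T0:
        raise ValueError("plateau must exceed the starting temperature")
    if rise_rate is None:
        key = method if method in _TRAVERSE_MIN else "B"
        rise_rate = rise_rate_for_traverse(plateau_C, _TRAVERSE_MIN[key])
    t_s = np.arange(0.0, duration_min * 60.0 + 5.0, 10.0)
    t_min = t_s / 60.0
    if math.isinf(rise_rate):
        T = np.where(t_s > 0, plateau_C, T0)
    else:
        T = plateau_C - (plateau_C - T0) * np.exp(-rise_rate * t_min)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        T = T + rng.normal(0.0, noise_sd, size=T.size)
    return TemperatureProfile(time=t_s, temp=T)


# ---------------------------------------------------------------------------
# Study-level dataset: kinetics trajectories, chemistry links, creep suite
# ---------------------------------------------------------------------------


def default_kinetics() -> dict[tuple[str, str], DecayFit]:
    """Ground-truth first-order ERA decay per variety x method.

    Rates decrease from boiling through steaming to sous-vide, and the
    orange (Cheddar) variety softens faster than the violet (Depurple) one,
    mirroring the qualitative ordering the descriptor stage is meant to
    resolve.
    """
    table = {
        ("Depurple", "B"): (95.0, 22.0, 0.090),
        ("Depurple", "S"): (95.0, 26.0, 0.060),
        ("Depurple", "SV"): (95.0, 30.0, 0.045),
        ("Cheddar", "B"): (90.0, 18.0, 0.130),
        ("Cheddar", "S"): (90.0, 24.0, 0.085),
        ("Cheddar", "SV"): (90.0, 28.0, 0.060),
    }
    return {
        key: DecayFit(ERA0=e0, ERAinf=einf, k=k, n=1.0)
        for key, (e0, einf, k) in table.items()
    }


def default_link() -> dict[str, tuple[float, float, float]]:
    """Linear link (intercept, coef_ERA, coef_EPR) from descriptors to
    dry-basis concentrations: extractability rises as ERA falls and EPR
    rises."""
    return {
        "TotSte": (3000.0, -30.0, 0.5),
        "TotToc": (150.0, -1.5, 0.02),
    }


# V-shaped EPR companion trajectory: common fresh level, method-specific
# minimum at 10 min of heating, then a variety-specific linear rebound.
_EPR0 = 2000.0
_EPR_MIN = {"B": 800.0, "S": 900.0, "SV": 1100.0}
_EPR_END = {
    ("Depurple", "B"): 1400.0,
    ("Depurple", "S"): 1300.0,
    ("Depurple", "SV"): 1250.0,
    ("Cheddar", "B"): 2400.0,
    ("Cheddar", "S"): 2100.0,
    ("Cheddar", "SV"): 1800.0,
}
_EPR_T_MIN = 10.0  # min of heating at the EPR minimum
_EPR_T_END = 40.0

_W0 = {"Depurple": 92.3, "Cheddar": 92.8}  # % water in the fresh tissue
_DW = {"B": 4.2, "S": 2.2, "SV": 1.5}  # asymptotic water uptake, % points
_W_TAU = 12.0  # min

_STEROL_FRACTIONS = {"beta_sitosterol": 0.62, "campesterol": 0.28, "stigmasterol": 0.10}
_TOC_FRACTIONS = {"gamma_T": 0.55, "alpha_T": 0.33, "delta_T": 0.12}

_UR0 = 27.0  # s/kPa, fresh integrated compliance
_UR_GAIN = 2.5  # relative Ur increase at complete loss of ERA


def epr_trajectory(variety: str, method: str, t_min: float) -> float:
    """Noise-free EPR companion value at heating time t (min)."""
    lo = _EPR_MIN[method]
    end = _EPR_END[(variety, method)]
    if t_min <= _EPR_T_MIN:
        return _EPR0 + (lo - _EPR0) * t_min / _EPR_T_MIN
    frac = min((t_min - _EPR_T_MIN) / (_EPR_T_END - _EPR_T_MIN), 1.5)
    return lo + (end - lo) * frac


def water_trajectory(variety: str, method: str, t_min: float) -> float:
    """Bounded increasing water percentage during cooking."""
    return _W0[variety] + _DW[method] * (1.0 - math.exp(-t_min / _W_TAU))


@dataclass(frozen=True)
class StudyDataset:
    """Joined synthetic study: rheology descriptors, chemistry specimens and
    the ground truth used to generate them."""

    descriptors: pd.DataFrame
    specimens: pd.DataFrame
    truth: dict


def gen_study_dataset(
    config: GeneratorConfig,
    true_kinetics: dict[tuple[str, str], DecayFit] | None = None,
    true_link: dict[str, tuple[float, float, float]] | None = None,
) -> StudyDataset:
    """Generate the per-replicate descriptor and specimen tables.

    Descriptor rows (one per rheology replicate) carry ERA drawn from the
    decay trajectory, the EPR companion, the integrated compliance Ur and
    the supplementary moduli E0/EtaN, all with multiplicative noise of CV
    ``noise_cv_descriptor``.  Specimen rows (one per chemistry replicate)
    carry water %, individual and total sterols/tocopherols computed from
    the *noise-free* trajectory values through ``true_link`` plus
    multiplicative noise of CV ``noise_cv_chemistry``, so a noiseless run
    lets the regression stage recover the link coefficients exactly.
    """
    kinetics = true_kinetics if true_kinetics is not None else default_kinetics()
    link = true_link if true_link is not None else default_link()
    for v in config.varieties:
        for m in config.methods:
            if (v, m) not in kinetics:
                raise ValueError(f"no kinetics entry for condition {(v, m)}")
    for resp, coefs in link.items():
        if not all(math.isfinite(c) for c in coefs):
            raise ValueError(f"non-finite link coefficients for {resp}")

    rng = np.random.default_rng(config.seed)
    desc_rows = []
    spec_rows = []
    for v in config.varieties:
        for m in config.methods:
            decay = kinetics[(v, m)]
            for t in config.times_min:
                era_true = float(eval_decay(decay, t))
                epr_true = epr_trajectory(v, m, t)
                ur_true = _UR0 * (1.0 + _UR_GAIN * (1.0 - era_true / decay.ERA0))
                e0_true = 1.1 * era_true
                etan_true = 80000.0 - 25.0 * epr_true
                w_true = water_trajectory(v, m, t)
                cv = config.noise_cv_descriptor
                for rep in range(1, config.replicates_rheology + 1):
                    noise = 1.0 + rng.normal(0.0, cv, size=5) if cv > 0 else np.ones(5)
                    desc_rows.append(
                        {
                            "variety": v,
                            "method": m,
                            "time_min": t,
                            "replicate": rep,
                            "ERA": min(era_true * noise[0], 100.0),
                            "EPR": epr_true * noise[1],
                            "Ur": ur_true * noise[2],
                            "E0": e0_true * noise[3],
                            "EtaN": etan_true * noise[4],
                        }
                    )
                ccv = config.noise_cv_chemistry
                for rep in range(1, config.replicates_chemistry + 1):
                    # fresh (uncooked) specimens are the time_min == 0 rows of
                    # each cooking branch, so tables join exactly on the keys
                    row = {
                        "variety": v,
                        "method": m,
                        "time_min": t,
                        "replicate": rep,
                        "water_pct": min(
                            w_true * (1.0 + rng.normal(0.0, ccv / 50.0)) if ccv > 0 else w_true,
                            99.9,
                        ),
                    }
                    for resp, (a, b_era, b_epr) in link.items():
                        total = a + b_era * era_true + b_epr * epr_true
                        if ccv > 0:
                            total *= 1.0 + rng.normal(0.0, ccv)
                        total = max(total, 0.0)
                        fractions = {"TotSte": _STEROL_FRACTIONS, "TotToc": _TOC_FRACTIONS}.get(resp)
                        if fractions is not None:
                            parts = {name: total * f for name, f in fractions.items()}
                            row.update(parts)
                            row[resp] = sum(parts.values())
                        else:
                            row[resp] = total
                    spec_rows.append(row)

    truth = {
        "kinetics": kinetics,
        "link": link,
        "epr": {"EPR0": _EPR0, "minimum_at_min": _EPR_T_MIN},
        "water": {"W0": _W0, "uptake": _DW, "tau_min": _W_TAU},
    }
    return StudyDataset(
        descriptors=pd.DataFrame(desc_rows),
        specimens=pd.DataFrame(spec_rows),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Condition-level Burgers parameters and the standard creep suite
# ---------------------------------------------------------------------------

_FRESH_BURGERS = {
    "Depurple": (0.010, ((0.014, 8.0), (0.012, 45.0), (0.010, 90.0))),
    "Cheddar": (0.009, ((0.012, 8.0), (0.010, 45.0), (0.009, 90.0))),
}
_SOFTENING_GAIN = 2.0  # relative compliance increase at complete loss of ERA


def burgers_for_condition(
    variety: str,
    method: str,
    time_min: float,
    kinetics: dict[tuple[str, str], DecayFit] | None = None,
    hold_s: float = 600.0,
) -> BurgersParams:
    """Plausible Burgers parameters for one cooking condition.

    Cooking scales the reversible compliances with the softening fraction
    1 - ERA(t)/ERA0, and the flow coefficient JN is solved in closed form so
    that the curve's elastic recovery ability matches the decay trajectory:
    with A = J0 + sum Ji (1 - e^(-T/RTi)) and target ERA (%),

        JN = A (100 - ERA) / (ERA * T).
    """
    kinetics = kinetics if kinetics is not None else default_kinetics()
    decay = kinetics[(variety, method)]
    era = float(eval_decay(decay, time_min))
    softness = 1.0 - era / decay.ERA0
    J0f, elements_f = _FRESH_BURGERS[variety]
    scale = 1.0 + _SOFTENING_GAIN * softness
    J0 = J0f * scale
    elements = tuple((Ji * scale, RTi) for Ji, RTi in elements_f)
    A = J0 + sum(Ji * (1.0 - math.exp(-hold_s / RTi)) for Ji, RTi in elements)
    JN = A * (100.0 - era) / (era * hold_s)
    return BurgersParams(J0=J0, elements=elements, JN=JN)


def standard_creep_suite(
    seed: int = 0,
    variety: str = "Cheddar",
    methods: tuple[str, ...] = METHODS,
    times_min: tuple[float, ...] = (10.0, 25.0, 40.0),
    replicates: int = 6,
    noise_cv: float = 0.005,
    schedule: LoadSchedule = LoadSchedule(),
):
    """The standard synthetic creep suite: 9 cooking conditions x 6 replicates.

    Yields ``(condition, replicate, true_params, curve)`` with per-curve
    seeds spawned deterministically from ``seed``.
    """
    children = np.random.SeedSequence(seed).generate_state(
        len(methods) * len(times_min) * replicates
    )
    i = 0
    for method in methods:
        for t in times_min:
            params = burgers_for_condition(variety, method, t, hold_s=schedule.hold_s)
            for rep in range(1, replicates + 1):
                curve = gen_creep_curve(
                    params, schedule, noise_cv=noise_cv, seed=int(children[i] % 2**31)
                )
                i += 1
                yield {"variety": variety, "method": method, "time_min": t}, rep, params, curve
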