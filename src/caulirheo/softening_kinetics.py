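"""Decompartmentalization (softening) kinetics of the elastic recovery ability.

The heat-driven decay of ERA with cooking time t (min) is modelled as a
fixed-order decay toward an equilibrium plateau:

    ERA(t) = ERAinf + (ERA0 - ERAinf) * exp(-k * t^n)

with ERA0 the fresh-sample level (held fixed at the t=0 mean), ERAinf the
long-time plateau, k (min^-n) the rate constant and n the dimensionless
kinetic order.  k, n and ERAinf are estimated simultaneously by nonlinear
least squares; with sparse time grids n can be fixed (typically to 1, the
apparent first-order regime).  The characteristic time t50 is the heating
time at which ERA reaches half of its fresh level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .creep_model import FitError, lack_of_fit

__all__ = ["DecayFit", "eval_decay", "fit_decay", "t50"]


@dataclass(frozen=True)
class DecayFit:
    ERA0: float  # %, fixed to the fresh-sample mean
    ERAinf: float  # %, fitted plateau
    k: float  # min^-n
    n: float  # dimensionless order
    t50: float | None = None  # min; None when ERA never reaches 50% of ERA0
    E_pct: float = float("nan")
    r2: float = float("nan")
    at_bounds: bool = False  # ERAinf pinned at a bound during fitting

    def __post_init__(self) -> None:
        if not (0.0 <= self.ERAinf <= self.ERA0 <= 100.0 + 1e-9):
            raise ValueError(
                f"require 0 <= ERAinf ({self.ERAinf}) <= ERA0 ({self.ERA0}) <= 100"
            )
        if not self.k > 0:
            raise ValueError("k must be positive")
        if not self.n > 0:
            raise ValueError("n must be positive")


def eval_decay(fit: DecayFit, t) -> np.ndarray:
    """ERA(t) = ERAinf + (ERA0 - ERAinf) exp(-k t^n); vectorized over t (min)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return fit.ERAinf + (fit.ERA0 - fit.ERAinf) * np.exp(-fit.k * np.power(t, fit.n))


def fit_decay(times, era_values, fix_n: float | None = None) -> DecayFit:
    """Fit the decay model to pooled ERA observations.

    ``times`` must include t=0, whose mean sets ERA0.  With n free at least
    4 distinct time points are required; with n fixed, 3.  ERAinf landing on
    a bound of [0, ERA0] is flagged via ``at_bounds``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(era_values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and era_values must be equally long 1-D arrays")
    distinct = np.unique(t)
    if 0.0 not in distinct:
        raise ValueError("a t=0 (fresh) observation is required to fix ERA0")
    needed = 3 if fix_n is not None else 4
    if distinct.size < needed:
        raise ValueError(f"need >= {needed} distinct time points, got {distinct.size}")
    ERA0 = float(y[t == 0.0].mean())

    # initial guesses: plateau below the last observed mean, rate from a
    # log-linear read-off at the first nonzero time
    y_end = float(y[t == distinct[-1]].mean())
    inf0 = float(np.clip(0.8 * min(y_end, ERA0), 0.0, ERA0 * 0.95))
    t1 = distinct[distinct > 0][0]
    y1 = float(y[t == t1].mean())
    ratio = (y1 - inf0) / max(ERA0 - inf0, 1e-9)
    k0 = -np.log(np.clip(ratio, 1e-6, 0.999)) / t1
    k0 = float(np.clip(k0, 1e-4, 5.0))
    n0 = 1.0 if fix_n is None else float(fix_n)

    if fix_n is None:
        x0 = np.array([k0, n0, inf0])
        lb = np.array([1e-8, 0.05, 0.0])
        ub = np.array([50.0, 5.0, ERA0])

        def unpack(x):
            return x[0], x[1], x[2]

    else:
        if not fix_n > 0:
            raise ValueError("fix_n must be positive")
        x0 = np.array([k0, inf0])
        lb = np.array([1e-8, 0.0])
        ub = np.array([50.0, ERA0])

        def unpack(x):
            return x[0], float(fix_n), x[1]

    def resid(x):
        k, n, inf = unpack(x)
        model = inf + (ERA0 - inf) * np.exp(-k * np.power(t, n))
        return model - y

    result = optimize.least_squares(
        resid, x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000
    )
    if not result.success:
        raise FitError(f"decay fit did not converge: {result.message}")
    k, n, inf = unpack(result.x)
    at_bounds = bool(np.isclose(inf, 0.0, atol=1e-9) or np.isclose(inf, ERA0, atol=1e-9))
    fitted = resid(result.x) + y
    E = lack_of_fit(fitted, y, n_params=3)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = DecayFit(
        ERA0=ERA0, ERAinf=float(inf), k=float(k), n=float(n),
        E_pct=E, r2=r2, at_bounds=at_bounds,
    )
    if fit.ERAinf < 0.5 * fit.ERA0:
        fit = replace(fit, t50=t50(fit))
    return fit


def t50(fit: DecayFit) -> float:
    """Heating time (min) at which ERA reaches 50% of the fresh level.

    Closed form t50 = [ (1/k) ln((ERA0 - ERAinf)/(0.5 ERA0 - ERAinf)) ]^(1/n);
    only defined when the plateau lies below half of ERA0.
    """
    if fit.ERAinf >= 0.5 * fit.ERA0:
        raise ValueError(
            f"t50 undefined: plateau ERAinf={fit.ERAinf} >= 0.5*ERA0={0.5 * fit.ERA0}"
        )
    inner = np.log((fit.ERA0 - fit.ERAinf) / (0.5 * fit.ERA0 - fit.ERAinf)) / fit.k
    return float(inner ** (1.0 / fit.n))
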