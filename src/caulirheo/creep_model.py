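"""Elastoplastic (tailored Burgers) creep-compliance model.

The creep compliance of parenchymatic plant tissue under a constant load is
described as a Maxwell spring + dashpot in series with up to four
Kelvin-Voigt (spring || dashpot) elements:

    J(t) = J0 + sum_i Ji * (1 - exp(-t / RTi)) + JN * t

where ``J0`` (kPa^-1) is the instantaneous reversible compliance, ``Ji``
(kPa^-1) are the retarded reversible compliances with characteristic
relaxation times ``RTi`` (s), and ``JN`` (kPa^-1 s^-1) is the steady-state
irreversible (viscoplastic flow) coefficient.

Fitting is performed on the loading (hold) segment of a creep/recovery test
by bounded nonlinear least squares, optionally with a soft-L1 robust loss.
The number of retarded elements is selected with the Durbin-Watson statistic
of the fit residuals, and parameter uncertainty is quantified with a
parametric (Monte Carlo) bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.stattools import durbin_watson as _sm_durbin_watson

__all__ = [
    "BurgersParams",
    "CreepCurve",
    "CreepFit",
    "FitError",
    "eval_burgers",
    "burgers_integral",
    "fit_burgers",
    "select_model_order",
    "durbin_watson",
    "lack_of_fit",
    "monte_carlo_ci",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit cannot be obtained."""


@dataclass(frozen=True)
class BurgersParams:
    """Parameters of the tailored Burgers model, in canonical order.

    ``elements`` holds ``(Ji, RTi)`` pairs sorted by strictly increasing
    relaxation time; the canonical ordering makes parameter vectors from
    independent fits comparable (no label switching).
    """

    J0: float
    elements: tuple[tuple[float, float], ...] = ()
    JN: float = 0.0

    def __post_init__(self) -> None:
        if not self.J0 > 0:
            raise ValueError(f"J0 must be positive, got {self.J0}")
        if self.JN < 0:
            raise ValueError(f"JN must be nonnegative, got {self.JN}")
        for Ji, RTi in self.elements:
            if Ji < 0:
                raise ValueError(f"retarded compliance must be >= 0, got {Ji}")
            if not RTi > 0:
                raise ValueError(f"relaxation time must be > 0, got {RTi}")
        ordered = tuple(sorted(((float(j), float(r)) for j, r in self.elements), key=lambda e: e[1]))
        if any(b[1] <= a[1] for a, b in zip(ordered, ordered[1:])):
            raise ValueError("relaxation times must be distinct")
        object.__setattr__(self, "elements", ordered)

    @property
    def m(self) -> int:
        """Number of retarded (Kelvin-Voigt) elements."""
        return len(self.elements)

    @property
    def Ji(self) -> np.ndarray:
        return np.array([j for j, _ in self.elements])

    @property
    def RTi(self) -> np.ndarray:
        return np.array([r for _, r in self.elements])

    @property
    def sum_Ji(self) -> float:
        return float(self.Ji.sum()) if self.elements else 0.0

    @property
    def n_params(self) -> int:
        return 2 + 2 * self.m

    def to_array(self) -> np.ndarray:
        """Flatten to ``[J0, J1..Jm, RT1..RTm, JN]`` for the optimizer."""
        return np.concatenate([[self.J0], self.Ji, self.RTi, [self.JN]])

    @classmethod
    def from_array(cls, x: np.ndarray, m: int) -> "BurgersParams":
        """Rebuild from the optimizer vector, restoring canonical RT order."""
        x = np.asarray(x, dtype=float)
        J0 = x[0]
        Ji = x[1 : 1 + m]
        RTi = x[1 + m : 1 + 2 * m]
        JN = x[1 + 2 * m]
        order = np.argsort(RTi)
        # perturb exactly-tied relaxation times so the canonical ordering is strict
        rt_sorted = RTi[order].copy()
        for i in range(1, m):
            if rt_sorted[i] <= rt_sorted[i - 1]:
                rt_sorted[i] = np.nextafter(rt_sorted[i - 1], np.inf)
        elements = tuple((max(float(Ji[order][i]), 0.0), float(rt_sorted[i])) for i in range(m))
        return cls(J0=float(J0), elements=elements, JN=max(float(JN), 0.0))

    @property
    def names(self) -> tuple[str, ...]:
        names = ["J0"]
        names += [f"J{i + 1}" for i in range(self.m)]
        names += [f"RT{i + 1}" for i in range(self.m)]
        names.append("JN")
        return tuple(names)


@dataclass(frozen=True)
class CreepCurve:
    """A sampled creep/recovery compliance curve.

    ``segment`` labels each sample as ``"loading"`` (constant stress applied)
    or ``"recovery"`` (stress removed at ``t_unload``); the loading samples
    must precede the recovery samples.
    """

    time: np.ndarray
    compliance: np.ndarray
    t_unload: float
    segment: np.ndarray
    stress_kPa: float = 40.0

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        compliance = np.asarray(self.compliance, dtype=float)
        segment = np.asarray(self.segment)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "compliance", compliance)
        object.__setattr__(self, "segment", segment)
        if time.ndim != 1 or time.shape != compliance.shape or time.shape != segment.shape:
            raise ValueError("time, compliance and segment must be 1-D and equally long")
        if time.size < 2 or time[0] != 0 or np.any(np.diff(time) <= 0):
            raise ValueError("time must be strictly increasing from 0")
        if not (time[0] <= self.t_unload <= time[-1]):
            raise ValueError("t_unload must lie within the sampled time range")
        labels = set(np.unique(segment))
        if not labels <= {"loading", "recovery"}:
            raise ValueError(f"unknown segment labels: {labels - {'loading', 'recovery'}}")
        is_load = segment == "loading"
        if is_load.any() and (~is_load).any() and not np.all(is_load[: int(is_load.sum())]):
            raise ValueError("loading samples must precede recovery samples")

    @property
    def loading_mask(self) -> np.ndarray:
        return self.segment == "loading"

    @property
    def loading_time(self) -> np.ndarray:
        return self.time[self.loading_mask]

    @property
    def loading_compliance(self) -> np.ndarray:
        return self.compliance[self.loading_mask]

    @property
    def recovery_time(self) -> np.ndarray:
        return self.time[~self.loading_mask]

    @property
    def recovery_compliance(self) -> np.ndarray:
        return self.compliance[~self.loading_mask]


@dataclass(frozen=True)
class CreepFit:
    """Result of fitting the Burgers model to a creep curve."""

    params: BurgersParams
    m: int
    residuals: np.ndarray
    fitted: np.ndarray
    E_pct: float
    dw: float
    loss: str = "squared"
    cost: float = 0.0
    ci95: dict[str, tuple[float, float]] | None = None
    residual_mean_pvalue: float = float("nan")

    def with_ci(self, ci95: dict[str, tuple[float, float]]) -> "CreepFit":
        return replace(self, ci95=ci95)


def eval_burgers(params: BurgersParams, t) -> np.ndarray:
    """Evaluate J(t) = J0 + sum Ji (1 - exp(-t/RTi)) + JN t. Vectorized."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    J = np.full_like(t, params.J0, dtype=float)
    for Ji, RTi in params.elements:
        J = J + Ji * (1.0 - np.exp(-t / RTi))
    J = J + params.JN * t
    return J


def burgers_integral(params: BurgersParams, T: float) -> float:
    """Closed-form integral of J(t) over [0, T].

    int_0^T J dt = J0 T + sum Ji (T - RTi (1 - e^(-T/RTi))) + JN T^2 / 2.
    Used as an analytic cross-check of the trapezoidal integrated compliance.
    """
    if T < 0:
        raise ValueError("T must be nonnegative")
    total = params.J0 * T + params.JN * T**2 / 2.0
    for Ji, RTi in params.elements:
        total += Ji * (T - RTi * (1.0 - np.exp(-T / RTi)))
    return float(total)


def durbin_watson(residuals) -> float:
    """Durbin-Watson statistic sum (r_t - r_{t-1})^2 / sum r_t^2 of ordered residuals."""
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 residuals")
    if np.all(r == 0):
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(_sm_durbin_watson(r))


def lack_of_fit(fitted, observed, n_params: int) -> float:
    """Lack-of-fit E% : root of the dof-corrected mean squared relative residual.

    E% = 100 * sqrt( 1/(N - p) * sum ((Jfit - Jobs)/Jfit)^2 )
    """
    fitted = np.asarray(fitted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if fitted.shape != observed.shape:
        raise ValueError("fitted and observed must have equal length")
    N = fitted.size
    if N <= n_params:
        raise ValueError(f"need more points ({N}) than parameters ({n_params})")
    if np.any(fitted == 0):
        raise ValueError("relative residual undefined where the fitted value is 0")
    rel = (fitted - observed) / fitted
    return float(100.0 * np.sqrt(np.sum(rel**2) / (N - n_params)))


def _initial_guess(t: np.ndarray, J: np.ndarray, m: int) -> np.ndarray:
    """Heuristic start: J0 from the first sample, JN from the terminal slope,
    the remaining amplitude split evenly over the retarded elements, and
    relaxation times log-spaced over [1, t_end/2] (the objective is multimodal
    in the RTi, so the spread matters more than the exact values)."""
    J0 = max(J[0], 1e-12)
    tail = t >= t[-1] * 0.75
    if tail.sum() >= 2:
        JN = max(float(np.polyfit(t[tail], J[tail], 1)[0]), 0.0)
    else:
        JN = 0.0
    if m == 0:
        return np.array([J0, JN])
    amplitude = max(float(J[-1] - JN * t[-1] - J0), 1e-9)
    Ji = np.full(m, amplitude / m)
    RTi = np.geomspace(1.0, max(t[-1] / 2.0, 2.0), m) if m > 1 else np.array([max(t[-1] / 10.0, 1.0)])
    return np.concatenate([[J0], Ji, RTi, [JN]])


def fit_burgers(curve: CreepCurve, m: int, loss: str = "squared") -> CreepFit:
    """Fit the m-element Burgers model to the loading segment of ``curve``.

    ``loss="squared"`` is ordinary least squares; ``loss="robust"`` uses a
    soft-L1 (Huber-like) loss with scale 1.345 times the MAD of the residuals
    at the initial guess.  ``m=0`` degenerates to the pure Maxwell line
    J0 + JN t.
    """
    if m < 0 or m > 4:
        raise ValueError("number of retarded elements must be in 0..4")
    if loss not in ("squared", "robust"):
        raise ValueError(f"unknown loss {loss!r}")
    t = curve.loading_time
    J = curve.loading_compliance
    n_params = 2 + 2 * m
    if t.size < n_params:
        raise FitError(f"loading segment has {t.size} points; need >= {n_params} for m={m}")

    x0 = _initial_guess(t, J, m)
    eps = 1e-12
    if m == 0:
        lb = np.array([eps, 0.0])
        ub = np.array([np.inf, np.inf])

        def model(x):
            return x[0] + x[1] * t

    else:
        lb = np.concatenate([[eps], np.zeros(m), np.full(m, 1e-3), [0.0]])
        ub = np.concatenate([[np.inf], np.full(m, np.inf), np.full(m, t[-1]), [np.inf]])

        def model(x):
            out = np.full_like(t, x[0])
            for i in range(m):
                out = out + x[1 + i] * (1.0 - np.exp(-t / x[1 + m + i]))
            return out + x[1 + 2 * m] * t

    def resid(x):
        return model(x) - J

    kwargs: dict = {"bounds": (lb, ub), "xtol": 1e-15, "ftol": 1e-15, "gtol": 1e-15, "max_nfev": 20000}
    if loss == "robust":
        mad = float(np.median(np.abs(resid(x0) - np.median(resid(x0)))))
        kwargs["loss"] = "soft_l1"
        kwargs["f_scale"] = max(1.345 * 1.4826 * mad, 1e-9)
    x0 = np.clip(x0, lb, ub)
    result = optimize.least_squares(resid, x0, **kwargs)
    if not result.success:
        raise FitError(f"Burgers fit (m={m}, loss={loss}) did not converge: {result.message}")

    if m == 0:
        params = BurgersParams(J0=float(max(result.x[0], eps)), elements=(), JN=float(max(result.x[1], 0.0)))
    else:
        params = BurgersParams.from_array(result.x, m)
    fitted = eval_burgers(params, t)
    residuals = J - fitted
    E = lack_of_fit(fitted, J, n_params)
    if np.all(residuals == 0):  # exact fit: residuals carry no autocorrelation signal
        dw = 2.0
        pval = 1.0
    else:
        dw = durbin_watson(residuals)
        pval = float(stats.ttest_1samp(residuals, 0.0).pvalue)
    return CreepFit(
        params=params,
        m=m,
        residuals=residuals,
        fitted=fitted,
        E_pct=E,
        dw=dw,
        loss=loss,
        cost=float(result.cost),
        residual_mean_pvalue=pval,
    )


def select_model_order(
    curve: CreepCurve,
    max_m: int = 4,
    loss: str = "squared",
    tie_margin: float = 0.05,
) -> CreepFit:
    """Choose the number of retarded elements with the Durbin-Watson criterion.

    Candidate orders 1..max_m are fitted; among the fits whose residual mean
    is compatible with zero (one-sample t-test, alpha 0.05) the fit whose
    Durbin-Watson statistic is closest to 2 wins.  Because a larger model
    with a vanishing extra element reproduces the smaller model's residuals
    almost exactly, "closest" is applied with a parsimony margin: the
    smallest order within ``tie_margin`` of the best |DW - 2| is returned.
    """
    if max_m < 1:
        raise ValueError("max_m must be >= 1")
    fits: dict[int, CreepFit] = {}
    errors: list[str] = []
    for m in range(1, max_m + 1):
        try:
            fits[m] = fit_burgers(curve, m, loss=loss)
        except FitError as exc:  # pragma: no cover - diagnostic path
            errors.append(str(exc))
    if not fits:
        raise FitError("no candidate order converged: " + "; ".join(errors))
    if max_m == 1:
        return fits[1]
    candidates = {m: f for m, f in fits.items() if f.residual_mean_pvalue >= 0.05}
    if not candidates:
        candidates = fits
    best = min(abs(f.dw - 2.0) for f in candidates.values())
    for m in sorted(candidates):
        if abs(candidates[m].dw - 2.0) <= best + tie_margin:
            return candidates[m]
    raise AssertionError("unreachable")  # pragma: no cover


def monte_carlo_ci(
    fit: CreepFit,
    curve: CreepCurve,
    n_sims: int = 500,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Parametric-bootstrap 95% confidence intervals for the fit parameters.

    Synthetic curves are drawn as fitted values plus Gaussian noise with the
    residual standard deviation, refitted at the same order, and the
    2.5/97.5 percentiles of each (canonically ordered) parameter are taken.
    Raises if more than 20% of the refits fail.
    """
    rng = np.random.default_rng(seed)
    t = curve.loading_time
    sd = float(np.std(fit.residuals, ddof=min(fit.params.n_params, fit.residuals.size - 1)))
    names = fit.params.names
    if sd == 0.0:
        point = fit.params.to_array()
        return {name: (float(v), float(v)) for name, v in zip(names, point)}
    draws = np.empty((n_sims, len(names)))
    failures = 0
    warm = fit.params.to_array()
    for i in range(n_sims):
        J_sim = fit.fitted + rng.normal(0.0, sd, size=t.size)
        try:
            sim_fit = _refit_fixed_order(t, J_sim, fit.m, warm, loss=fit.loss)
            draws[i] = sim_fit.to_array()
        except FitError:
            failures += 1
            draws[i] = np.nan
    if failures > 0.2 * n_sims:
        raise FitError(f"{failures}/{n_sims} bootstrap refits failed (order m={fit.m})")
    lo = np.nanpercentile(draws, 2.5, axis=0)
    hi = np.nanpercentile(draws, 97.5, axis=0)
    return {name: (float(a), float(b)) for name, a, b in zip(names, lo, hi)}


def _refit_fixed_order(t: np.ndarray, J: np.ndarray, m: int, x0: np.ndarray, loss: str) -> BurgersParams:
    """Fast refit used by the bootstrap: warm-started at the point estimate."""
    eps = 1e-12
    if m == 0:
        lb = np.array([eps, 0.0])
        ub = np.array([np.inf, np.inf])
    else:
        lb = np.concatenate([[eps], np.zeros(m), np.full(m, 1e-3), [0.0]])
        ub = np.concatenate([[np.inf], np.full(m, np.inf), np.full(m, t[-1]), [np.inf]])

    def resid(x):
        if m == 0:
            return x[0] + x[1] * t - J
        out = np.full_like(t, x[0])
        for i in range(m):
            out = out + x[1 + i] * (1.0 - np.exp(-t / x[1 + m + i]))
        return out + x[1 + 2 * m] * t - J

    kwargs: dict = {"bounds": (lb, ub), "xtol": 1e-12, "ftol": 1e-12, "gtol": 1e-12, "max_nfev": 5000}
    if loss == "robust":
        r0 = resid(x0)
        mad = float(np.median(np.abs(r0 - np.median(r0))))
        kwargs["loss"] = "soft_l1"
        kwargs["f_scale"] = max(1.345 * 1.4826 * mad, 1e-9)
    result = optimize.least_squares(resid, np.clip(x0, lb, ub), **kwargs)
    if not result.success:
        raise FitError(f"bootstrap refit failed: {result.message}")
    if m == 0:
        return BurgersParams(J0=float(max(result.x[0], eps)), elements=(), JN=float(max(result.x[1], 0.0)))
    return BurgersParams.from_array(result.x, m)
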