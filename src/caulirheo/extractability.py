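"""Phytochemical-extractability arithmetic and multivariate stage.

Concentration handling (fold changes against the fresh sample, dry/wet basis
conversion), multiple-regression models predicting total sterols, total
tocopherols or extracted water from the microstructure descriptors ERA and
EPR with a 70/30 calibration/validation split, and a correlation-matrix PCA
in which descriptor and concentration variables are "active" (they shape the
components) while individual compounds and reciprocal moduli are
"supplementary" (projected onto the components afterwards).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import train_test_split

__all__ = [
    "MRAModel",
    "PCAResult",
    "fold_change",
    "dry_to_wet",
    "join_tables",
    "fit_mra",
    "pca_supplementary",
]


def fold_change(cooked: float, fresh: float) -> float:
    """cooked/fresh concentration ratio (both on the same basis), 2 decimals."""
    if fresh <= 0:
        raise ValueError("fresh concentration must be positive")
    return round(cooked / fresh, 2)


def dry_to_wet(conc_db: float, water_pct: float) -> float:
    """Convert mg/kg dry basis to mg/kg wet basis given the water percentage."""
    if not 0.0 <= water_pct < 100.0:
        raise ValueError(f"water_pct must be in [0, 100), got {water_pct}")
    return conc_db * (1.0 - water_pct / 100.0)


_KEYS = ["variety", "method", "time_min"]


def join_tables(specimens: pd.DataFrame, descriptors: pd.DataFrame) -> pd.DataFrame:
    """Attach condition-mean rheology descriptors to each chemistry specimen.

    Rheology and chemistry replicates are unpaired (different specimens), so
    descriptors are averaged per (variety, method, time_min) condition before
    merging.
    """
    desc_cols = [c for c in descriptors.columns if c not in _KEYS + ["replicate"]]
    means = descriptors.groupby(_KEYS, as_index=False)[desc_cols].mean()
    return specimens.merge(means, on=_KEYS, how="inner", validate="many_to_one")


@dataclass(frozen=True)
class MRAModel:
    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]  # includes "const"
    standard_errors: dict[str, float]
    calibration_mare: float  # %
    validation_mare: float  # %
    validation_r2: float
    n_calibration: int
    n_validation: int
    intercept_only: bool = False

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.coefficients["const"], dtype=float)
        for name in self.predictors:
            out += self.coefficients[name] * table[name].to_numpy(dtype=float)
        return out


def _stepwise_ols(X: pd.DataFrame, y: np.ndarray, entry_p: float, removal_p: float) -> list[str]:
    """Forward stepwise selection with backward checks.

    A candidate enters when its coefficient p-value in the augmented model is
    below ``entry_p``; after each entry, any included predictor whose p-value
    exceeds ``removal_p`` is dropped.
    """
    included: list[str] = []
    while True:
        changed = False
        remaining = [c for c in X.columns if c not in included]
        best_p, best_c = entry_p, None
        for c in remaining:
            model = sm.OLS(y, sm.add_constant(X[included + [c]])).fit()
            p = float(model.pvalues[c])
            if p < best_p:
                best_p, best_c = p, c
        if best_c is not None:
            included.append(best_c)
            changed = True
        if included:
            model = sm.OLS(y, sm.add_constant(X[included])).fit()
            worst = model.pvalues.drop("const").astype(float)
            if float(worst.max()) > removal_p:
                included.remove(str(worst.idxmax()))
                changed = True
        if not changed:
            return included


def _mare(observed: np.ndarray, predicted: np.ndarray) -> float:
    mask = observed != 0
    if not mask.any():
        raise ValueError("MARE undefined: all observed values are zero")
    return float(100.0 * np.mean(np.abs((predicted[mask] - observed[mask]) / observed[mask])))


def fit_mra(
    table: pd.DataFrame,
    response: str,
    candidate_predictors: tuple[str, ...] = ("ERA", "EPR"),
    split_seed: int = 0,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> MRAModel:
    """Stepwise multiple regression with a 70/30 calibration/validation split.

    The split is stratified by variety x method when those columns are
    present (so both splits span the cooking design) and is deterministic
    under ``split_seed``.  Coefficient standard errors come from the usual
    OLS covariance (X'X)^-1 sigma^2; accuracy is reported as the mean
    absolute relative error (MARE, %) and the R^2 of predicted vs observed
    on the held-out rows.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows to split 70/30")
    missing = [c for c in (response, *candidate_predictors) if c not in table.columns]
    if missing:
        raise KeyError(f"columns missing from table: {missing}")
    strata = None
    if {"variety", "method"} <= set(table.columns):
        labels = table["variety"].astype(str) + "|" + table["method"].astype(str)
        if labels.value_counts().min() >= 2 and labels.nunique() > 1:
            strata = labels
    cal, val = train_test_split(
        table, test_size=0.3, random_state=split_seed, stratify=strata
    )
    X_cal = cal[list(candidate_predictors)].astype(float)
    y_cal = cal[response].to_numpy(dtype=float)

    selected = _stepwise_ols(X_cal, y_cal, entry_p, removal_p)
    intercept_only = not selected
    exog = sm.add_constant(X_cal[selected]) if selected else np.ones((len(cal), 1))
    ols = sm.OLS(y_cal, exog).fit()
    if selected:
        coefs = {str(k): float(v) for k, v in ols.params.items()}
        ses = {str(k): float(v) for k, v in ols.bse.items()}
    else:
        coefs = {"const": float(ols.params[0])}
        ses = {"const": float(ols.bse[0])}

    y_val = val[response].to_numpy(dtype=float)
    pred_val = np.full(len(val), coefs["const"], dtype=float)
    for name in selected:
        pred_val += coefs[name] * val[name].to_numpy(dtype=float)
    # R^2 of the linear regression of predicted vs observed on held-out rows
    if np.std(pred_val) > 0 and np.std(y_val) > 0:
        r2_val = float(np.corrcoef(pred_val, y_val)[0, 1] ** 2)
    else:
        r2_val = 1.0 if np.allclose(pred_val, y_val) else 0.0
    return MRAModel(
        response=response,
        predictors=tuple(selected),
        coefficients=coefs,
        standard_errors=ses,
        calibration_mare=_mare(y_cal, np.asarray(ols.fittedvalues)),
        validation_mare=_mare(y_val, pred_val),
        validation_r2=r2_val,
        n_calibration=len(cal),
        n_validation=len(val),
        intercept_only=intercept_only,
    )


@dataclass(frozen=True)
class PCAResult:
    eigenvalues: np.ndarray  # nonincreasing; sums to the number of active variables
    percent_variance: np.ndarray  # sums to 100 over all components
    loadings: pd.DataFrame  # active variables x components (variable-score correlations)
    supplementary: pd.DataFrame  # supplementary variables x components (score correlations)
    scores: pd.DataFrame  # specimens x components
    components: np.ndarray  # orthonormal eigenvectors, variables x components


def pca_supplementary(
    table: pd.DataFrame,
    active: tuple[str, ...],
    supplementary: tuple[str, ...] = (),
) -> PCAResult:
    """Correlation-matrix PCA with supplementary-variable projection.

    Active columns are standardized (z-scores, ddof=1) and decomposed; the
    loading of a variable on a component is its Pearson correlation with the
    component scores, which makes active and supplementary coordinates
    directly comparable: supplementary variables take no part in defining
    the components and are simply correlated with the scores afterwards.
    """
    for col in active:
        if col not in table.columns:
            raise KeyError(f"active column {col!r} missing")
        if float(table[col].std(ddof=1)) == 0.0:
            raise ValueError(f"active column {col!r} is constant (zero variance)")
    for col in supplementary:
        if col not in table.columns:
            raise KeyError(f"supplementary column {col!r} missing")
    n = len(table)
    p = len(active)
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows for {p} active variables")

    X = table[list(active)].to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)
    # deterministic sign: largest-magnitude coefficient of each component positive
    for c in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = Z @ Vt.T
    comp_names = [f"PC{i + 1}" for i in range(len(eig))]
    with np.errstate(invalid="ignore", divide="ignore"):
        loadings = Vt.T * np.sqrt(eig)  # = corr(active var, scores) for z-scored data

    # degenerate components (numerically zero variance) carry no direction;
    # coordinates on them are reported as 0 for both variable classes
    informative = eig > 1e-10 * max(float(eig[0]), 1.0)

    def _score_corr(cols: tuple[str, ...]) -> pd.DataFrame:
        out = np.zeros((len(cols), len(eig)))
        for i, col in enumerate(cols):
            v = table[col].to_numpy(dtype=float)
            sv = v.std(ddof=1)
            for c in range(len(eig)):
                sc = scores[:, c].std(ddof=1)
                if sv == 0 or sc == 0 or not informative[c]:
                    out[i, c] = 0.0
                else:
                    out[i, c] = np.corrcoef(v, scores[:, c])[0, 1]
        return pd.DataFrame(out, index=list(cols), columns=comp_names)

    return PCAResult(
        eigenvalues=eig,
        percent_variance=100.0 * eig / eig.sum(),
        loadings=pd.DataFrame(loadings, index=list(active), columns=comp_names),
        supplementary=_score_corr(tuple(supplementary)),
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        components=Vt.T,
    )
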