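"""Multiple imputation of missing covariates.

Single-variable imputation of a categorical covariate uses polytomous
(multinomial) logistic regression: the model is fit once on the complete
cases with a small ridge penalty, and each missing case draws a category
from its fitted probabilities, independently for each of the m
imputations.  This mirrors mice's ``polyreg`` method, where the
between-imputation variance comes from the category draws rather than
from refitting; ``param_uncertainty="bootstrap"`` switches to a
bootstrap-then-fit scheme that additionally propagates model-parameter
uncertainty.

Continuous covariates are imputed by predictive mean matching (PMM): a
Bayesian-bootstrap-perturbed linear fit ranks observed donors by
predicted mean and each missing case borrows the observed value of one
of its nearest donors, so imputed values are always actually observed
values.

:func:`run_chained_equations` composes these per-variable methods into
fully conditional specification (chained equations) for tables with
several incomplete covariates, visiting variables in order of
increasing missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._multinomial import fit_multinomial, predict_proba
from ._rng import stream
from .datamodel import CovariateTable

__all__ = [
    "ImputationModelSpec",
    "ImputedDatasets",
    "impute_categorical",
    "impute_pmm",
    "run_chained_equations",
]

_MAX_BOOT_ATTEMPTS = 10


@dataclass
class ImputationModelSpec:
    """Imputation model for one incomplete variable.

    ``predictors`` may mix covariate names and CpG site IDs (resolved
    against the ``site_data`` frame passed to the chained-equations
    runner).  ``method`` is one of ``polytomous``, ``logistic``, ``pmm``,
    ``normal``.
    """

    target: str
    predictors: tuple[str, ...]
    method: str = "polytomous"
    ridge: float = 1e-5
    pmm_donors: int = 5
    param_uncertainty: str = "none"

    def __post_init__(self):
        if self.param_uncertainty not in ("none", "bootstrap"):
            raise ValueError("param_uncertainty must be 'none' or 'bootstrap'")
        if self.target in self.predictors:
            raise ValueError(f"target {self.target!r} cannot predict itself")
        if self.method not in ("polytomous", "logistic", "pmm", "normal"):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be positive")
        self.predictors = tuple(self.predictors)


@dataclass
class ImputedDatasets:
    """m completed copies of the imputed object plus provenance.

    ``completed`` holds pandas Series (single-variable runs) or
    DataFrames (chained runs).  Observed cells are identical across all
    m copies; only originally missing cells differ.
    """

    m: int
    completed: list
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers


def _with_intercept(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.hstack([np.ones((X.shape[0], 1)), X])


def _bootstrap_with_all_codes(rng, codes_obs: np.ndarray, n_codes: int) -> np.ndarray:
    """Bootstrap indices over complete cases; redraw until every observed
    category survives (at most 10 attempts)."""
    n = codes_obs.shape[0]
    for _ in range(_MAX_BOOT_ATTEMPTS):
        idx = rng.integers(0, n, n)
        if len(np.unique(codes_obs[idx])) == n_codes:
            return idx
    raise RuntimeError(
        "bootstrap resample kept losing a category after "
        f"{_MAX_BOOT_ATTEMPTS} attempts; too few cases in some category"
    )


def draw_categories(rng, probs: np.ndarray) -> np.ndarray:
    """Draw one category index per row of a probability matrix."""
    u = rng.random(probs.shape[0])
    return (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)


def polytomous_draw(
    rng,
    y_codes: np.ndarray,
    X: np.ndarray,
    obs: np.ndarray,
    n_codes: int,
    ridge: float,
    bootstrap: bool = False,
) -> np.ndarray:
    """One polytomous imputation; returns codes for missing rows.

    ``y_codes`` are integer codes (-1 for missing) over *observed*
    categories re-indexed 0..K'-1; ``X`` already includes an intercept.
    With ``bootstrap`` the complete cases are resampled before fitting.
    """
    mis = ~obs
    if n_codes == 1:
        return np.zeros(int(mis.sum()), dtype=int)
    Xo = X[obs]
    yo = y_codes[obs]
    if bootstrap:
        idx = _bootstrap_with_all_codes(rng, yo, n_codes)
        Xo, yo = Xo[idx], yo[idx]
    beta = fit_multinomial(Xo, yo, n_codes, ridge=ridge)
    probs = predict_proba(X[mis], beta, n_codes)
    return draw_categories(rng, probs)


# ---------------------------------------------------------------------------
# single-variable operations


def impute_categorical(
    target: pd.Series,
    predictors,
    m: int,
    ridge: float = 1e-5,
    seed: int = 0,
    levels: Sequence[str] | None = None,
    param_uncertainty: str = "none",
) -> ImputedDatasets:
    """Multiply impute a categorical variable by polytomous regression.

    Only categories present among the observed values can be imputed;
    with a single observed category the fit degenerates to a
    deterministic fill.  Requires more complete cases than predictors.
    ``param_uncertainty`` is ``"none"`` (mice-polyreg style: one fit,
    m sets of category draws) or ``"bootstrap"`` (refit per imputation
    on a resample of the complete cases).
    """
    if param_uncertainty not in ("none", "bootstrap"):
        raise ValueError("param_uncertainty must be 'none' or 'bootstrap'")
    target = pd.Series(target)
    X = _with_intercept(np.asarray(predictors, dtype=float))
    if np.isnan(X).any():
        raise ValueError("predictors must be fully observed")
    obs = target.notna().to_numpy()
    n_obs = int(obs.sum())
    if X.shape[1] >= n_obs:
        raise ValueError(
            f"{X.shape[1] - 1} predictors with only {n_obs} complete cases; "
            "use smaller bins so the imputation model can be fit"
        )
    observed_levels = [l for l in (levels or pd.unique(target.dropna())) if (target == l).any()]
    code_of = {lev: k for k, lev in enumerate(observed_levels)}
    y_codes = np.full(len(target), -1, dtype=int)
    for lev, k in code_of.items():
        y_codes[(target == lev).to_numpy()] = k
    K = len(observed_levels)

    probs = None
    if param_uncertainty == "none" and (~obs).any() and K > 1:
        beta = fit_multinomial(X[obs], y_codes[obs], K, ridge=ridge)
        probs = predict_proba(X[~obs], beta, K)

    completed = []
    for i in range(m):
        rng = stream(seed, "impute", 0, i)
        filled = target.copy()
        if (~obs).any():
            if param_uncertainty == "bootstrap":
                draws = polytomous_draw(rng, y_codes, X, obs, K, ridge, bootstrap=True)
            elif K == 1:
                draws = np.zeros(int((~obs).sum()), dtype=int)
            else:
                draws = draw_categories(rng, probs)
            filled.iloc[np.flatnonzero(~obs)] = [observed_levels[k] for k in draws]
        completed.append(filled)
    return ImputedDatasets(
        m=m,
        completed=completed,
        provenance={
            "method": "polytomous",
            "ridge": ridge,
            "seed": seed,
            "param_uncertainty": param_uncertainty,
        },
    )


def pmm_draw(
    rng,
    y: np.ndarray,
    X: np.ndarray,
    obs: np.ndarray,
    donors: int,
) -> np.ndarray:
    """One PMM imputation; returns imputed values for missing rows.

    The observed cases' predicted means come from the ordinary fit; the
    missing cases' from a Bayesian-bootstrap (Dirichlet-weighted) refit,
    which perturbs the regression line between imputations.
    """
    Xo, yo = X[obs], y[obs]
    Xm = X[~obs]
    coef_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    w = rng.dirichlet(np.ones(Xo.shape[0])) * Xo.shape[0]
    sw = np.sqrt(w)
    coef_star, *_ = np.linalg.lstsq(Xo * sw[:, None], yo * sw, rcond=None)
    pred_obs = Xo @ coef_hat
    pred_mis = Xm @ coef_star
    d = np.abs(pred_obs[None, :] - pred_mis[:, None])
    k = min(donors, Xo.shape[0])
    nearest = np.argpartition(d, k - 1, axis=1)[:, :k]
    pick = rng.integers(0, k, Xm.shape[0])
    return yo[nearest[np.arange(Xm.shape[0]), pick]]


def impute_pmm(
    target: pd.Series,
    predictors,
    m: int,
    donors: int = 5,
    seed: int = 0,
) -> ImputedDatasets:
    """Multiply impute a continuous variable by predictive mean matching."""
    target = pd.Series(target)
    X = _with_intercept(np.asarray(predictors, dtype=float))
    obs = target.notna().to_numpy()
    n_obs = int(obs.sum())
    if n_obs < donors:
        raise ValueError(f"need at least {donors} complete cases for {donors} donors")
    if n_obs <= X.shape[1]:
        raise ValueError("fewer complete cases than predictors")
    y = target.to_numpy(dtype=float)
    completed = []
    for i in range(m):
        rng = stream(seed, "impute", 0, i)
        filled = target.copy()
        if (~obs).any():
            filled.iloc[np.flatnonzero(~obs)] = pmm_draw(rng, y, X, obs, donors)
        completed.append(filled)
    return ImputedDatasets(
        m=m, completed=completed, provenance={"method": "pmm", "donors": donors, "seed": seed}
    )


def _normal_draw(rng, y, X, obs):
    """Bayesian linear-regression imputation for missing rows."""
    Xo, yo = X[obs], y[obs]
    n, p = Xo.shape
    coef_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ coef_hat
    df = n - p
    sigma2_star = resid @ resid / rng.chisquare(df)
    XtX_inv = np.linalg.inv(Xo.T @ Xo)
    L = np.linalg.cholesky(XtX_inv * sigma2_star)
    coef_star = coef_hat + L @ rng.standard_normal(p)
    Xm = X[~obs]
    return Xm @ coef_star + np.sqrt(sigma2_star) * rng.standard_normal(Xm.shape[0])


# ---------------------------------------------------------------------------
# chained equations


def _encode_predictors(
    df: pd.DataFrame,
    schema,
    predictors: Sequence[str],
    site_data: pd.DataFrame | None,
) -> np.ndarray:
    """Numeric predictor matrix from current completed values.

    Categorical predictors are dummy-coded against their reference
    level; site IDs are looked up in ``site_data`` (samples x sites).
    """
    cols = []
    for name in predictors:
        if name in df.columns:
            var = schema[name]
            if var.kind == "categorical":
                for lev in var.levels:
                    if lev != var.reference:
                        cols.append((df[name] == lev).to_numpy(dtype=float))
            else:
                cols.append(df[name].to_numpy(dtype=float))
        elif site_data is not None and name in site_data.columns:
            cols.append(site_data[name].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown predictor {name!r}")
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def run_chained_equations(
    table: CovariateTable,
    specs: Mapping[str, ImputationModelSpec] | Sequence[ImputationModelSpec],
    m: int,
    n_cycles: int = 10,
    seed: int = 0,
    site_data: pd.DataFrame | None = None,
) -> ImputedDatasets:
    """Fully conditional specification over several incomplete covariates.

    Missing cells are initialized by random draws from each variable's
    observed marginal; variables are then revisited in order of
    increasing missingness for ``n_cycles`` cycles, each re-imputed from
    the current completed values of its predictors.  The m imputations
    are independent chains.  Every incomplete variable must have a spec.
    """
    if not isinstance(specs, Mapping):
        specs = {s.target: s for s in specs}
    mask = table.missing_mask
    incomplete = [c for c in table.data.columns if mask[c].any()]
    for c in incomplete:
        if c not in specs:
            raise ValueError(f"incomplete variable {c!r} has no imputation spec")
    order = sorted(incomplete, key=lambda c: (int(mask[c].sum()), c))

    completed = []
    for i in range(m):
        rng = stream(seed, "chain", i)
        df = table.data.copy()
        # marginal initialization
        for c in order:
            obs_vals = table.data[c].dropna().to_numpy()
            n_mis = int(mask[c].sum())
            df.loc[mask[c], c] = rng.choice(obs_vals, n_mis)
        for _ in range(n_cycles if incomplete else 0):
            for c in order:
                spec = specs[c]
                obs = (~mask[c]).to_numpy()
                X = _with_intercept(
                    _encode_predictors(df, table.schema, spec.predictors, site_data)
                )
                if X.shape[1] >= int(obs.sum()):
                    raise ValueError(
                        f"imputation model for {c!r} has >= as many predictors as "
                        "complete cases; use smaller bins"
                    )
                if spec.method in ("polytomous", "logistic"):
                    var = table.schema[c]
                    if var.kind == "categorical":
                        observed_levels = [
                            l for l in var.levels if (table.data[c] == l).any()
                        ]
                    else:  # binary
                        observed_levels = sorted(table.data[c].dropna().unique())
                    code_of = {lev: k for k, lev in enumerate(observed_levels)}
                    y_codes = df[c].map(code_of).to_numpy(dtype=int)
                    draws = polytomous_draw(
                        rng,
                        y_codes,
                        X,
                        obs,
                        len(observed_levels),
                        spec.ridge,
                        bootstrap=spec.param_uncertainty == "bootstrap",
                    )
                    df.loc[mask[c], c] = [observed_levels[k] for k in draws]
                elif spec.method == "pmm":
                    y = df[c].to_numpy(dtype=float)
                    df.loc[mask[c], c] = pmm_draw(rng, y, X, obs, spec.pmm_donors)
                else:  # normal
                    y = df[c].to_numpy(dtype=float)
                    df.loc[mask[c], c] = _normal_draw(rng, y, X, obs)
        completed.append(df)
    return ImputedDatasets(
        m=m,
        completed=completed,
        provenance={"seed": seed, "n_cycles": n_cycles, "order": order},
    )
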