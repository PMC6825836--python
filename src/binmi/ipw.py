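"""Inverse-probability-weighted complete-case EWAS.

A comparator to multiple imputation: model the probability of being a
complete case from the fully observed covariates, then reweight the
complete cases by the inverse of that probability so they represent the
whole cohort.  IPW is consistent when the missingness model is correct,
but it discards the incomplete cases' methylation information, so its
standard errors are typically larger than those of MI.  Per-site fits
use weighted least squares with heteroskedasticity-robust (sandwich)
standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import ewas
from .datamodel import CovariateTable, MethylationMatrix

__all__ = ["WeightSet", "estimate_weights", "run_ipw_ewas"]


@dataclass
class WeightSet:
    sample_ids: np.ndarray
    completeness_prob: np.ndarray
    weight: np.ndarray  # 0 for incomplete individuals
    trimmed: np.ndarray
    stabilized: bool
    trim_quantile: float | None


def estimate_weights(
    covariates: CovariateTable,
    complete: np.ndarray,
    predictors=("age", "sex"),
    stabilize: bool = True,
    trim_quantile: float | None = 0.99,
) -> WeightSet:
    """Fit a completeness model and return inverse-probability weights.

    Logistic regression of the complete-case indicator on the (fully
    observed) predictors; complete cases receive weight 1/p-hat,
    incomplete cases weight 0.  ``stabilize`` multiplies by the marginal
    completeness rate so weights average ~1; ``trim_quantile`` clips
    weights symmetrically at the (1-q, q) quantiles among complete
    cases.
    """
    complete = np.asarray(complete, dtype=bool)
    if complete.all() or not complete.any():
        if not complete.any():
            raise ValueError("need both complete and incomplete individuals")
        # no missingness: weights are exactly 1 under stabilization
        n = covariates.n
        return WeightSet(
            covariates.sample_ids,
            np.ones(n),
            np.ones(n) if stabilize else np.ones(n),
            np.zeros(n, dtype=bool),
            stabilize,
            trim_quantile,
        )
    cols = covariates.data[list(predictors)]
    if cols.isna().any().any():
        raise ValueError("completeness-model predictors must be fully observed")
    X = sm.add_constant(cols.to_numpy(dtype=float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(complete.astype(float), X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # pragma: no cover - statsmodels wraps several errors
        raise ValueError(f"completeness model failed to fit: {exc}") from exc
    prob = np.asarray(fit.predict(X))
    # quasi-separation (a fully complete stratum) leaves complete-case weights
    # finite and is fine; perfect separation drives some complete case's
    # fitted probability to 0 and the weight to infinity
    if (prob[complete] < 1e-6).any():
        raise ValueError(
            "completeness model is perfectly separated; use fewer predictors or trimming"
        )
    weight = np.where(complete, 1.0 / prob, 0.0)
    if stabilize:
        weight *= complete.mean()
    trimmed = np.zeros(covariates.n, dtype=bool)
    if trim_quantile is not None:
        w_cc = weight[complete]
        lo, hi = np.quantile(w_cc, [1 - trim_quantile, trim_quantile])
        clipped = np.clip(weight, lo, hi)
        trimmed = complete & (clipped != weight)
        weight = np.where(complete, clipped, 0.0)
    return WeightSet(covariates.sample_ids, prob, weight, trimmed, stabilize, trim_quantile)


def run_ipw_ewas(
    methylation: MethylationMatrix,
    covariates: CovariateTable,
    weights: WeightSet,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Weighted per-site EWAS on complete cases with sandwich SEs.

    Output matches the pooled-EWAS table shape, so downstream
    significance and evaluation code treat IPW like any other strategy.
    """
    complete = weights.weight > 0
    if int(complete.sum()) <= 5:
        raise ValueError("effective sample smaller than the model parameter count")
    rows = covariates.sample_ids[complete]
    sub = CovariateTable(covariates.data.loc[rows], dict(covariates.schema))
    pos = pd.Index(methylation.sample_ids).get_indexer(rows)
    Y = methylation.values[:, pos]
    X = ewas.build_design(sub)
    keep = ~np.all(X == 0, axis=0)
    Xk = X[:, keep]
    w = weights.weight[complete]
    n, p = Xk.shape

    XtW = Xk.T * w
    A = np.linalg.inv(XtW @ Xk)
    beta_k = (A @ (XtW @ Y.T)).T  # (S, p)
    resid = Y - beta_k @ Xk.T
    # sandwich: A (X' W diag(e^2) W X) A, HC0
    we2 = (w[None, :] * resid) ** 2  # (S, n)
    meat = np.einsum("ni,sn,nj->sij", Xk, we2, Xk, optimize=True)
    var = np.einsum("ij,sjk,kl->sil", A, meat, A, optimize=True)
    se_k = np.sqrt(np.diagonal(var, axis1=1, axis2=2))
    df = n - p

    beta = np.full((Y.shape[0], 5), np.nan)
    se = np.full((Y.shape[0], 5), np.nan)
    beta[:, keep] = beta_k
    se[:, keep] = se_k
    pvals = ewas._t_pvalues(beta, se, df)
    table = pd.DataFrame(
        {
            "site_id": methylation.site_ids,
            "beta_former": beta[:, 3],
            "se_former": se[:, 3],
            "p_former": pvals[:, 3],
            "beta_current": beta[:, 4],
            "se_current": se[:, 4],
            "p_current": pvals[:, 4],
            "df": float(df),
        }
    )
    table = ewas.mark_significant(table, alpha, n_tests or methylation.n_sites)
    table.attrs["strategy"] = "ipw"
    table.attrs["stabilized"] = weights.stabilized
    table.attrs["trim_quantile"] = weights.trim_quantile
    return table
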