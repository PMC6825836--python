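"""Per-site association models, Bonferroni significance, and Rubin pooling.

The association model at every CpG site is the linear regression

    methylation ~ age + sex + smoking(former) + smoking(current)

with never-smokers as the reference, sex coded 0/1 (female = 0), and age
in years, uncentered.  Across imputed data sets the per-site fits are
combined by Rubin's rules with Barnard–Rubin small-sample degrees of
freedom.  A site is called significant when the smaller of its two
smoking p-values falls below the Bonferroni threshold ``alpha/n_tests``
(a joint Wald F over both smoking terms is available as an alternative
for single fits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CovariateTable, MethylationMatrix

__all__ = [
    "EwasFit",
    "build_design",
    "fit_site_model",
    "fit_ewas",
    "pool_rubin",
    "bonferroni_threshold",
    "significant_sites",
    "mark_significant",
]

DESIGN_COLUMNS = ("intercept", "age", "sex", "smoking_former", "smoking_current")
SMOKING_COEFS = ("former", "current")


@dataclass
class EwasFit:
    """Single-site OLS fit; NaN entries mark inestimable coefficients."""

    site_id: str
    beta: np.ndarray  # over (former, current)
    se: np.ndarray
    df_residual: int
    p: np.ndarray
    p_joint: float = np.nan


# ---------------------------------------------------------------------------
# design construction


def smoking_codes(values: pd.Series, levels=("never", "former", "current")) -> np.ndarray:
    """Integer codes (never=0, former=1, current=2); missing -> -1."""
    codes = pd.Categorical(values, categories=list(levels)).codes
    return np.asarray(codes, dtype=np.int64)


def design_from_parts(age: np.ndarray, sex: np.ndarray, smoke_codes: np.ndarray) -> np.ndarray:
    """Assemble the n x 5 EWAS design from numeric parts (codes 0/1/2)."""
    n = age.shape[0]
    X = np.empty((n, 5))
    X[:, 0] = 1.0
    X[:, 1] = age
    X[:, 2] = sex
    X[:, 3] = smoke_codes == 1
    X[:, 4] = smoke_codes == 2
    return X


def build_design(covariates: CovariateTable, rows: np.ndarray | None = None) -> np.ndarray:
    """EWAS design matrix for the given rows (all rows by default)."""
    df = covariates.data if rows is None else covariates.data.loc[rows]
    codes = smoking_codes(df["smoking"])
    if (codes < 0).any():
        raise ValueError("design rows contain missing smoking values")
    return design_from_parts(
        df["age"].to_numpy(dtype=float), df["sex"].to_numpy(dtype=float), codes
    )


# ---------------------------------------------------------------------------
# OLS cores


def ols_shared_design(Y: np.ndarray, X: np.ndarray):
    """OLS of every row of ``Y`` (S x n) on one design ``X`` (n x p).

    Returns ``(beta, se, df)`` with shapes (S, p), (S, p), scalar.
    Columns that are identically zero (an empty smoking level) are
    dropped from the fit and reported as NaN.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    keep = ~np.all(X == 0, axis=0)
    Xk = X[:, keep]
    pk = Xk.shape[1]
    XtX = Xk.T @ Xk
    XtY = Xk.T @ Y.T
    coef = np.linalg.solve(XtX, XtY)  # (pk, S)
    resid = Y - (Xk @ coef).T
    df = n - pk
    sigma2 = (resid**2).sum(axis=1) / df
    d = np.diag(np.linalg.inv(XtX))
    beta = np.full((Y.shape[0], p), np.nan)
    se = np.full((Y.shape[0], p), np.nan)
    beta[:, keep] = coef.T
    se[:, keep] = np.sqrt(sigma2[:, None] * d[None, :])
    return beta, se, df


def ols_batch_design(Y: np.ndarray, X: np.ndarray):
    """OLS of ``Y[b]`` on ``X[b]`` for a batch of single-outcome designs.

    ``Y`` is (B, n), ``X`` is (B, n, p); all designs must be full rank
    (the caller checks smoking-level presence once per completed data
    set).  Returns ``(beta, se, df)`` with shapes (B, p), (B, p), scalar.
    """
    B, n, p = X.shape
    Xt = X.transpose(0, 2, 1)
    XtX = np.matmul(Xt, X)
    XtY = np.matmul(Xt, Y[..., None])
    coef = np.linalg.solve(XtX, XtY)[..., 0]  # (B, p)
    resid = Y - np.matmul(X, coef[..., None])[..., 0]
    df = n - p
    sigma2 = (resid**2).sum(axis=1) / df
    inv = np.linalg.inv(XtX)
    d = np.diagonal(inv, axis1=1, axis2=2)
    se = np.sqrt(sigma2[:, None] * d)
    return coef, se, df


def _t_pvalues(beta: np.ndarray, se: np.ndarray, df) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.abs(beta / se)
    return 2.0 * stats.t.sf(t, df)


# ---------------------------------------------------------------------------
# public fitting interfaces


def fit_site_model(methylation_row: np.ndarray, covariates: CovariateTable, site_id: str = "") -> EwasFit:
    """Fit the EWAS model at a single site on fully observed rows."""
    X = build_design(covariates)
    y = np.asarray(methylation_row, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("methylation row and covariates disagree on n")
    if X.shape[0] <= 5:
        raise ValueError("need more individuals than model parameters")
    beta, se, df = ols_shared_design(y[None, :], X)
    p = _t_pvalues(beta, se, df)
    p_joint = joint_smoking_f(y, X, df)
    return EwasFit(
        site_id=site_id,
        beta=beta[0, 3:5],
        se=se[0, 3:5],
        df_residual=df,
        p=p[0, 3:5],
        p_joint=p_joint,
    )


def joint_smoking_f(y: np.ndarray, X: np.ndarray, df: int) -> float:
    """Wald F p-value for both smoking terms jointly (single fit)."""
    keep = ~np.all(X == 0, axis=0)
    smoke_cols = [i for i in (3, 4) if keep[i]]
    if not smoke_cols:
        return np.nan
    Xk = X[:, keep]
    reduced_cols = [i for i, c in enumerate(np.flatnonzero(keep)) if c not in (3, 4)]
    Xr = Xk[:, reduced_cols]
    rss_full = _rss(y, Xk)
    rss_red = _rss(y, Xr)
    q = len(smoke_cols)
    F = ((rss_red - rss_full) / q) / (rss_full / df)
    return float(stats.f.sf(F, q, df))


def _rss(y, X):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def fit_ewas(
    methylation: MethylationMatrix,
    covariates: CovariateTable,
    rows: np.ndarray | None = None,
) -> pd.DataFrame:
    """Complete-data (or complete-case) EWAS over all sites.

    ``rows`` restricts to a subset of sample IDs (e.g., complete cases).
    Returns a table with per-site smoking coefficients, SEs, p-values,
    the joint-F p-value, and the residual df.
    """
    if rows is None:
        Y = methylation.values
        X = build_design(covariates)
    else:
        pos = pd.Index(methylation.sample_ids).get_indexer(rows)
        if (pos < 0).any():
            raise ValueError("rows not found among methylation samples")
        Y = methylation.values[:, pos]
        X = build_design(covariates, rows=rows)
    beta, se, df = ols_shared_design(Y, X)
    p = _t_pvalues(beta, se, df)
    out = pd.DataFrame(
        {
            "site_id": methylation.site_ids,
            "beta_former": beta[:, 3],
            "se_former": se[:, 3],
            "p_former": p[:, 3],
            "beta_current": beta[:, 4],
            "se_current": se[:, 4],
            "p_current": p[:, 4],
            "df": float(df),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Rubin's rules


def pool_rubin(qhat: np.ndarray, se: np.ndarray, df_com: int):
    """Pool m per-imputation estimates by Rubin's rules.

    Parameters
    ----------
    qhat, se
        Arrays of shape (m, ...) of estimates and their standard errors;
        trailing axes range over sites/coefficients.
    df_com
        Complete-data residual degrees of freedom.

    Returns
    -------
    dict with ``qbar``, ``W`` (within), ``B`` (between), ``T`` (total),
    ``se``, ``df`` (Barnard–Rubin), and two-sided t ``p``; each of the
    trailing shape.  ``B == 0`` degenerates exactly to the single fit
    with ``df = df_com``.
    """
    qhat = np.asarray(qhat, dtype=float)
    se = np.asarray(se, dtype=float)
    m = qhat.shape[0]
    if m < 2:
        raise ValueError("pooling needs m >= 2")
    qbar = qhat.mean(axis=0)
    W = (se**2).mean(axis=0)
    B = qhat.var(axis=0, ddof=1)
    # identical estimates leave rounding residue ~eps^2 in B; treat as zero
    B = np.where(B <= np.finfo(float).eps ** 2 * (1.0 + qbar**2), 0.0, B)
    T = W + (1.0 + 1.0 / m) * B
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = (1.0 + 1.0 / m) * B / T
        df_old = (m - 1) / lam**2
        df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
        df = df_old * df_obs / (df_old + df_obs)
    df = np.where(B == 0, float(df_com), df)
    se_pool = np.sqrt(T)
    p = _t_pvalues(qbar, se_pool, df)
    return {"qbar": qbar, "W": W, "B": B, "T": T, "se": se_pool, "df": df, "p": p}


# ---------------------------------------------------------------------------
# significance


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


def mark_significant(table: pd.DataFrame, alpha: float, n_tests: int, test: str = "min-p") -> pd.DataFrame:
    """Add/refresh the ``significant`` column under the chosen smoking test."""
    if n_tests < len(table):
        raise ValueError("n_tests must cover at least the rows tested")
    thr = bonferroni_threshold(alpha, n_tests)
    if test == "min-p":
        minp = np.fmin(table["p_former"].to_numpy(), table["p_current"].to_numpy())
        sig = minp < thr
    elif test == "joint-F":
        if "p_joint" not in table.columns:
            raise ValueError("joint-F test requires a p_joint column (single fits only)")
        sig = table["p_joint"].to_numpy() < thr
    else:
        raise ValueError(f"unknown smoking test {test!r}")
    out = table.copy()
    out["significant"] = np.where(np.isnan(sig.astype(float)), False, sig).astype(bool)
    return out


def significant_sites(table: pd.DataFrame, alpha: float, n_tests: int, test: str = "min-p") -> set:
    """Site IDs significant at the Bonferroni level alpha/n_tests."""
    marked = mark_significant(table, alpha, n_tests, test=test)
    return set(marked.loc[marked["significant"], "site_id"])
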