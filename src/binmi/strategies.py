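"""Imputation strategies for high-dimensional covariate imputation.

Imputing a missing covariate without bias requires every analysis-model
outcome — here, every CpG site — to appear in the imputation model, which
is impossible when sites outnumber cases.  The strategies below trade
off between that ideal and computational reality:

* ``complete_case`` — no imputation; analyze rows with observed smoking.
* ``separate``      — one imputation model per site (site + age + sex).
* ``random_bins``   — partition sites into bins of fixed size; impute
  once per bin using all the bin's sites, and analyze each site within
  the bin whose imputation used it.
* ``naive``         — a single imputation model using every site that
  was Bonferroni-significant in the complete-case EWAS.
* ``wu``            — a single model using forward-stepwise BIC
  selection from the top 100 complete-case-associated sites.
* ``wu_bins``       — random bins with the Wu-selected sites added to
  every bin.

Sites left out of the imputation model (possible only under ``naive``
and ``wu``) have their associations attenuated toward the null; the
binned strategies avoid this because every site is used to impute the
covariate for its own analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ewas
from ._multinomial import fit_multinomial, loglik, predict_proba
from ._rng import stream
from .datamodel import SMOKING_LEVELS, AnalysisConfig, CovariateTable, MethylationMatrix
from .mice_engine import _bootstrap_with_all_codes, draw_categories

__all__ = [
    "BinScheme",
    "make_random_bins",
    "make_wu_bins",
    "select_sites_naive",
    "select_sites_wu",
    "run_strategy",
    "cases_per_variable",
    "STRATEGIES",
]

STRATEGIES = ("complete_case", "separate", "random_bins", "naive", "wu", "wu_bins")

#: refuse the separate-sites strategy above this many sites unless forced;
#: one imputation model per site is the paper-scale HPC workload.
SEPARATE_SITE_BUDGET = 20_000


@dataclass
class BinScheme:
    """A partition (or selected-site-augmented cover) of site IDs."""

    strategy: str
    bins: list[list[str]]
    always_included: list[str] = field(default_factory=list)
    bin_size: int = 0
    seed: int = 0

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def cases_per_variable(n_complete: int, bin_size: int) -> float:
    """Cases-to-variables ratio of a bin's imputation model (sites + age + sex)."""
    return n_complete / (bin_size + 2)


def make_random_bins(site_ids, bin_size: int, seed: int) -> BinScheme:
    """Shuffle sites and chunk into consecutive bins of ``bin_size``.

    The last bin may be smaller; the bin count is ceil(N / bin_size).
    """
    site_ids = list(site_ids)
    if not site_ids:
        raise ValueError("cannot bin an empty site list")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    order = np.array(site_ids, dtype=object)
    stream(seed, "bins").shuffle(order)
    bins = [list(order[i : i + bin_size]) for i in range(0, len(order), bin_size)]
    return BinScheme("random_bins", bins, bin_size=bin_size, seed=seed)


def make_wu_bins(site_ids, selected, bin_size: int, seed: int) -> BinScheme:
    """Random bins that all contain the selected sites.

    Non-selected sites are shuffled and chunked into groups of
    ``bin_size - |selected|``; each bin is the selected set plus one
    chunk, so the count is ceil((N - s) / (bin_size - s)).
    """
    selected = list(selected)
    s = len(selected)
    if s >= bin_size:
        raise ValueError(
            f"{s} selected sites do not fit in bins of {bin_size}; increase bin_size"
        )
    sel_set = set(selected)
    rest = [x for x in site_ids if x not in sel_set]
    if not rest:
        raise ValueError("no non-selected sites to bin")
    order = np.array(rest, dtype=object)
    stream(seed, "bins").shuffle(order)
    chunk = bin_size - s
    bins = [selected + list(order[i : i + chunk]) for i in range(0, len(order), chunk)]
    return BinScheme("wu_bins", bins, always_included=selected, bin_size=bin_size, seed=seed)


def select_sites_naive(cc_results: pd.DataFrame, alpha: float, n_tests: int) -> list[str]:
    """Sites Bonferroni-significant in the complete-case EWAS, by ascending p."""
    marked = ewas.mark_significant(cc_results, alpha, n_tests)
    sig = marked[marked["significant"]].copy()
    sig["minp"] = np.fmin(sig["p_former"], sig["p_current"])
    sig = sig.sort_values(["minp", "site_id"])
    return list(sig["site_id"])


def select_sites_wu(
    cc_results: pd.DataFrame,
    methylation: MethylationMatrix,
    covariates: CovariateTable,
    top_k: int = 100,
    ridge: float = 1e-5,
) -> list[str]:
    """Forward-stepwise BIC selection of imputation predictors.

    Candidates are the ``top_k`` sites by complete-case association
    (ascending min of the two smoking p-values, ties by site ID).
    Starting from the base multinomial model smoking ~ age + sex fitted
    on complete cases, the candidate whose addition most decreases
    BIC = -2 logL + q log n is added until no candidate decreases it.
    Selected sites are returned in addition order.
    """
    if top_k == 0:
        return []
    ranked = cc_results.copy()
    ranked["minp"] = np.fmin(ranked["p_former"], ranked["p_current"])
    ranked = ranked.sort_values(["minp", "site_id"])
    candidates = list(ranked["site_id"].iloc[:top_k])

    complete = covariates.complete_mask(["smoking"])
    n = int(complete.sum())
    if n < 30:
        raise ValueError("need at least 30 complete cases for stepwise selection")
    rows = covariates.data.loc[complete]
    codes_full = ewas.smoking_codes(rows["smoking"])
    observed_levels = [l for k, l in enumerate(SMOKING_LEVELS) if (codes_full == k).any()]
    remap = {SMOKING_LEVELS.index(l): k for k, l in enumerate(observed_levels)}
    y = np.array([remap[c] for c in codes_full])
    K = len(observed_levels)
    if K < 2:
        raise ValueError("smoking is constant among complete cases; base model cannot fit")

    site_pos = pd.Index(methylation.site_ids)
    sample_pos = pd.Index(methylation.sample_ids).get_indexer(rows.index)
    meth_cc = methylation.values[:, sample_pos]  # sites x complete cases

    base = np.column_stack(
        [np.ones(n), rows["age"].to_numpy(float), rows["sex"].to_numpy(float)]
    )

    def bic_of(ll: np.ndarray, p_cols: int) -> np.ndarray:
        return -2.0 * ll + (K - 1) * p_cols * np.log(n)

    beta0 = fit_multinomial(base, y, K, ridge=ridge, max_iter=60, tol=1e-8)
    bic_cur = float(bic_of(loglik(base, y, beta0, K), base.shape[1]))

    selected: list[str] = []
    X_cur = base
    remaining = list(candidates)
    while remaining:
        cols = meth_cc[site_pos.get_indexer(remaining)]  # (B, n)
        Xb = np.broadcast_to(X_cur, (len(remaining),) + X_cur.shape)
        Xb = np.concatenate([Xb, cols[:, :, None]], axis=2)
        betas = fit_multinomial(Xb, y, K, ridge=ridge, max_iter=60, tol=1e-8)
        bics = bic_of(loglik(Xb, y, betas, K), X_cur.shape[1] + 1)
        best = int(np.argmin(bics))
        if bics[best] >= bic_cur:
            break
        bic_cur = float(bics[best])
        chosen = remaining.pop(best)
        selected.append(chosen)
        X_cur = np.column_stack([X_cur, meth_cc[site_pos.get_loc(chosen)]])
    return selected


# ---------------------------------------------------------------------------
# orchestration


def _smoking_state(covariates: CovariateTable):
    """Observed smoking codes and the design bookkeeping shared by all bins."""
    smoking = covariates.data["smoking"]
    obs = smoking.notna().to_numpy()
    observed_levels = [l for l in SMOKING_LEVELS if (smoking == l).any()]
    if "never" not in observed_levels and len(observed_levels) > 1:
        raise ValueError("no never-smokers observed; smoking dummies are collinear")
    code_of = {lev: k for k, lev in enumerate(observed_levels)}
    y = np.full(covariates.n, -1, dtype=np.int8)
    for lev, k in code_of.items():
        y[(smoking == lev).to_numpy()] = k
    full_code = np.array([SMOKING_LEVELS.index(l) for l in observed_levels])
    return obs, y, observed_levels, full_code


def _impute_bins(methylation, covariates, scheme, config) -> list[np.ndarray]:
    """m completed smoking-code vectors per bin.

    Each bin fits the polytomous model smoking ~ age + sex + (the bin's
    sites) on the complete cases and draws categories for the missing
    cases from the fitted probabilities, independently per imputation
    (mice-polyreg semantics; ``config.param_uncertainty = "bootstrap"``
    refits on a resample per imputation instead).  Draws for (bin, i)
    come from their own named stream, so results are independent of
    scheduling; bins of equal size share one batched Newton solve.
    """
    obs, y, observed_levels, _ = _smoking_state(covariates)
    K = len(observed_levels)
    n = covariates.n
    n_obs = int(obs.sum())
    age = covariates.data["age"].to_numpy(float)
    sex = covariates.data["sex"].to_numpy(float)
    site_pos = pd.Index(methylation.site_ids)
    mis_idx = np.flatnonzero(~obs)
    obs_idx = np.flatnonzero(obs)
    m = config.m

    completed = [None] * scheme.n_bins
    if not mis_idx.size or K == 1:
        # nothing to impute (or a degenerate one-category fill)
        codes = y.copy()
        codes[mis_idx] = 0
        for b in range(scheme.n_bins):
            completed[b] = np.broadcast_to(codes, (m, n)).copy()
        return completed

    by_size: dict[int, list[int]] = {}
    for b, sites in enumerate(scheme.bins):
        by_size.setdefault(len(sites), []).append(b)

    yo = y[obs_idx]
    for size, group in by_size.items():
        p = 3 + size
        if p >= n_obs:
            raise ValueError(
                f"bin of {size} sites gives {p - 1} predictors with only {n_obs} "
                "complete cases; use smaller bins"
            )
        Bg = len(group)
        X = np.empty((Bg, n, p))
        X[:, :, 0] = 1.0
        X[:, :, 1] = age
        X[:, :, 2] = sex
        for j, b in enumerate(group):
            rows = site_pos.get_indexer(scheme.bins[b])
            X[j, :, 3:] = methylation.values[rows].T
        Xo = X[:, obs_idx, :]
        Xm = X[:, mis_idx, :]
        out = np.empty((Bg, m, n), dtype=np.int8)
        out[:] = y
        if config.param_uncertainty == "none":
            beta = fit_multinomial(Xo, yo, K, ridge=config.ridge)
            probs = predict_proba(Xm, beta, K)  # (Bg, n_mis, K)
            for j, b in enumerate(group):
                for i in range(m):
                    rng = stream(config.seed, "impute", b, i)
                    out[j, i, mis_idx] = draw_categories(rng, probs[j])
        else:
            for i in range(m):
                rngs = [stream(config.seed, "impute", b, i) for b in group]
                boot = np.stack(
                    [_bootstrap_with_all_codes(rng, yo, K) for rng in rngs]
                )  # (Bg, n_obs)
                Xb = np.take_along_axis(Xo, boot[:, :, None], axis=1)
                yb = yo[boot]
                beta = fit_multinomial(Xb, yb, K, ridge=config.ridge)
                probs = predict_proba(Xm, beta, K)
                for j, rng in enumerate(rngs):
                    out[j, i, mis_idx] = draw_categories(rng, probs[j])
        for j, b in enumerate(group):
            completed[b] = out[j]
    return completed


def _pool_bin(Y, age, sex, full_codes_m, keep):
    """Fit the EWAS at the given site rows for each completed data set
    and pool by Rubin's rules.  Returns per-site pooled columns."""
    m = full_codes_m.shape[0]
    qhat = np.empty((m, Y.shape[0], 2))
    sehat = np.empty((m, Y.shape[0], 2))
    df_com = None
    for i in range(m):
        X = ewas.design_from_parts(age, sex, full_codes_m[i])[:, keep]
        beta, se, df_com = ewas.ols_shared_design(Y, X)
        # map kept columns back to (former, current)
        bfull = np.full((Y.shape[0], 5), np.nan)
        sfull = np.full((Y.shape[0], 5), np.nan)
        bfull[:, keep] = beta
        sfull[:, keep] = se
        qhat[i] = bfull[:, 3:5]
        sehat[i] = sfull[:, 3:5]
    return ewas.pool_rubin(qhat, sehat, df_com)


def run_strategy(
    strategy: str,
    methylation: MethylationMatrix,
    covariates: CovariateTable,
    config: AnalysisConfig,
    force: bool = False,
) -> pd.DataFrame:
    """Run one imputation strategy end to end and pool the EWAS.

    Returns a per-site table (original site order, every site exactly
    once) with pooled smoking coefficients, SEs, Barnard–Rubin df
    (reported as the smaller of the two coefficients' df), t-based
    p-values, and Bonferroni significance at ``alpha / n_sites``.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    n_sites = methylation.n_sites
    site_ids = list(methylation.site_ids)

    if strategy == "complete_case":
        rows = covariates.sample_ids[covariates.complete_mask(["smoking"])]
        table = ewas.fit_ewas(methylation, covariates, rows=rows)
        table = ewas.mark_significant(table, config.alpha, n_sites)
        table.attrs["strategy"] = strategy
        return table

    obs, _, observed_levels, full_code = _smoking_state(covariates)
    keep = [0, 1, 2]
    if "former" in observed_levels:
        keep.append(3)
    if "current" in observed_levels:
        keep.append(4)

    cc_table = None
    if strategy in ("naive", "wu", "wu_bins"):
        cc_table = ewas.fit_ewas(methylation, covariates, rows=covariates.sample_ids[obs])

    if strategy == "separate":
        if n_sites > SEPARATE_SITE_BUDGET and not force:
            raise ValueError(
                f"separate-sites strategy over {n_sites} sites means {n_sites} "
                "imputation procedures; pass force=True to run anyway"
            )
        scheme = BinScheme("separate", [[s] for s in site_ids], bin_size=1, seed=config.seed)
    elif strategy == "random_bins":
        scheme = make_random_bins(site_ids, config.bin_size, config.seed)
    elif strategy == "naive":
        selected = select_sites_naive(cc_table, config.alpha, n_sites)
        scheme = BinScheme("naive", [selected], always_included=selected, seed=config.seed)
    elif strategy == "wu":
        selected = select_sites_wu(cc_table, methylation, covariates, ridge=config.ridge)
        scheme = BinScheme("wu", [selected], always_included=selected, seed=config.seed)
    else:  # wu_bins
        selected = select_sites_wu(cc_table, methylation, covariates, ridge=config.ridge)
        scheme = make_wu_bins(site_ids, selected, config.bin_size, config.seed)

    completed = _impute_bins(methylation, covariates, scheme, config)

    age = covariates.data["age"].to_numpy(float)
    sex = covariates.data["sex"].to_numpy(float)
    n = covariates.n
    site_pos = pd.Index(methylation.site_ids)

    frames = []
    if strategy in ("naive", "wu"):
        # one imputation serves every site
        full_codes_m = full_code[completed[0]]
        pooled = _pool_bin(methylation.values, age, sex, full_codes_m, keep)
        frames.append(_pooled_frame(site_ids, pooled))
    elif strategy == "separate":
        # all bins singleton: batch the EWAS across bins per imputation
        m = config.m
        B = scheme.n_bins
        qhat = np.empty((m, B, 2))
        sehat = np.empty((m, B, 2))
        Y = methylation.values  # bin b analyzes site b (scheme preserves order)
        codes = np.stack(completed)  # (B, m, n)
        df_com = n - len(keep)
        for i in range(m):
            fc = full_code[codes[:, i, :]]  # (B, n)
            X = np.empty((B, n, len(keep)))
            X[:, :, 0] = 1.0
            X[:, :, 1] = age
            X[:, :, 2] = sex
            col = 3
            if 3 in keep:
                X[:, :, col] = fc == 1
                col += 1
            if 4 in keep:
                X[:, :, col] = fc == 2
            beta, se, df_com = ewas.ols_batch_design(Y, X)
            bfull = np.full((B, 5), np.nan)
            sfull = np.full((B, 5), np.nan)
            bfull[:, keep] = beta
            sfull[:, keep] = se
            qhat[i] = bfull[:, 3:5]
            sehat[i] = sfull[:, 3:5]
        pooled = ewas.pool_rubin(qhat, sehat, df_com)
        frames.append(_pooled_frame(site_ids, pooled))
    else:
        for b, sites in enumerate(scheme.bins):
            own = [s for s in sites if scheme.strategy != "wu_bins" or s not in scheme.always_included]
            if scheme.strategy == "wu_bins" and b == 0:
                own = scheme.always_included + own  # selected sites analyzed once, in bin 0
            rows = site_pos.get_indexer(own)
            full_codes_m = full_code[completed[b]]
            pooled = _pool_bin(methylation.values[rows], age, sex, full_codes_m, keep)
            frames.append(_pooled_frame(own, pooled))

    table = pd.concat(frames, ignore_index=True)
    table = table.set_index("site_id").loc[site_ids].reset_index()
    table = ewas.mark_significant(table, config.alpha, n_sites)
    table.attrs["strategy"] = strategy
    table.attrs["n_bins"] = scheme.n_bins
    table.attrs["always_included"] = list(scheme.always_included)
    return table


def _pooled_frame(site_ids, pooled) -> pd.DataFrame:
    df = np.fmin(pooled["df"][:, 0], pooled["df"][:, 1])
    return pd.DataFrame(
        {
            "site_id": site_ids,
            "beta_former": pooled["qbar"][:, 0],
            "se_former": pooled["se"][:, 0],
            "p_former": pooled["p"][:, 0],
            "beta_current": pooled["qbar"][:, 1],
            "se_current": pooled["se"][:, 1],
            "p_current": pooled["p"][:, 1],
            "df": df,
            "B_former": pooled["B"][:, 0],
            "B_current": pooled["B"][:, 1],
        }
    )
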