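"""Performance metrics and the replicate-level simulation study.

"Truth" throughout is the EWAS on the complete (no-missingness) data of
the same synthetic replicate, not the generating effect sizes: the
question a practitioner faces is how much of the complete-data answer a
method recovers after covariate values go missing.  The true-positive
rate is the percentage of complete-data-significant sites a method also
flags; the false-positive rate is the percentage of the method's
significant sites that the complete data did not flag (a
false-discovery proportion).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ewas, ipw, strategies
from ._rng import child_seed
from .datamodel import AnalysisConfig, CovariateTable
from .synthetic_data import (
    CohortSpec,
    EffectSpec,
    MissingnessMechanism,
    apply_missingness,
    generate_cohort,
    generate_methylation,
)

__all__ = [
    "tp_fp_rates",
    "bias_table",
    "site_groups",
    "StudyConfig",
    "run_simulation_study",
]


def tp_fp_rates(found: set, truth: set) -> tuple[float, float]:
    """True-positive and false-positive percentages.

    tp = 100 * |found ∩ truth| / |truth|;
    fp = 100 * |found \\ truth| / |found|, NaN when nothing was found.
    """
    if not truth:
        raise ValueError("truth set is empty")
    tp = 100.0 * len(found & truth) / len(truth)
    fp = 100.0 * len(found - truth) / len(found) if found else float("nan")
    return tp, fp


def site_groups(
    truth_results: pd.DataFrame, selected: set, truth_significant: set
) -> pd.DataFrame:
    """Site partition underlying the bias breakdown.

    Groups: ``selected`` (sites the imputation model used),
    ``true_not_selected`` (complete-data-significant but unused), and
    ``other``; each split by the sign of the complete-data former-smoker
    coefficient.
    """
    out = truth_results[["site_id", "beta_former"]].copy()

    def grp(sid):
        if sid in selected:
            return "selected"
        if sid in truth_significant:
            return "true_not_selected"
        return "other"

    out["group"] = out["site_id"].map(grp)
    out["sign"] = np.where(out["beta_former"] > 0, "positive", "negative")
    return out[["site_id", "group", "sign"]]


def bias_table(
    method_results: pd.DataFrame,
    truth_results: pd.DataFrame,
    groups: pd.DataFrame,
    coefficient: str = "former",
) -> pd.DataFrame:
    """Per-group mean coefficient, SE, bias, and bias SD.

    Bias per site is the method's coefficient minus the complete-data
    coefficient.  ``groups`` must carry ``site_id``, ``group``, ``sign``
    covering the same sites as both tables.
    """
    b, s = f"beta_{coefficient}", f"se_{coefficient}"
    merged = method_results[["site_id", b, s]].merge(
        truth_results[["site_id", b]], on="site_id", suffixes=("", "_truth"), validate="1:1"
    )
    if len(merged) != len(method_results) or len(merged) != len(truth_results):
        raise ValueError("method and truth tables cover different sites")
    merged = merged.merge(groups, on="site_id", validate="1:1")
    merged["bias"] = merged[b] - merged[f"{b}_truth"]
    agg = (
        merged.groupby(["group", "sign"], observed=True)
        .agg(
            n_sites=("site_id", "size"),
            mean_beta=(b, "mean"),
            mean_se=(s, "mean"),
            mean_bias=("bias", "mean"),
            sd_bias=("bias", lambda x: x.std(ddof=1)),
        )
        .reset_index()
    )
    return agg


@dataclass
class StudyConfig:
    """Desk-scale analogue of the full simulation design.

    The defaults keep the cohort at the reference size (464
    individuals) while shrinking the array to 2,000 sites with 40
    planted smoking effects, so the whole study runs on a single CPU.
    ``strategies`` pairs a strategy name with a bin size (None where the
    strategy takes none); bin sizes 150 and 45 are the ~3:1 and ~10:1
    cases-to-variables settings.
    """

    n_individuals: int = 464
    n_sites: int = 2000
    n_true: int = 40
    mechanisms: tuple[str, ...] = ("MM1",)
    strategies: tuple[tuple[str, int | None], ...] = (
        ("complete_case", None),
        ("separate", None),
        ("random_bins", 45),
        ("random_bins", 150),
    )
    repeats: int = 10
    m: int = 20
    alpha: float = 0.05
    seed: int = 0
    effect_spec: EffectSpec | None = None
    cohort_spec: CohortSpec | None = None
    keep_site_tables: bool = False

    def label(self, name: str, bin_size) -> str:
        if name == "random_bins":
            return f"random_bins_{bin_size}"
        if name == "wu_bins":
            return f"wu_bins_{bin_size}"
        return name


def run_simulation_study(config: StudyConfig, verbose: bool = False):
    """Generate replicates, run every mechanism x strategy, score them.

    For each repeat: draw a cohort and methylation matrix, compute the
    complete-data "truth" EWAS and its significant-site set, apply each
    missingness mechanism, run each strategy, and record true/false
    positive percentages and the mean/SD of the former-smoker SEs across
    sites.  Returns a tidy table with one row per
    (repeat, mechanism, strategy); with ``keep_site_tables`` also a dict
    of the per-site tables keyed by (repeat, mechanism, label) plus
    ``(repeat, 'truth')`` entries.
    """
    cohort_spec = config.cohort_spec or CohortSpec(n_individuals=config.n_individuals)
    effect_spec = config.effect_spec or EffectSpec(
        n_sites=config.n_sites, n_true=config.n_true
    )
    if verbose:
        n_runs = config.repeats * len(config.mechanisms) * len(config.strategies)
        print(
            f"study scale: {config.repeats} repeats x {len(config.mechanisms)} "
            f"mechanisms x {len(config.strategies)} strategies = {n_runs} runs at "
            f"{config.n_sites} sites, n = {cohort_spec.n_individuals}, m = {config.m}"
        )
    rows = []
    tables: dict = {}
    for rep in range(config.repeats):
        cohort = generate_cohort(cohort_spec, child_seed(config.seed, "cohort", rep))
        meth, truth_gen = generate_methylation(
            cohort, effect_spec, child_seed(config.seed, "meth", rep)
        )
        truth_table = ewas.fit_ewas(meth, cohort)
        truth_table = ewas.mark_significant(truth_table, config.alpha, meth.n_sites)
        truth_sig = set(truth_table.loc[truth_table["significant"], "site_id"])
        if config.keep_site_tables:
            tables[(rep, "truth")] = truth_table
            tables[(rep, "generating")] = truth_gen
        for mech_name in config.mechanisms:
            mech = MissingnessMechanism.by_name(mech_name)
            observed = apply_missingness(
                cohort, mech, ["smoking"], child_seed(config.seed, "miss", rep, mech_name)
            )
            missing_frac = float(observed.data["smoking"].isna().mean())
            for name, bin_size in config.strategies:
                label = config.label(name, bin_size)
                run_cfg = AnalysisConfig(
                    bin_size=bin_size or 45,
                    m=config.m,
                    alpha=config.alpha,
                    seed=child_seed(config.seed, "run", rep, mech_name, label),
                )
                t0 = time.perf_counter()
                if name == "ipw":
                    ws = ipw.estimate_weights(
                        observed, observed.complete_mask(["smoking"])
                    )
                    table = ipw.run_ipw_ewas(
                        meth, observed, ws, alpha=config.alpha
                    )
                else:
                    table = strategies.run_strategy(
                        name, meth, observed, run_cfg, force=True
                    )
                elapsed = time.perf_counter() - t0
                found = set(table.loc[table["significant"], "site_id"])
                if truth_sig:
                    tp, fp = tp_fp_rates(found, truth_sig)
                    excluded = False
                else:  # degenerate replicate: no complete-data signal
                    tp, fp, excluded = float("nan"), float("nan"), True
                rows.append(
                    {
                        "repeat": rep,
                        "mechanism": mech_name,
                        "strategy": label,
                        "n_significant": len(found),
                        "n_truth": len(truth_sig),
                        "tp_pct": tp,
                        "fp_pct": fp,
                        "mean_se_former": float(table["se_former"].mean()),
                        "sd_se_former": float(table["se_former"].std(ddof=1)),
                        "missing_frac": missing_frac,
                        "excluded": excluded,
                        "seconds": elapsed,
                    }
                )
                if config.keep_site_tables:
                    tables[(rep, mech_name, label)] = table
                if verbose:
                    print(
                        f"rep {rep} {mech_name} {label}: {len(found)} significant, "
                        f"tp {tp:.1f}% fp {fp:.1f}% ({elapsed:.1f}s)"
                    )
    result = pd.DataFrame(rows)
    return (result, tables) if config.keep_site_tables else result
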