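import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from binmi.datamodel import AnalysisConfig
from binmi.ewas import fit_ewas, mark_significant
from binmi.strategies import (
    BinScheme,
    cases_per_variable,
    make_random_bins,
    make_wu_bins,
    run_strategy,
    select_sites_naive,
    select_sites_wu,
)
from binmi.synthetic_data import (
    CohortSpec,
    EffectSpec,
    MissingnessMechanism,
    apply_missingness,
    generate_cohort,
    generate_methylation,
)


class TestRandomBins:
    def test_reference_450k_bin_counts(self):
        # 482,739 sites at the two cases:variables settings used in practice
        ids = [f"cg{i}" for i in range(482_739)]
        assert make_random_bins(ids, 150, seed=0).n_bins == 3219
        assert make_random_bins(ids, 45, seed=0).n_bins == 10_728

    def test_single_chunk(self):
        scheme = make_random_bins([f"s{i}" for i in range(10)], 10, seed=1)
        assert scheme.n_bins == 1
        assert sorted(scheme.bins[0]) == sorted(f"s{i}" for i in range(10))

    def test_partition_property(self):
        ids = [f"s{i}" for i in range(107)]
        scheme = make_random_bins(ids, 10, seed=2)
        flat = [s for b in scheme.bins for s in b]
        assert sorted(flat) == sorted(ids)
        assert all(len(b) <= 10 for b in scheme.bins)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            make_random_bins([], 5, seed=0)

    @given(n=hs.integers(1, 3000), b=hs.integers(1, 500))
    @settings(max_examples=30)
    def test_bin_count_formula(self, n, b):
        scheme = make_random_bins([f"s{i}" for i in range(n)], b, seed=3)
        assert scheme.n_bins == math.ceil(n / b)


class TestWuBins:
    def test_selected_in_every_bin(self):
        ids = [f"s{i}" for i in range(100)]
        scheme = make_wu_bins(ids, ["s3", "s7"], 10, seed=4)
        assert scheme.n_bins == 13  # ceil(98 / 8)
        for b in scheme.bins:
            assert len(b) <= 10
            assert {"s3", "s7"} <= set(b)

    def test_empty_selection_reduces_to_random_bins(self):
        ids = [f"s{i}" for i in range(57)]
        a = make_wu_bins(ids, [], 9, seed=5)
        b = make_random_bins(ids, 9, seed=5)
        assert a.bins == b.bins

    def test_all_but_one_selected_single_bin(self):
        ids = [f"s{i}" for i in range(6)]
        scheme = make_wu_bins(ids, ids[:5], 7, seed=6)
        assert scheme.n_bins == 1

    def test_oversized_selection_rejected(self):
        with pytest.raises(ValueError, match="bin_size"):
            make_wu_bins([f"s{i}" for i in range(20)], [f"s{i}" for i in range(5)], 5, seed=7)

    @given(
        n=hs.integers(10, 2000),
        b=hs.integers(2, 200),
        s=hs.integers(0, 100),
    )
    @settings(max_examples=30)
    def test_wu_bin_count_formula(self, n, b, s):
        if s >= b or s >= n:
            return
        ids = [f"s{i}" for i in range(n)]
        scheme = make_wu_bins(ids, ids[:s], b, seed=8)
        assert scheme.n_bins == math.ceil((n - s) / (b - s))
        # every non-selected site in exactly one bin
        from collections import Counter

        counts = Counter(x for bin_ in scheme.bins for x in bin_ if x not in set(ids[:s]))
        assert all(v == 1 for v in counts.values())
        assert len(counts) == n - s

    def test_cases_per_variable_helper(self):
        assert cases_per_variable(464, 150) == pytest.approx(464 / 152)


@pytest.fixture(scope="module")
def small_run(cohort464):
    meth, truth = generate_methylation(
        cohort464, EffectSpec(n_sites=300, n_true=15), seed=201
    )
    observed = apply_missingness(
        cohort464, MissingnessMechanism.mm1(), ["smoking"], seed=202
    )
    return meth, truth, observed


class TestSelection:
    def test_naive_monotone_in_alpha(self, small_run, cohort464):
        meth, _, observed = small_run
        cc = fit_ewas(meth, cohort464, rows=cohort464.sample_ids[observed.complete_mask(["smoking"])])
        sel_small = set(select_sites_naive(cc, 0.01, 300))
        sel_large = set(select_sites_naive(cc, 0.05, 300))
        assert sel_small <= sel_large

    def test_naive_empty_allowed(self, small_run, cohort464):
        meth, _, _ = small_run
        cc = fit_ewas(meth, cohort464)
        assert select_sites_naive(cc, 1e-12, 300) == []

    def test_strong_site_selected_by_naive_and_wu_first(self, cohort464):
        spec = EffectSpec(
            n_sites=400,
            n_true=1,
            effect_range_former=(2.0, 2.0),
            effect_range_current=(2.0, 2.0),
            sign_mix=1.0,
        )
        meth, truth = generate_methylation(cohort464, spec, seed=203)
        strong = truth.loc[truth["is_true"], "site_id"].iloc[0]
        cc = fit_ewas(meth, cohort464)
        assert strong in select_sites_naive(cc, 0.05, 400)
        wu = select_sites_wu(cc, meth, cohort464)
        assert wu[0] == strong

    def test_wu_topk_zero_empty(self, small_run, cohort464):
        meth, _, _ = small_run
        cc = fit_ewas(meth, cohort464)
        assert select_sites_wu(cc, meth, cohort464, top_k=0) == []

    def test_wu_resists_pure_noise(self, cohort464):
        # BIC's log-n penalty should keep chance associations out
        sizes = []
        for rep in range(20):
            meth, _ = generate_methylation(
                cohort464, EffectSpec(n_sites=150, n_true=0), seed=400 + rep
            )
            cc = fit_ewas(meth, cohort464)
            sizes.append(len(select_sites_wu(cc, meth, cohort464, top_k=100)))
        assert np.mean([s <= 2 for s in sizes]) >= 0.9


class TestRunStrategy:
    def cfg(self, **kw):
        kw.setdefault("bin_size", 45)
        kw.setdefault("m", 5)
        kw.setdefault("seed", 99)
        return AnalysisConfig(**kw)

    def test_complete_case_equals_ewas_on_complete_rows(self, small_run, cohort464):
        meth, _, observed = small_run
        table = run_strategy("complete_case", meth, observed, self.cfg())
        rows = cohort464.sample_ids[observed.complete_mask(["smoking"])]
        direct = fit_ewas(meth, cohort464, rows=rows)
        direct = mark_significant(direct, 0.05, meth.n_sites)
        np.testing.assert_array_equal(table["beta_former"], direct["beta_former"])
        np.testing.assert_array_equal(table["significant"], direct["significant"])

    @pytest.mark.parametrize("strategy", ["separate", "random_bins", "naive", "wu_bins"])
    def test_zero_missingness_recovers_complete_data_ewas(self, strategy, cohort464):
        meth, _ = generate_methylation(cohort464, EffectSpec(n_sites=60, n_true=5), seed=204)
        table = run_strategy(strategy, meth, cohort464, self.cfg(bin_size=20), force=True)
        direct = fit_ewas(meth, cohort464)
        np.testing.assert_allclose(table["beta_former"], direct["beta_former"], atol=1e-10)
        np.testing.assert_allclose(table["se_former"], direct["se_former"], atol=1e-10)
        assert (table["B_former"] == 0).all()
        np.testing.assert_allclose(table["df"], direct["df"], atol=1e-10)

    @pytest.mark.parametrize("strategy,bs", [("random_bins", 37), ("wu_bins", 41), ("separate", 1)])
    def test_partition_integrity(self, small_run, strategy, bs):
        meth, _, observed = small_run
        table = run_strategy(strategy, meth, observed, self.cfg(bin_size=bs), force=True)
        assert len(table) == meth.n_sites
        assert sorted(table["site_id"]) == sorted(meth.site_ids)
        assert list(table["site_id"]) == list(meth.site_ids)  # original order

    def test_determinism_bit_identical(self, small_run):
        meth, _, observed = small_run
        a = run_strategy("random_bins", meth, observed, self.cfg())
        b = run_strategy("random_bins", meth, observed, self.cfg())
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_separate_budget_guard(self, small_run):
        meth, _, observed = small_run
        import binmi.strategies as st

        old = st.SEPARATE_SITE_BUDGET
        st.SEPARATE_SITE_BUDGET = 100
        try:
            with pytest.raises(ValueError, match="force"):
                run_strategy("separate", meth, observed, self.cfg())
        finally:
            st.SEPARATE_SITE_BUDGET = old

    def test_unknown_strategy(self, small_run):
        meth, _, observed = small_run
        with pytest.raises(ValueError, match="unknown strategy"):
            run_strategy("magic", meth, observed, self.cfg())

    def test_pooled_se_below_complete_case(self, small_run):
        # MI uses all 464 rows, so pooled SEs should undercut the
        # complete-case SEs on average
        meth, _, observed = small_run
        cc = run_strategy("complete_case", meth, observed, self.cfg())
        mi = run_strategy("random_bins", meth, observed, self.cfg(m=10))
        assert mi["se_former"].mean() < cc["se_former"].mean()

    def test_bootstrap_mode_runs_and_increases_B(self, small_run):
        meth, _, observed = small_run
        sub_ids = list(meth.site_ids[:40])
        pos = [list(meth.site_ids).index(s) for s in sub_ids]
        from binmi.datamodel import MethylationMatrix

        sub = MethylationMatrix(
            np.array(sub_ids, object), meth.sample_ids, meth.values[pos], standardized=True
        )
        plain = run_strategy("random_bins", sub, observed, self.cfg(bin_size=20, m=10))
        boot = run_strategy(
            "random_bins", sub, observed,
            self.cfg(bin_size=20, m=10, param_uncertainty="bootstrap"),
        )
        assert boot["B_former"].mean() > plain["B_former"].mean()
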