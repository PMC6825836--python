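import numpy as np
import pandas as pd
import pytest
from scipy import stats

from binmi.datamodel import CovariateTable, Variable
from binmi.mice_engine import (
    ImputationModelSpec,
    impute_categorical,
    impute_pmm,
    run_chained_equations,
)


def series(values):
    return pd.Series(values, index=[f"s{i}" for i in range(len(values))])


class TestImputeCategorical:
    def test_one_observed_category_fills_deterministically(self):
        target = series(["former", "former", None, "former", None])
        x = np.arange(5.0)[:, None]
        out = impute_categorical(target, x, m=4, seed=0)
        for filled in out.completed:
            assert (filled == "former").all()

    def test_no_missing_is_identity(self):
        target = series(["never", "former", "current", "never"])
        x = np.arange(4.0)[:, None]
        out = impute_categorical(target, x, m=3, seed=1)
        for filled in out.completed:
            pd.testing.assert_series_equal(filled, target)

    @pytest.mark.parametrize("mode", ["none", "bootstrap"])
    def test_separated_predictor_drives_imputation(self, mode):
        # y = A iff x < 0; a missing case at x = -5 should be imputed A
        x = np.concatenate([np.linspace(-3, -0.5, 25), np.linspace(0.5, 3, 25), [-5.0]])
        y = ["A"] * 25 + ["B"] * 25 + [None]
        out = impute_categorical(series(y), x[:, None], m=100, seed=2, param_uncertainty=mode)
        draws = [filled.iloc[-1] for filled in out.completed]
        assert np.mean([d == "A" for d in draws]) >= 0.95

    def test_observed_values_never_altered(self):
        rng = np.random.default_rng(3)
        y = np.where(rng.random(80) < 0.5, "never", "former").astype(object)
        y[rng.random(80) < 0.3] = None
        target = series(list(y))
        x = rng.normal(0, 1, (80, 2))
        out = impute_categorical(target, x, m=10, seed=4)
        obs = target.notna()
        for filled in out.completed:
            assert (filled[obs] == target[obs]).all()
            assert filled.notna().all()
            assert filled.isin(["never", "former"]).all()

    def test_draws_vary_between_imputations(self):
        rng = np.random.default_rng(5)
        y = np.where(rng.random(100) < 0.5, "never", "former").astype(object)
        y[rng.random(100) < 0.4] = None
        out = impute_categorical(series(list(y)), rng.normal(0, 1, (100, 1)), m=20, seed=6)
        mats = np.stack([(f == "former").to_numpy() for f in out.completed])
        assert mats[:, pd.Series(y).isna().to_numpy()].std(axis=0).sum() > 0

    def test_too_many_predictors_rejected(self):
        target = series(["never", "former", None, "never", "former"])
        x = np.random.default_rng(7).normal(0, 1, (5, 6))
        with pytest.raises(ValueError, match="smaller bins"):
            impute_categorical(target, x, m=2, seed=8)


class TestImputePmm:
    def test_imputed_values_are_observed_donors(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 60)
        y = 2 * x + rng.normal(0, 0.1, 60)
        target = series(list(y))
        target.iloc[::7] = np.nan
        observed_set = set(target.dropna())
        out = impute_pmm(target, x[:, None], m=8, seed=10)
        for filled in out.completed:
            assert set(filled[target.isna()]) <= observed_set

    def test_nearest_donor_enumeration(self):
        # y = 2x exactly; the missing case at x = 3 predicts 6, and the
        # two nearest observed values are 5.9 and 6.1
        x = np.array([1.0, 2.0, 2.95, 3.05, 4.0, 5.0, 3.0])
        y = series([2.0, 4.0, 5.9, 6.1, 8.0, 10.0, np.nan])
        out = impute_pmm(y, x[:, None], m=30, donors=2, seed=11)
        vals = {filled.iloc[-1] for filled in out.completed}
        assert vals <= {5.9, 6.1}
        assert len(vals) == 2  # both donors get drawn over 30 imputations

    def test_no_missing_identity(self):
        y = series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        out = impute_pmm(y, np.arange(6.0)[:, None], m=3, seed=12)
        for filled in out.completed:
            pd.testing.assert_series_equal(filled, y)


def build_table(df):
    schema = {}
    for c in df.columns:
        if df[c].dtype == object:
            levels = tuple(sorted(df[c].dropna().unique()))
            if set(levels) <= {"never", "former", "current"}:
                levels = ("never", "former", "current")
            schema[c] = Variable(c, "categorical", levels, levels[0])
        else:
            schema[c] = Variable(c, "continuous")
    return CovariateTable(df, schema)


class TestChainedEquations:
    def _two_var_table(self, n=250, miss=0.15, seed=13):
        rng = np.random.default_rng(seed)
        age = rng.normal(50, 8, n).round()
        z = rng.normal(0, 1, n)
        bw = 3.2 + 0.5 * z + rng.normal(0, 0.3, n)
        smoke = np.where(z > 0.8, "current", np.where(rng.random(n) < 0.5, "never", "former"))
        df = pd.DataFrame(
            {"age": age, "smoking": smoke, "birthweight": bw},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
        df.loc[df.index[rng.random(n) < miss], "smoking"] = np.nan
        df.loc[df.index[rng.random(n) < miss], "birthweight"] = np.nan
        return build_table(df)

    def _specs(self):
        return [
            ImputationModelSpec("smoking", ("age", "birthweight")),
            ImputationModelSpec("birthweight", ("age", "smoking"), method="pmm"),
        ]

    def test_zero_missing_gives_identical_copies(self):
        table = self._two_var_table(miss=0.0)
        out = run_chained_equations(table, self._specs(), m=3, n_cycles=2, seed=14)
        for df in out.completed:
            pd.testing.assert_frame_equal(df, table.data)

    def test_missing_spec_rejected(self):
        table = self._two_var_table()
        with pytest.raises(ValueError, match="no imputation spec"):
            run_chained_equations(
                table, [ImputationModelSpec("smoking", ("age",))], m=2, seed=15
            )

    def test_observed_immutable_and_complete(self):
        table = self._two_var_table()
        mask = table.missing_mask
        out = run_chained_equations(table, self._specs(), m=4, n_cycles=3, seed=16)
        for df in out.completed:
            assert not df.isna().any().any()
            for c in table.data.columns:
                obs = ~mask[c]
                assert (df.loc[obs, c] == table.data.loc[obs, c]).all()

    def test_determinism(self):
        table = self._two_var_table()
        a = run_chained_equations(table, self._specs(), m=3, n_cycles=2, seed=17)
        b = run_chained_equations(table, self._specs(), m=3, n_cycles=2, seed=17)
        for x, y in zip(a.completed, b.completed):
            pd.testing.assert_frame_equal(x, y)

    def test_single_variable_reduces_to_direct_imputation(self):
        # with one incomplete variable the chained run should match the
        # single-variable op in distribution (chi-square over 200 runs)
        rng = np.random.default_rng(18)
        n = 120
        x = rng.normal(0, 1, n)
        smoke = np.where(x > 0.5, "former", "never").astype(object)
        miss = rng.random(n) < 0.25
        smoke_obs = smoke.copy()
        smoke_obs[miss] = None
        df = pd.DataFrame(
            {"age": x * 8 + 50, "smoking": list(smoke_obs)},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
        table = build_table(df)
        target = table.data["smoking"]

        direct = impute_categorical(target, df[["age"]].to_numpy(), m=200, seed=19)
        chained = run_chained_equations(
            table,
            [ImputationModelSpec("smoking", ("age",))],
            m=200,
            n_cycles=2,
            seed=20,
        )
        d_former = np.array(
            [(f[miss] == "former").sum() for f in direct.completed]
        ).sum()
        c_former = np.array(
            [(c.loc[miss, "smoking"] == "former").sum() for c in chained.completed]
        ).sum()
        total = 200 * miss.sum()
        tbl = np.array([[d_former, total - d_former], [c_former, total - c_former]])
        _, p, *_ = stats.chi2_contingency(tbl)
        assert p > 0.001

    def test_correlated_pair_parameter_recovery(self):
        # MCAR missingness in two correlated variables: the pooled slope
        # between them should recover the generating value
        slopes = []
        for rep in range(30):
            rng = np.random.default_rng(300 + rep)
            n = 300
            x = rng.normal(0, 1, n)
            w = 1.0 + 0.8 * x + rng.normal(0, 0.5, n)
            df = pd.DataFrame(
                {"x": x, "w": w},
                index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            )
            df.loc[df.index[rng.random(n) < 0.1], "x"] = np.nan
            df.loc[df.index[rng.random(n) < 0.1], "w"] = np.nan
            table = build_table(df)
            specs = [
                ImputationModelSpec("x", ("w",), method="normal"),
                ImputationModelSpec("w", ("x",), method="normal"),
            ]
            out = run_chained_equations(table, specs, m=5, n_cycles=5, seed=rep)
            rep_slopes = []
            for c in out.completed:
                X = np.column_stack([np.ones(n), c["x"]])
                rep_slopes.append(np.linalg.lstsq(X, c["w"], rcond=None)[0][1])
            slopes.append(np.mean(rep_slopes))
        slopes = np.array(slopes)
        mc_se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 0.8) < 2 * mc_se
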