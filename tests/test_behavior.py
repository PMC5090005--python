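"""Inverse efficiency, feature selection, regression, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import effconn as ec


class TestInverseEfficiency:
    def test_basic_ratio(self):
        trials = pd.DataFrame(
            {"rt_ms": [500.0] * 8 + [400.0] * 2, "correct": [1] * 8 + [0] * 2}
        )
        rec = ec.inverse_efficiency(trials)
        assert rec.accuracy == pytest.approx(0.8)
        assert rec.ie == pytest.approx(625.0)

    def test_perfect_accuracy_ie_is_mean_rt(self):
        trials = pd.DataFrame({"rt_ms": [300.0, 500.0], "correct": [1, 1]})
        assert ec.inverse_efficiency(trials).ie == pytest.approx(400.0)

    def test_29_of_30_example(self):
        rt = np.full(30, 505.63)
        correct = np.ones(30, int)
        correct[0] = 0
        rec = ec.inverse_efficiency(pd.DataFrame({"rt_ms": rt, "correct": correct}))
        assert rec.ie == pytest.approx(505.63 / (29 / 30), abs=0.01)
        assert rec.ie == pytest.approx(523.07, abs=0.01)

    def test_no_correct_trials_fails(self):
        with pytest.raises(ValueError, match="no correct trials"):
            ec.inverse_efficiency(pd.DataFrame({"rt_ms": [1.0], "correct": [0]}))


class TestSelectFeatures:
    def test_strong_planted_effect_has_high_power(self, rng):
        """Population |r|=0.8 at n=24 is detected with power >= 0.95."""
        hits = 0
        reps = 300
        for k in range(reps):
            r = np.random.default_rng(k)
            x = r.standard_normal(24)
            y = 0.8 * x + np.sqrt(1 - 0.64) * r.standard_normal(24)
            sel = ec.select_features(x[:, None], y, alpha=0.05)
            hits += int(sel["selected"].iloc[0])
        assert hits / reps >= 0.95

    def test_shuffled_ie_selects_at_alpha(self, rng):
        m = rng.standard_normal((24, 50))
        rates = []
        for k in range(500):
            y = np.random.default_rng(k).permutation(rng.standard_normal(24))
            rates.append(ec.select_features(m, y).loc[:, "selected"].mean())
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - 0.05) < 3 * se + 1e-12

    def test_duplicated_column_identical_stats(self, rng):
        x = rng.standard_normal((20, 2))
        x[:, 1] = x[:, 0]
        y = rng.standard_normal(20)
        sel = ec.select_features(x, y)
        assert sel["r"].iloc[0] == sel["r"].iloc[1]
        assert sel["p"].iloc[0] == sel["p"].iloc[1]

    def test_agrees_with_scipy_pearsonr(self, rng):
        x = rng.standard_normal((18, 5))
        y = rng.standard_normal(18)
        sel = ec.select_features(x, y)
        for j in range(5):
            r, p = stats.pearsonr(x[:, j], y)
            assert sel["r"].iloc[j] == pytest.approx(r, abs=1e-12)
            assert sel["p"].iloc[j] == pytest.approx(p, abs=1e-12)

    def test_selection_flags_agree_with_critical_r(self, rng):
        n = 24
        crit = ec.critical_r(n, 0.05)
        x = rng.standard_normal((n, 200))
        y = rng.standard_normal(n)
        sel = ec.select_features(x, y, alpha=0.05)
        for _, row in sel.iterrows():
            assert row["selected"] == (abs(row["r"]) >= crit - 1e-9)


class TestCriticalR:
    @pytest.mark.parametrize("n,expected", [(24, 0.4044), (16, 0.4973)])
    def test_known_thresholds(self, n, expected):
        assert ec.critical_r(n, 0.05) == pytest.approx(expected, abs=1e-4)

    def test_alpha_one_gives_zero(self):
        assert ec.critical_r(24, 1.0) == 0.0


class TestFitRegression:
    def test_exact_linear_relation_r2_one(self, rng):
        x = rng.standard_normal((20, 3))
        y = x @ [1.0, -2.0, 0.5] + 3.0
        m = ec.fit_regression(x, y)
        assert m.r2 == pytest.approx(1.0, abs=1e-10)

    def test_f_r2_df_identity_holds(self, rng):
        for _ in range(20):
            x = rng.standard_normal((24, 5))
            y = rng.standard_normal(24)
            m = ec.fit_regression(x, y)
            assert m.r2 == pytest.approx(
                m.df1 * m.F / (m.df1 * m.F + m.df2), abs=1e-12
            )
            assert (m.df1, m.df2) == (5, 18)

    def test_null_expected_r2_is_df1_over_nm1(self, rng):
        """E[R^2] = k/(n-1) when y is independent of X."""
        n, k, reps = 24, 5, 400
        r2s = [
            ec.fit_regression(
                np.random.default_rng(i).standard_normal((n, k)),
                np.random.default_rng(10_000 + i).standard_normal(n),
            ).r2
            for i in range(reps)
        ]
        expected = k / (n - 1)
        assert np.mean(r2s) == pytest.approx(expected, abs=0.02)

    def test_standardized_coefficients_match_zscored_fit(self, rng):
        x = rng.standard_normal((30, 3)) * [1.0, 10.0, 0.1]
        y = x @ [0.5, 0.05, 5.0] + rng.standard_normal(30)
        m = ec.fit_regression(x, y)
        xz = (x - x.mean(0)) / x.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        mz = ec.fit_regression(xz, yz)
        np.testing.assert_allclose(m.coef_standardized, mz.coef_raw, atol=1e-10)
        assert m.F == pytest.approx(mz.F)

    def test_collinear_column_dropped_with_warning(self, rng):
        x = rng.standard_normal((20, 2))
        x = np.column_stack([x, x[:, 0]])
        y = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="collinear"):
            m = ec.fit_regression(x, y)
        assert m.dropped_collinear == [2]
        assert m.df1 == 2

    def test_saturated_design_rejected(self, rng):
        with pytest.raises(ValueError, match="residual df"):
            ec.fit_regression(rng.standard_normal((5, 5)), rng.standard_normal(5))

    def test_near_saturated_flagged(self, rng):
        with pytest.warns(UserWarning, match="saturated"):
            m = ec.fit_regression(rng.standard_normal((24, 12)), rng.standard_normal(24))
        assert m.near_saturated


class TestFToR2:
    @pytest.mark.parametrize(
        "f,df1,df2,pct",
        [
            (6.52, 12, 11, 88),
            (6.85, 14, 9, 91),
            (13.85, 3, 20, 68),
            (6.40, 4, 19, 57),
            (4.17, 6, 17, 60),
            (4.04, 3, 20, 38),
        ],
    )
    def test_known_model_summaries(self, f, df1, df2, pct):
        assert round(100 * ec.f_to_r2(f, df1, df2)) == pct

    def test_zero_f_gives_zero(self):
        assert ec.f_to_r2(0.0, 3, 20) == 0.0


class TestFdrAdjust:
    def test_stepup_rejects_all_when_largest_p_passes(self):
        reject, adj = ec.fdr_adjust([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_flat_half_rejects_none(self):
        reject, _ = ec.fdr_adjust([0.5, 0.5, 0.5], q=0.05)
        assert not reject.any()

    def test_single_small_p_rejected(self):
        reject, adj = ec.fdr_adjust([0.04], q=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.04)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ec.fdr_adjust([])


class TestSubnetworkModels:
    def _setup(self, rng, planted_net="default"):
        atlas = ec.make_atlas(30, {"default": 10, "frontal": 10, "occipital": 10}, seed=0)
        m = rng.standard_normal((24, 30))
        y = m[:, 2] - m[:, 5] + 0.4 * rng.standard_normal(24)
        sel = ec.select_features(m, y, alpha=0.05)
        return atlas, m, y, sel

    def test_planted_module_attains_highest_r2(self, rng):
        atlas, m, y, sel = self._setup(rng)
        models = ec.subnetwork_models(sel, atlas, m, y)
        assert "default" in models
        best = max(models, key=lambda k: models[k].r2)
        assert best == "default"

    def test_single_node_subnetwork_is_simple_regression(self, rng):
        atlas = ec.make_atlas(2, {"a": 1, "b": 1}, seed=0)
        m = rng.standard_normal((24, 2))
        y = 2 * m[:, 0] + 0.1 * rng.standard_normal(24)
        sel = ec.select_features(m, y, alpha=0.05)
        models = ec.subnetwork_models(sel, atlas, m, y)
        assert models["a"].df1 == 1

    def test_module_r2_bounded_by_full_model(self, rng):
        atlas, m, y, sel = self._setup(rng)
        chosen = sel.loc[sel["selected"], "node_id"].astype(int).tolist()
        full = ec.fit_regression(m[:, chosen], y, predictors=chosen)
        for model in ec.subnetwork_models(sel, atlas, m, y).values():
            assert model.r2 <= full.r2 + 1e-10

    def test_empty_selection_rejected(self, rng):
        atlas, m, y, sel = self._setup(rng)
        sel["selected"] = False
        with pytest.raises(ValueError, match="no selected"):
            ec.subnetwork_models(sel, atlas, m, y)
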