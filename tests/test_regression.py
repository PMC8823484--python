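import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import difkit as dk
from difkit.exceptions import DesignError, SeparationError
from difkit.regression import DIFConfig, LogisticFit, results_frame
from oracles import grid_logistic

# fixed 8-row dataset for oracle comparison
X8 = np.column_stack([np.ones(8), np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0])])
Y8 = np.array([0, 0, 1, 0, 1, 0, 1, 1.0])


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        fit = dk.fit_logistic(np.array([0.0, 1.0]), np.ones((2, 1)))
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-9)
        assert fit.loglik == pytest.approx(2 * np.log(0.5))

    def test_matches_grid_search_oracle(self):
        fit = dk.fit_logistic(Y8, X8)
        coef_star, ll_star = grid_logistic(X8, Y8)
        assert np.max(np.abs(fit.coef - coef_star)) < 1e-3
        assert fit.loglik == pytest.approx(ll_star, abs=1e-3)
        assert fit.grad_norm < 1e-8

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(300), rng.normal(size=300), rng.integers(0, 2, 300)])
        eta = X @ np.array([-0.3, 0.8, 0.5])
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = dk.fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(ours.coef, ref.params, atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_label_flip_negates_coefficients(self):
        fit = dk.fit_logistic(Y8, X8)
        flipped = dk.fit_logistic(1 - Y8, X8)
        assert np.allclose(fit.coef, -flipped.coef, atol=1e-7)
        assert fit.loglik == pytest.approx(flipped.loglik)

    def test_constant_response_rejected(self):
        with pytest.raises(DesignError):
            dk.fit_logistic(np.ones(5), np.ones((5, 1)))

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(DesignError):
            dk.fit_logistic(np.array([0, 1, 0, 1, 0, 1.0]), X)

    def test_separation_raises_with_column(self):
        x = np.linspace(-2, 2, 20)
        y = (x > 0).astype(float)  # perfectly separated
        with pytest.raises(SeparationError) as exc:
            dk.fit_logistic(y, np.column_stack([np.ones(20), x]))
        assert exc.value.column == 1


class TestEffectSizes:
    @staticmethod
    def _fit(coef, ll):
        return LogisticFit(np.asarray(coef, float), ll, 0.0, 1)

    def test_identical_slope_gives_zero_dbeta1(self):
        m0 = self._fit([0.1, 1.2], -100.0)
        m1 = self._fit([0.0, 1.2, 0.3], -99.0)
        m2 = self._fit([0.0, 1.2, 0.3, 0.1], -98.5)
        dbeta1, _, _ = dk.effect_sizes(m0, m1, m2)
        assert dbeta1 == 0.0

    def test_equal_likelihoods_give_zero_pseudo_r2(self):
        m0 = self._fit([0.1, 1.2], -100.0)
        m1 = self._fit([0.1, 1.1, 0.3], -100.0)
        m2 = self._fit([0.1, 1.1, 0.3, 0.0], -100.0)
        _, dR1, dR2 = dk.effect_sizes(m0, m1, m2)
        assert dR1 == 0.0 and dR2 == 0.0

    def test_hand_computed_values_reproduced_exactly(self):
        m0 = self._fit([0.0, 2.0], -200.0)
        m1 = self._fit([0.0, 1.5, 0.4], -180.0)
        m2 = self._fit([0.0, 1.5, 0.4, 0.2], -171.0)
        dbeta1, dR1, dR2 = dk.effect_sizes(m0, m1, m2)
        assert dbeta1 == abs((2.0 - 1.5) / 2.0) == 0.25
        assert dR1 == 1 - (-180.0) / (-200.0) == pytest.approx(0.1)
        assert dR2 == 1 - (-171.0) / (-180.0) == pytest.approx(0.05)

    def test_zero_baseline_slope_yields_unavailable(self):
        m0 = self._fit([0.1, 0.0], -50.0)
        m1 = self._fit([0.1, 0.0, 0.2], -49.0)
        m2 = self._fit([0.1, 0.0, 0.2, 0.0], -49.0)
        with pytest.warns(UserWarning):
            dbeta1, _, _ = dk.effect_sizes(m0, m1, m2)
        assert dbeta1 is None

    @pytest.mark.parametrize(
        "dbeta1,dR1,dR2,expect",
        [
            (0.0099, 0.069, 0.069, (False, False, False)),
            (0.0101, 0.071, 0.071, (True, True, True)),
        ],
    )
    def test_threshold_boundary_classification(self, dbeta1, dR1, dR2, expect):
        config = DIFConfig()
        assert (dbeta1 > config.threshold_dbeta1) is expect[0]
        assert (dR1 > config.threshold_dR1) is expect[1]
        assert (dR2 > config.threshold_dR2) is expect[2]


def _toy_dif_data(seed=0, n=400, shift=0.0):
    rng = np.random.default_rng(seed)
    theta = rng.normal(size=n)
    group = np.repeat(["ref", "foc"], n // 2)
    b = np.where(group == "foc", shift, 0.0)
    p = 1 / (1 + np.exp(-(1.2 * theta - b)))
    y = (rng.random(n) < p).astype(float)
    return y, theta, dk.GroupFactor.from_labels(group, levels=("ref", "foc"))


class TestDIFTestItem:
    def test_row_duplication_doubles_chi_square(self):
        y, theta, g = _toy_dif_data(2, n=200, shift=0.8)
        r1 = dk.dif_test_item(y, theta, g)
        y2 = np.concatenate([y, y])
        theta2 = np.concatenate([theta, theta])
        g2 = dk.GroupFactor(g.levels, np.concatenate([g.codes, g.codes]))
        r2 = dk.dif_test_item(y2, theta2, g2)
        assert r2.chi2_uniform == pytest.approx(2 * r1.chi2_uniform, rel=1e-8)
        assert r2.chi2_nonuniform == pytest.approx(2 * r1.chi2_nonuniform, rel=1e-8)

    def test_toy_chi_square_matches_grid_oracle(self):
        rng = np.random.default_rng(9)
        theta = np.array([-1.5, -1, -0.5, 0, 0.5, 1, 1.5, 2, -0.8, 0.3, 1.1, -0.2])
        g = dk.GroupFactor.from_labels(["a"] * 6 + ["b"] * 6)
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1, 0, 1, 1, 0.0])
        res = dk.dif_test_item(y, theta, g)
        X0 = np.column_stack([np.ones(12), theta])
        X1 = np.column_stack([X0, g.dummies()])
        _, ll0 = grid_logistic(X0, y)
        _, ll1 = grid_logistic(X1, y)
        assert res.chi2_uniform == pytest.approx(2 * (ll1 - ll0), abs=1e-2)

    def test_nesting_of_log_likelihoods(self):
        y, theta, g = _toy_dif_data(5, n=300, shift=0.5)
        res = dk.dif_test_item(y, theta, g)
        assert res.fits["m0"].loglik <= res.fits["m1"].loglik <= res.fits["m2"].loglik
        assert res.chi2_uniform >= 0 and res.chi2_nonuniform >= 0
        assert 0 <= res.p_uniform <= 1 and 0 <= res.p_nonuniform <= 1

    def test_reference_level_invariance(self):
        y, theta, g = _toy_dif_data(7, n=400, shift=0.6)
        fwd = dk.dif_test_item(y, theta, g)
        g_rev = dk.GroupFactor.from_labels(
            np.asarray(g.levels, dtype=object)[g.codes], levels=(g.levels[1], g.levels[0])
        )
        rev = dk.dif_test_item(y, theta, g_rev)
        assert fwd.chi2_uniform == pytest.approx(rev.chi2_uniform, abs=1e-6)
        assert fwd.p_uniform == pytest.approx(rev.p_uniform, abs=1e-8)
        assert fwd.dR1 == pytest.approx(rev.dR1, abs=1e-9)
        assert fwd.dR2 == pytest.approx(rev.dR2, abs=1e-9)
        assert fwd.dbeta1 == pytest.approx(rev.dbeta1, abs=1e-7)

    def test_three_level_group_block_df(self):
        rng = np.random.default_rng(12)
        n = 600
        theta = rng.normal(size=n)
        g = dk.GroupFactor.from_labels(rng.choice(["poor", "mid", "rich"], n))
        p = 1 / (1 + np.exp(-1.1 * theta))
        y = (rng.random(n) < p).astype(float)
        res = dk.dif_test_item(y, theta, g)
        assert res.df_uniform == 2 and res.df_nonuniform == 2

    def test_separation_falls_back_to_penalized(self):
        theta = np.linspace(-2, 2, 40)
        y = (theta > 0).astype(float)
        g = dk.GroupFactor.from_labels(np.tile(["a", "b"], 20))
        res = dk.dif_test_item(y, theta, g)
        assert res.status == "ok" and res.penalized

    def test_null_p_values_are_uniform(self):
        # items independent of group given theta: p-values ~ U(0,1)
        pvals = []
        for seed in range(60):
            y, theta, g = _toy_dif_data(seed + 100, n=300, shift=0.0)
            res = dk.dif_test_item(y, theta, g)
            pvals.extend([res.p_uniform, res.p_nonuniform])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


class TestScanAndGroupFactor:
    def test_two_item_scan_returns_two_results(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=200)
        p = 1 / (1 + np.exp(-theta))
        Y = (rng.random((200, 2)) < p[:, None]).astype(float)
        g = dk.GroupFactor.from_labels(np.tile(["a", "b"], 100))
        results = dk.dif_scan(Y, theta, g)
        assert len(results) == 2
        table = results_frame(results)
        assert list(table.index) == [1, 2]

    def test_group_factor_invariants(self):
        with pytest.raises(ValueError):
            dk.GroupFactor.from_labels(["a", "a", "a"])  # single level
        with pytest.raises(ValueError):
            dk.GroupFactor(("a", "b"), np.array([0, 0, 0]))  # empty level
        g = dk.GroupFactor.from_labels(["x", "y", "x", "z"], levels=("x", "y", "z"))
        D = g.dummies()
        assert D.shape == (4, 2)
        assert np.array_equal(D.sum(axis=0), [1, 1])

    def test_scanner_estimator(self, small_cohort):
        rm, cov, truth, _ = small_cohort
        scanner = dk.DIFScanner().fit(rm.values, cov["group"].to_numpy(), theta=truth.theta)
        assert len(scanner.results_) == 15
        assert set(scanner.flagged_items_) <= set(range(1, 16))
        assert scanner.get_params()["alpha"] == 0.01


@given(st.floats(0.001, 0.5), st.floats(0.0, 0.2))
def test_flags_are_pure_threshold_functions(alpha, value):
    config = DIFConfig(alpha=alpha)
    assert (value > config.threshold_dR1) == (value > 0.07)
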