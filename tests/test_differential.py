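import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cistrans.differential import da_binomial_lr, de_cluster, de_hurdle
from cistrans.glmm import _GroupData, _marginal_loglik, fit_linear_mixed

from conftest import simulate_gene


class TestHurdle:
    def test_detection_filter_skips_rare_gene(self):
        counts = np.zeros(400)
        counts[:10] = 5  # 2.5% detection, below the 10% rule
        diag = np.repeat([1, 0], 200)
        donors = np.repeat(np.arange(8), 50)
        res, fit = de_hurdle(counts, diag, donors)
        assert res is None and fit is None

    def test_all_zero_group_skipped(self):
        counts = np.concatenate([np.random.default_rng(0).poisson(2, 200), np.zeros(200)])
        diag = np.repeat([1, 0], 200)
        donors = np.repeat(np.arange(8), 50)
        res, _ = de_hurdle(counts, diag, donors)
        assert res is None

    def test_label_swap_flips_sign(self):
        counts, diag, donors = simulate_gene(0, 0.5)
        r1, _ = de_hurdle(counts, diag, donors)
        r2, _ = de_hurdle(counts, 1 - diag, donors)
        assert r1.log2fc == pytest.approx(-r2.log2fc, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-3)

    def test_planted_effect_detected(self):
        counts, diag, donors = simulate_gene(42, 0.5)
        res, fit = de_hurdle(counts, diag, donors)
        assert res.log2fc > 0 and res.p < 0.05
        assert fit.sigma_discrete >= 0 and np.isfinite(fit.loglik)

    def test_lrt_statistic_nonnegative(self):
        for s in range(5):
            counts, diag, donors = simulate_gene(s, 0.0)
            res, _ = de_hurdle(counts, diag, donors)
            assert 0 <= res.p <= 1


class TestQuadratureConsistency:
    def test_vanishing_variance_recovers_plain_logistic(self):
        # at sigma -> 0 the GH marginal likelihood equals the ordinary
        # logistic likelihood at the same coefficients
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(300), rng.normal(size=300)])
        beta = np.array([0.3, -0.7])
        y = (rng.random(300) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
        groups = np.repeat(np.arange(10), 30)
        data = _GroupData(X, y, groups)
        nodes, weights = np.polynomial.hermite.hermgauss(9)
        ll_gh = _marginal_loglik(np.concatenate([beta, [np.log(1e-8)]]), data, nodes, weights)
        eta = X @ beta
        ll_plain = float(np.sum(y * eta - np.logaddexp(0, eta)))
        assert ll_gh == pytest.approx(ll_plain, abs=1e-6)

    def test_linear_mixed_boundary_equals_ols(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        y = X @ [1.0, 0.5] + rng.normal(0, 1, 200)  # no group effect
        groups = np.repeat(np.arange(10), 20)
        fit = fit_linear_mixed(X, y, groups)
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        assert fit.loglik >= ols.llf - 1e-8
        assert fit.tau < 0.3

    def test_linear_mixed_recovers_variance(self):
        rng = np.random.default_rng(2)
        groups = np.repeat(np.arange(30), 40)
        u = rng.normal(0, 0.5, 30)
        X = np.ones((1200, 1))
        y = 2.0 + u[groups] + rng.normal(0, 1, 1200)
        fit = fit_linear_mixed(X, y, groups)
        assert fit.tau == pytest.approx(0.5, abs=0.15)
        assert fit.sigma == pytest.approx(1.0, abs=0.1)


class TestBinomialDa:
    def _covariates(self, n, rng):
        return pd.DataFrame({"frags": rng.normal(2000, 300, n), "age": rng.normal(80, 5, n)})

    def test_constant_peak_gives_p_one(self):
        rng = np.random.default_rng(0)
        diag = np.repeat([1, 0], 100)
        res = da_binomial_lr(np.ones(200), diag, self._covariates(200, rng))
        assert res.p == 1.0 and "constant_peak" in res.flags

    def test_detection_filter(self):
        rng = np.random.default_rng(0)
        x = np.zeros(400)
        x[:5] = 1
        assert da_binomial_lr(x, np.repeat([1, 0], 200), self._covariates(400, rng)) is None

    def test_planted_accessibility_shift_detected(self):
        rng = np.random.default_rng(3)
        diag = np.repeat([1, 0], 400)
        lam = np.where(diag == 1, 2.0, 1.0)
        x = rng.poisson(lam)
        res = da_binomial_lr(x, diag, self._covariates(800, rng))
        assert res.log2fc > 0 and res.p < 1e-4

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            diag = np.repeat([1, 0], 150)
            x = rng.poisson(1.5, 300)
            cov = self._covariates(300, rng)
            ps.append(da_binomial_lr(x, diag, cov).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestDeCluster:
    def test_fdr_family_and_columns(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, (6, 400))
        diag = np.repeat([1, 0], 200)
        donors = np.repeat(np.arange(8), 50)
        df = de_cluster(counts, [f"g{i}" for i in range(6)], diag, donors, mixed=False)
        assert (df["fdr"] >= df["p"] - 1e-12).all()
        assert set(["feature", "log2fc", "p", "fdr", "pct_group1", "pct_group2"]) <= set(df.columns)
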