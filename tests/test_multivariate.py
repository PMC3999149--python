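"""Multivariate association tests against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from mvgwas.errors import ConvergenceError, MonomorphicInputError, RankDeficientError
from mvgwas.multivariate import (
    BayesPriors,
    PCHSettings,
    _nig_log_bf,
    bayes_mv_bf,
    bimbam_partition_bf,
    cca_test,
    ordinal_reverse_lrt,
    pch_test,
)
from mvgwas.univariate import uv_linear_test


def _small_data(seed=5, n=30, effect=0.3):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.4, n).astype(float)
    y = effect * g[:, None] * np.array([1.0, 0.5, 0.0]) + rng.standard_normal((n, 3))
    return g, y


class TestCCA:
    def test_single_trait_equals_univariate(self, qtl_dataset):
        g, y = qtl_dataset.genotype, qtl_dataset.traits
        p_cca = cca_test(g, y[:, :1]).measure
        p_uv = uv_linear_test(g, y[:, 0])[0]
        assert p_cca == pytest.approx(p_uv, rel=1e-10)

    def test_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        g, y = _small_data(n=20)
        df = pd.DataFrame(y, columns=["Y1", "Y2", "Y3"])
        df["G"] = g
        tab = MANOVA.from_formula("Y1 + Y2 + Y3 ~ G", data=df).mv_test()
        p_ref = tab.results["G"]["stat"].loc["Wilks' lambda", "Pr > F"]
        assert cca_test(g, y).measure == pytest.approx(p_ref, rel=1e-8)

    def test_affine_invariance(self, qtl_dataset, rng):
        g, y = qtl_dataset.genotype, qtl_dataset.traits
        a_mat = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        shift = rng.standard_normal(3)
        p1 = cca_test(g, y).measure
        p2 = cca_test(g, y @ a_mat.T + shift).measure
        assert p1 == pytest.approx(p2, rel=1e-8)

    def test_orthogonal_traits_give_p_one(self, rng):
        g = rng.binomial(2, 0.4, 50).astype(float)
        y = rng.standard_normal((50, 3))
        gc = g - g.mean()
        y = y - np.outer(gc, gc @ y) / (gc @ gc)  # project genotype out
        res = cca_test(g, y)
        assert res.measure == pytest.approx(1.0)
        assert res.detail["canonical_r"] == pytest.approx(0.0, abs=1e-7)

    def test_degenerate_inputs(self, rng):
        y = rng.standard_normal((30, 3))
        with pytest.raises(MonomorphicInputError):
            cca_test(np.ones(30), y)
        g = rng.binomial(2, 0.4, 30)
        y[:, 2] = y[:, 0]  # rank-deficient
        with pytest.raises(RankDeficientError):
            cca_test(g, y)


class TestBayesMV:
    def test_zero_prior_scale_identity(self, qtl_dataset):
        g, y = qtl_dataset.genotype, qtl_dataset.traits
        res = bayes_mv_bf(g, y, BayesPriors(b_prior_scale=0.0))
        assert res.measure == 0.0

    def test_k1_matches_quadrature_oracle(self):
        # independent oracle: numerically integrate the conjugate model
        # (beta, sigma^2) for one trait on the centered data (m = n - 1).
        g, y3 = _small_data(seed=5, n=30)
        y = y3[:, 0]
        gc, yc = g - g.mean(), y - y.mean()
        vb, nu, s_scale = 0.02, 4.0, 6.0
        m = len(g) - 1

        def loglik(b, s2):
            r = yc - gc * b
            return -0.5 * m * np.log(2 * np.pi * s2) - (r @ r) / (2 * s2)

        def f_alt(b, s2):
            return np.exp(
                loglik(b, s2)
                + stats.invgamma.logpdf(s2, nu / 2, scale=s_scale / 2)
                + stats.norm.logpdf(b, 0, np.sqrt(vb * s2))
                + 40
            )

        def f_null(s2):
            return np.exp(
                loglik(0.0, s2)
                + stats.invgamma.logpdf(s2, nu / 2, scale=s_scale / 2)
                + 40
            )

        alt, _ = integrate.dblquad(
            f_alt, 0.01, 20, lambda s: -3, lambda s: 3, epsrel=1e-10
        )
        null, _ = integrate.quad(f_null, 0.01, 20, epsrel=1e-10)
        oracle = np.log10(alt / null)
        mine = bayes_mv_bf(g, y[:, None], BayesPriors()).measure
        assert mine == pytest.approx(oracle, abs=1e-6)

    def test_monotone_in_effect_size(self):
        rng = np.random.default_rng(9)
        n = 500
        g = rng.binomial(2, 0.4, n).astype(float)
        e = rng.standard_normal((n, 3))
        bfs = []
        for a in (0.0, 0.1, 0.2, 0.4):
            y = a * g[:, None] + e
            bfs.append(bayes_mv_bf(g, y).measure)
        assert np.all(np.diff(bfs) > 0)

    def test_trait_order_invariance(self, qtl_dataset, rng):
        g, y = qtl_dataset.genotype, qtl_dataset.traits
        perm = rng.permutation(3)
        assert bayes_mv_bf(g, y[:, perm]).measure == pytest.approx(
            bayes_mv_bf(g, y).measure, rel=1e-10
        )


class TestOrdinalReverse:
    def test_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        g, y = _small_data(seed=7, n=300)
        res = ordinal_reverse_lrt(g, y)
        codes = pd.Series(g).astype("category").cat.codes
        sm_fit = OrderedModel(codes, y, distr="logit").fit(method="bfgs", disp=False)
        counts = np.bincount(codes)
        ll0 = np.sum(counts * np.log(counts / len(g)))
        p_ref = stats.chi2.sf(2 * (sm_fit.llf - ll0), 3)
        assert res.measure == pytest.approx(p_ref, abs=1e-6)
        np.testing.assert_allclose(res.detail["betas"], sm_fit.params[:3], atol=1e-4)

    def test_two_category_reduces_to_logistic(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 400
        g = rng.binomial(1, 0.3, n).astype(float)  # only 0/1 observed
        y = 0.3 * g[:, None] + rng.standard_normal((n, 3))
        res = ordinal_reverse_lrt(g, y)
        fit = sm.Logit(g, sm.add_constant(y)).fit(disp=False)
        p_ref = stats.chi2.sf(2 * (fit.llf - fit.llnull), 3)
        assert res.measure == pytest.approx(p_ref, abs=1e-6)

    def test_null_calibration(self):
        rng = np.random.default_rng(13)
        n = 500
        ps = []
        for _ in range(1500):
            g = rng.binomial(2, 0.4, n).astype(float)
            y = rng.standard_normal((n, 3))
            ps.append(ordinal_reverse_lrt(g, y).measure)
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_constant_trait_dropped_with_reduced_df(self):
        g, y = _small_data(seed=15, n=200)
        y = np.column_stack([y, np.ones(len(g))])
        with pytest.warns(UserWarning):
            res = ordinal_reverse_lrt(g, y)
        assert res.detail["df"] == 3

    def test_rare_category_collapsed(self):
        rng = np.random.default_rng(17)
        n = 600
        g = rng.binomial(2, 0.03, n).astype(float)  # MAF 3%: homozygotes rare
        assert np.count_nonzero(g == 2) < 5
        y = rng.standard_normal((n, 3))
        res = ordinal_reverse_lrt(g, y)
        assert res.detail["n_categories"] == 2

    def test_exhausted_iterations_raise_convergence_error(self):
        g, y = _small_data(seed=19, n=300, effect=0.5)
        with pytest.raises(ConvergenceError) as exc:
            ordinal_reverse_lrt(g, y, max_iter=1)
        assert exc.value.n_iter == 1 and exc.value.grad_norm > 0


class TestBimbam:
    def test_k1_reduces_to_grid_averaged_univariate_bf(self):
        g, y3 = _small_data(seed=21, n=100)
        y = y3[:, :1]
        priors = BayesPriors()
        ones = np.ones((len(g), 1))
        per = [
            np.exp(_nig_log_bf(y[:, 0], g, ones, s)) for s in priors.bimbam_sigma_a
        ]
        expected = np.log10(np.mean(per))
        assert bimbam_partition_bf(g, y, priors).measure == pytest.approx(
            expected, abs=1e-10
        )

    def test_nig_bf_matches_quadrature_oracle(self):
        g, y3 = _small_data(seed=5, n=30)
        y = y3[:, 0]
        sa, n = 0.15, len(g)
        mine = _nig_log_bf(y, g, np.ones((n, 1)), sa) / np.log(10)

        def ll(a, b, s2):
            r = y - a - g * b
            return -0.5 * n * np.log(2 * np.pi * s2) - (r @ r) / (2 * s2)

        def f_alt(a, b, ls2):
            s2 = np.exp(ls2)  # Jeffreys 1/s2 times jacobian s2
            return np.exp(ll(a, b, s2) + stats.norm.logpdf(b, 0, np.sqrt(sa**2 * s2)) + 30)

        def f_null(a, ls2):
            s2 = np.exp(ls2)
            return np.exp(ll(a, 0.0, s2) + 30)

        alt, _ = integrate.tplquad(
            f_alt, -4, 4, -2, 2, -2, 2, epsrel=1e-8
        )
        null, _ = integrate.dblquad(f_null, -4, 4, -2, 2, epsrel=1e-8)
        assert mine == pytest.approx(np.log10(alt / null), abs=1e-5)

    def test_partition_enumeration_and_average_bound(self, qtl_dataset):
        g, y = qtl_dataset.genotype, qtl_dataset.traits
        res = bimbam_partition_bf(g, y)
        post = res.detail["partition_posteriors"]
        assert len(post) == 3**3 - 2**3  # 19 partitions with >= 1 D trait
        assert all("D" in part for part in post)
        assert sum(post.values()) == pytest.approx(1.0)
        # overall BF is the average of partition BFs, so the largest partition
        # BF is at most (number of partitions) times the overall BF
        best_log_bf = res.measure + np.log10(len(post) * max(post.values()))
        assert best_log_bf <= res.measure + np.log10(len(post)) + 1e-9

    def test_null_median_log_bf_nonpositive(self):
        rng = np.random.default_rng(23)
        n = 300
        bfs = []
        for _ in range(300):
            g = rng.binomial(2, 0.4, n).astype(float)
            y = rng.standard_normal((n, 3))
            bfs.append(bimbam_partition_bf(g, y).measure)
        assert np.median(bfs) <= 0

    def test_marginal_posteriors_sum_to_one(self, qtl_dataset):
        res = bimbam_partition_bf(qtl_dataset.genotype, qtl_dataset.traits)
        np.testing.assert_allclose(res.detail["marginal_udi"].sum(axis=1), 1.0)
        # trait 1 carries the simulated effect: mostly "directly affected"
        assert res.detail["marginal_udi"][0, 1] > 0.5


_TINY_PCH = PCHSettings(
    n_train=100, n_splits=12, n_bags=8, n_null=50, n_splits_null=6
)


class TestPCH:
    def test_detects_strong_signal(self, qtl_dataset):
        rng = np.random.default_rng(29)
        res = pch_test(qtl_dataset.genotype, qtl_dataset.traits, _TINY_PCH, rng)
        assert res.measure < 0.01
        assert res.detail["weights"].shape == (3,)

    def test_exchangeable_traits_give_balanced_weights(self):
        # equal per-trait effects with independent residuals: Sigma_e ~ I and
        # a_hat ~ a*1, so the heritability-optimal direction is the equal-
        # weight combination
        rng = np.random.default_rng(31)
        n = 600
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.25 * g[:, None] + rng.standard_normal((n, 3))
        res = pch_test(g, y, _TINY_PCH, rng)
        w = res.detail["weights"]
        assert np.all(w > 0) and w.max() / w.min() < 2
        assert res.measure < 0.01  # strong combined signal detected

    def test_null_p_not_degenerate(self, null_dataset):
        rng = np.random.default_rng(37)
        ps = [
            pch_test(null_dataset.genotype, null_dataset.traits, _TINY_PCH, rng).measure
            for _ in range(10)
        ]
        assert 0.001 < np.median(ps) <= 1.0
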