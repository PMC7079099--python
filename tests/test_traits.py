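"""BM/OU trait simulation moments; lambda and K estimators vs oracles."""

import numpy as np
import pytest

from phylofidelity import (
    KEstimator,
    LambdaEstimator,
    estimate_k,
    estimate_lambda,
    phylo_covariance,
    read_newick,
    rescale_to_root_age,
    reshuffle_trait,
    simulate_bm,
    simulate_coalescent_tree,
    simulate_ou,
    simulate_traits_many,
)


@pytest.fixture(scope="module")
def chrono100():
    return rescale_to_root_age(simulate_coalescent_tree(100, 31), 1.0)


class TestSimulation:
    def test_star_bm_variance(self):
        star = read_newick("(" + ",".join(f"t{i}:4" for i in range(20)) + ");")
        X = simulate_traits_many(star, 0.5, 4000, seed=1)
        v = X.to_numpy().var(axis=0, ddof=0).mean()  # E = sigma2 * T = 2.0
        se = X.to_numpy().var(axis=1).std(ddof=1) / np.sqrt(4000)
        assert abs(v - 2.0) < 3 * max(se, 0.05)

    def test_bm_tip_covariance_matches_shared_time(self, chrono100):
        X = simulate_traits_many(chrono100, 1.0, 4000, seed=2).to_numpy()
        C = phylo_covariance(chrono100).values
        rng = np.random.default_rng(0)
        for _ in range(5):
            i, j = rng.integers(0, 100, size=2)
            emp = np.cov(X[i], X[j])[0, 1]
            prod_sd = np.sqrt(C[i, i] * C[j, j])
            assert abs(emp - C[i, j]) < 3 * prod_sd / np.sqrt(4000) * 2.5

    def test_sigma2_scaling_is_exact_on_matched_seeds(self, chrono100):
        a = simulate_traits_many(chrono100, 0.2, 5, seed=3).to_numpy()
        b = simulate_traits_many(chrono100, 0.8, 5, seed=3).to_numpy()
        assert np.allclose(b, 2.0 * a)

    def test_ou_alpha_zero_is_exactly_bm(self, chrono100):
        bm = simulate_bm(chrono100, 0.2, seed=7)
        ou = simulate_ou(chrono100, 0.2, 0.0, seed=7)
        assert np.allclose(bm.values, ou.values)

    def test_ou_stationary_variance(self):
        # alpha * T >> 1: tips ~ iid Normal(0, sigma2 / (2 alpha))
        star = read_newick("(" + ",".join(f"t{i}:50" for i in range(25)) + ");")
        X = simulate_traits_many(star, 1.0, 3000, seed=4, alpha=1.0).to_numpy()
        v = X.var(ddof=0)
        assert abs(v - 0.5) < 3 * 0.5 * np.sqrt(2 / X.size)

    def test_negative_parameters_rejected(self, chrono100):
        with pytest.raises(ValueError):
            simulate_traits_many(chrono100, -1.0, 1)
        with pytest.raises(ValueError):
            simulate_traits_many(chrono100, 1.0, 1, alpha=-0.1)

    def test_determinism(self, chrono100):
        a = simulate_traits_many(chrono100, 0.2, 3, seed=5, alpha=0.5)
        b = simulate_traits_many(chrono100, 0.2, 3, seed=5, alpha=0.5)
        assert np.allclose(a, b)


class TestLambda:
    def test_loglik_matches_direct_mvn_density(self):
        from scipy.stats import multivariate_normal

        t5 = read_newick("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")
        est = LambdaEstimator(t5)
        x = np.array([0.3, -1.2, 0.7, 2.0])
        C = phylo_covariance(t5).values
        for lam in (0.0, 0.5, 1.0):
            S = C * lam
            np.fill_diagonal(S, np.diag(C))
            Si = np.linalg.inv(S)
            one = np.ones(4)
            mu = (one @ Si @ x) / (one @ Si @ one)
            s2 = (x - mu) @ Si @ (x - mu) / 4
            direct = multivariate_normal.logpdf(x, mean=mu * one, cov=s2 * S)
            assert est._loglik(lam, x) == pytest.approx(direct, abs=1e-8)

    def test_bm_traits_recover_lambda_one(self, chrono100):
        est = LambdaEstimator(chrono100)
        X = simulate_traits_many(chrono100, 0.2, 100, seed=6)
        lams = est.estimate_many(X)["lambda"]
        se = lams.std(ddof=1) / np.sqrt(len(lams))
        assert abs(lams.mean() - 1.0) < max(3 * se, 0.02)

    def test_iid_noise_gives_lambda_zero(self, chrono100):
        est = LambdaEstimator(chrono100)
        rng = np.random.default_rng(8)
        lams = [
            est.estimate(rng.standard_normal(100)).estimate for _ in range(40)
        ]
        assert np.mean(lams) < 0.05

    def test_optimum_beats_grid(self, chrono100):
        est = LambdaEstimator(chrono100)
        x = simulate_traits_many(chrono100, 0.2, 1, seed=9).to_numpy()[:, 0]
        res = est.estimate(x)
        for lam in (0.0, 0.5, 1.0):
            assert res.loglik >= est._loglik(lam, x) - 1e-6

    def test_lambda_above_one_is_allowed(self, chrono100):
        est = LambdaEstimator(chrono100)
        assert est.lam_max > 1.0

    def test_affine_invariance(self, chrono100):
        est = LambdaEstimator(chrono100)
        x = simulate_traits_many(chrono100, 0.2, 1, seed=10).to_numpy()[:, 0]
        a = est.estimate(x)
        b = est.estimate(3.5 * x - 2.0)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-6)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-6)

    def test_constant_trait_rejected(self, chrono100):
        with pytest.raises(ValueError):
            LambdaEstimator(chrono100).estimate(np.ones(100))


class TestK:
    def test_matches_brute_force_formula(self):
        tree = read_newick("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")
        x = np.array([0.3, -1.2, 0.7, 2.0])
        C = phylo_covariance(tree).values
        Ci = np.linalg.inv(C)
        one = np.ones(4)
        a_hat = (one @ Ci @ x) / (one @ Ci @ one)
        mse0 = (x - a_hat) @ (x - a_hat) / 3
        mse = (x - a_hat) @ Ci @ (x - a_hat) / 3
        expected = (np.trace(C) - 4 / (one @ Ci @ one)) / 3
        brute = (mse0 / mse) / expected
        assert estimate_k(
            _tv(x, tree), tree, n_perm=0
        ).estimate == pytest.approx(brute, abs=1e-10)

    def test_bm_traits_recover_k_one(self, chrono100):
        est = KEstimator(chrono100)
        ks = est.estimate_many(simulate_traits_many(chrono100, 0.2, 300, seed=11))
        se = ks.std(ddof=1) / np.sqrt(len(ks))
        assert abs(ks.mean() - 1.0) < 3 * se

    def test_k_positive_and_right_skewed_under_bm(self, chrono100):
        est = KEstimator(chrono100)
        ks = est.estimate_many(simulate_traits_many(chrono100, 0.2, 300, seed=12))
        assert (ks > 0).all()
        skew = ((ks - ks.mean()) ** 3).mean() / ks.std(ddof=0) ** 3
        assert skew > 0
        assert ks.median() < ks.mean()

    def test_affine_invariance(self, chrono100):
        est = KEstimator(chrono100)
        x = simulate_traits_many(chrono100, 0.2, 1, seed=13).to_numpy()[:, 0]
        a = est.estimate(x, n_perm=99, seed=1)
        b = est.estimate(0.1 * x + 7.0, n_perm=99, seed=1)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-9)
        assert a.p_value == pytest.approx(b.p_value)


class TestOUSignalDecay:
    def test_signal_decreases_with_selection_strength(self):
        """Strong selection erases phylogenetic signal: mean lambda and K
        decrease as alpha grows (root age 10, so alpha=1 is strong)."""
        tree = rescale_to_root_age(simulate_coalescent_tree(80, 41), 10.0)
        lam_est, k_est = LambdaEstimator(tree), KEstimator(tree)
        lam_means, k_means = [], []
        for alpha in (0.0, 1.0, 5.0, 20.0):
            X = simulate_traits_many(tree, 0.2, 60, seed=14, alpha=alpha)
            lam_means.append(lam_est.estimate_many(X)["lambda"].mean())
            k_means.append(k_est.estimate_many(X).mean())
        assert lam_means == sorted(lam_means, reverse=True)
        assert k_means == sorted(k_means, reverse=True)
        # K reacts to mean reversion much faster than lambda: lambda stays
        # high as long as close relatives remain correlated
        assert k_means[1] < 0.5
        assert lam_means[3] < 0.1 and k_means[3] < 0.1


class TestReshuffle:
    def test_multiset_preserved_and_deterministic(self, chrono100):
        tv = simulate_bm(chrono100, 0.2, seed=15)
        a = reshuffle_trait(tv, seed=3)
        b = reshuffle_trait(tv, seed=3)
        assert a.shuffled
        assert sorted(a.values) == sorted(tv.values)
        assert np.allclose(a.values, b.values)

    def test_k_permutation_type1_error_calibrated(self):
        """The K permutation test is exact under exchangeability, so the
        rejection rate on shuffled traits sits in the binomial band at 0.05."""
        tree = rescale_to_root_age(simulate_coalescent_tree(40, 51), 1.0)
        est = KEstimator(tree)
        rng = np.random.default_rng(16)
        n_tests = 400
        base = simulate_traits_many(tree, 0.2, n_tests, seed=17).to_numpy()
        rejections = 0
        for j in range(n_tests):
            x = rng.permutation(base[:, j])
            p = est.estimate(x, n_perm=99, seed=int(rng.integers(2**31))).p_value
            rejections += p < 0.05
        rate = rejections / n_tests
        se = np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(rate - 0.05) < 3 * se

    def test_lambda_lrt_type1_error_controlled(self):
        """The plain chi-square df-1 LRT is conservative at the lambda = 0
        boundary, so the false-positive rate must not exceed the nominal
        level (it typically sits near half of it)."""
        tree = rescale_to_root_age(simulate_coalescent_tree(40, 52), 1.0)
        est = LambdaEstimator(tree)
        rng = np.random.default_rng(18)
        base = simulate_traits_many(tree, 0.2, 300, seed=19).to_numpy()
        ps = [est.estimate(rng.permutation(base[:, j])).p_value for j in range(300)]
        rate = np.mean(np.asarray(ps) < 0.05)
        se = np.sqrt(0.05 * 0.95 / 300)
        assert rate < 0.05 + 3 * se


def _tv(x, tree):
    import pandas as pd

    from phylofidelity import TraitVector

    return TraitVector(pd.Series(x, index=tree.tip_labels))


def test_estimate_lambda_entry_point(chrono100):
    tv = simulate_bm(chrono100, 0.2, seed=20)
    est = estimate_lambda(tv, chrono100)
    assert est.statistic == "lambda"
    assert 0 <= est.p_value <= 1
    assert est.loglik is not None
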