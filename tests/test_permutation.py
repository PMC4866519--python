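import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cisqtl import (
    SimConfig,
    adaptive_adjusted_p,
    beta_adjusted_p,
    direct_adjusted_p,
    fit_beta_mle,
    full_permutation_pass,
    permute_and_scan,
    simulate_genotypes,
    simulate_phenotypes,
)
from cisqtl.permutation import BetaFit, beta_loglik, phenotype_rng


class TestDirectScheme:
    @pytest.mark.parametrize(
        "r,R,expected", [(0, 999, 1e-3), (999, 999, 1.0), (49, 999, 0.05)]
    )
    def test_empirical_formula(self, r, R, expected):
        assert direct_adjusted_p(r, R) == pytest.approx(expected, rel=1e-12)

    def test_lower_bound_is_one_over_R_plus_one(self):
        assert direct_adjusted_p(0, 10) == 1 / 11

    def test_zero_permutations_error(self):
        with pytest.raises(ValueError):
            direct_adjusted_p(0, 0)

    @settings(deadline=None)
    @given(st.integers(1, 500).flatmap(lambda R: st.tuples(st.just(R), st.integers(0, R))))
    def test_bounds_property(self, R_r):
        R, r = R_r
        p = direct_adjusted_p(r, R)
        assert 1 / (R + 1) <= p <= 1.0


class TestPermuteAndScan:
    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        G = rng.standard_normal((8, 40))
        y = rng.standard_normal(40)
        a = permute_and_scan(y, G, 50, 123, nominal_p=0.01)
        b = permute_and_scan(y, G, 50, 123, nominal_p=0.01)
        np.testing.assert_array_equal(a.null_pvalues, b.null_pvalues)
        assert a.r_exceed == b.r_exceed

    def test_single_variant_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        G = rng.standard_normal((1, 60))
        y = rng.standard_normal(60)
        null = permute_and_scan(y, G, 800, 5)
        assert stats.kstest(null.null_pvalues, "uniform").pvalue > 0.01

    def test_strong_signal_no_exceedances(self):
        cfg = SimConfig(n_samples=150, n_variants=10, n_phenotypes=1,
                        effects={0: (5, 2.0)}, noise_sd=0.1, seed=4)
        g = simulate_genotypes(cfg)
        p = simulate_phenotypes(g, cfg)
        from cisqtl import correlation_scan, correlation_to_pvalue
        r, best = correlation_scan(p.values[0], g.dosages)
        p_n = correlation_to_pvalue(float(r[best]), 148)
        null = permute_and_scan(p.values[0], g.dosages, 100, 6, nominal_p=p_n)
        assert null.r_exceed == 0

    def test_null_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(7)
        null = permute_and_scan(
            rng.standard_normal(30), rng.standard_normal((5, 30)), 100, 8
        )
        assert np.all(null.null_pvalues > 0) and np.all(null.null_pvalues <= 1)


class TestAdaptiveScheme:
    def test_single_permutation_enumeration(self):
        rng = np.random.default_rng(9)
        G = rng.standard_normal((3, 20))
        y = rng.standard_normal(20)
        p_adj, null = adaptive_adjusted_p(y, G, nominal_p=0.5, B=1, M=1, seed_or_rng=1)
        assert null.R == 1
        assert p_adj in (0.5, 1.0)

    def test_insignificant_hit_stops_early(self):
        rng = np.random.default_rng(10)
        G = rng.standard_normal((5, 40))
        y = rng.standard_normal(40)
        p_adj, null = adaptive_adjusted_p(
            y, G, nominal_p=1.0, B=20, M=10000, batch=50, seed_or_rng=2
        )
        assert null.R <= 100  # every null p <= 1, so B is hit within one batch
        assert p_adj > 0.2

    def test_agrees_with_direct_within_binomial_ci(self):
        rng = np.random.default_rng(11)
        G = rng.standard_normal((6, 80))
        y = rng.standard_normal(80)
        from cisqtl import correlation_scan, correlation_to_pvalue
        r, best = correlation_scan(y, G)
        p_n = correlation_to_pvalue(float(r[best]), 78)
        direct_null = permute_and_scan(y, G, 1000, 12, nominal_p=p_n)
        p_direct = direct_adjusted_p(direct_null.r_exceed, 1000)
        p_adapt, _ = adaptive_adjusted_p(y, G, p_n, B=10, M=1000, seed_or_rng=13)
        # the adaptive estimate stops at the B-th exceedance, so its spread
        # around the (direct) truth follows the negative binomial stopping
        # time: build a 99% envelope from its quantiles
        B = 10
        extra_lo, extra_hi = stats.nbinom.interval(0.99, B, p_direct)
        r_hi, r_lo = B + extra_hi, B + extra_lo  # total permutations at stop
        lo = (B + 1) / (min(r_hi, 1000) + 1)
        hi = min((B + 1) / (r_lo + 1), 1.0)
        assert lo <= p_adapt <= hi

    def test_invalid_b_m(self):
        with pytest.raises(ValueError):
            adaptive_adjusted_p(np.ones(5), np.ones((1, 5)), 0.5, B=5, M=2)


class TestBetaFit:
    def test_recovers_beta_1_500(self):
        rng = np.random.default_rng(14)
        sample = rng.beta(1.0, 500.0, size=1000)
        fit = fit_beta_mle(sample)
        assert fit.converged
        assert 0.85 <= fit.k_hat <= 1.15
        assert 420 <= fit.n_hat <= 580

    def test_k_near_one_for_minimum_of_uniforms(self):
        rng = np.random.default_rng(15)
        minima = rng.random((1000, 100)).min(axis=1)
        fit = fit_beta_mle(minima)
        assert abs(fit.k_hat - 1.0) < 0.15
        assert 70 <= fit.n_hat <= 140

    def test_optimizer_never_degrades_start(self):
        rng = np.random.default_rng(16)
        sample = rng.beta(0.8, 30.0, size=500)
        fit = fit_beta_mle(sample)
        from cisqtl.permutation import _mom_start
        k0, n0 = _mom_start(np.clip(sample, 1e-300, 1 - 1e-16))
        assert fit.loglik >= beta_loglik(k0, n0, sample) - 1e-9

    def test_matches_scipy_constrained_fit(self):
        rng = np.random.default_rng(17)
        sample = rng.beta(1.3, 80.0, size=2000)
        fit = fit_beta_mle(sample)
        k_ref, n_ref, _, _ = stats.beta.fit(sample, floc=0, fscale=1)
        assert fit.k_hat == pytest.approx(k_ref, rel=1e-3)
        assert fit.n_hat == pytest.approx(n_ref, rel=1e-3)

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            fit_beta_mle(np.full(5, 0.3))


class TestBetaAdjustedP:
    FIT = BetaFit(k_hat=1.0, n_hat=50.0, loglik=0.0, converged=True)

    def test_cdf_endpoints(self):
        assert beta_adjusted_p(0.0, self.FIT) == 0.0
        assert beta_adjusted_p(1.0, self.FIT) == 1.0

    def test_closed_form_independent_tests(self):
        # k = 1, n = L: P(U <= p) = 1 - (1 - p)^L
        for p_n in (1e-6, 1e-3, 0.01, 0.2, 0.9):
            expect = 1.0 - (1.0 - p_n) ** 50
            assert beta_adjusted_p(p_n, self.FIT) == pytest.approx(expect, rel=1e-12)

    def test_worked_example(self):
        assert beta_adjusted_p(0.01, self.FIT) == pytest.approx(0.39499393286246365, rel=1e-12)

    def test_strictly_increasing_in_nominal_p(self):
        fit = BetaFit(k_hat=0.9, n_hat=200.0, loglik=0.0, converged=True)
        xs = np.logspace(-12, -0.01, 60)
        ps = np.array([beta_adjusted_p(x, fit) for x in xs])
        assert np.all(np.diff(ps) >= 0)
        # strict below the point where the CDF saturates at double precision
        body = ps < 1 - 1e-9
        assert np.all(np.diff(ps[body]) > 0)

    def test_no_underflow_far_below_direct_floor(self):
        fit = BetaFit(k_hat=1.05, n_hat=800.0, loglik=0.0, converged=True)
        p = beta_adjusted_p(1e-200, fit)
        assert p > 0.0
        assert p < 1e-150

    def test_unconverged_fit_rejected(self):
        bad = BetaFit(k_hat=1.0, n_hat=10.0, loglik=0.0, converged=False)
        with pytest.raises(ValueError):
            beta_adjusted_p(0.5, bad)


class TestFullPass:
    def test_planted_eqtl_gets_lowest_adjusted_p(self):
        cfg = SimConfig(n_samples=150, n_variants=30, n_phenotypes=12,
                        maf_range=(0.2, 0.5), effects={3: (15, 1.0)}, seed=18)
        g = simulate_genotypes(cfg)
        p = simulate_phenotypes(g, cfg)
        res = full_permutation_pass(p, g, 1_000_000, scheme="beta", R=200, seed=19)
        best = min(res, key=lambda r: r.beta_p)
        assert best.phenotype_id == "pheno4"
        assert best.beta_p < 1e-4

    def test_beta_vs_direct_concordance(self):
        rho = []
        for seed in range(10):
            cfg = SimConfig(
                n_samples=120, n_variants=20, n_phenotypes=5,
                effects={0: (10, 0.5)}, seed=100 + seed,
            )
            g = simulate_genotypes(cfg)
            p = simulate_phenotypes(g, cfg)
            res = full_permutation_pass(p, g, 1_000_000, scheme="beta", R=300, seed=seed)
            rho.extend((r.perm_p, r.beta_p) for r in res)
        d, b = zip(*rho)
        assert stats.spearmanr(d, b).statistic > 0.95

    def test_effective_tests_shrink_under_ld(self):
        def median_nhat(rho, seed):
            cfg = SimConfig(n_samples=200, n_variants=40, n_phenotypes=10,
                            ld_rho=rho, seed=seed)
            g = simulate_genotypes(cfg)
            p = simulate_phenotypes(g, cfg)
            res = full_permutation_pass(p, g, 1_000_000, scheme="beta", R=300, seed=seed)
            return np.median([r.n_hat for r in res]), res[0].n_tested

        n_ld, L = median_nhat(0.9, 23)
        n_free, _ = median_nhat(0.0, 24)
        assert n_ld < L  # LD shrinks the effective number of tests
        assert n_free > 0.6 * L  # independent variants keep n near L
        assert n_ld < n_free

    def test_chunk_independent_rng_substreams(self):
        cfg = SimConfig(n_samples=80, n_variants=10, n_phenotypes=6, seed=25)
        g = simulate_genotypes(cfg)
        p = simulate_phenotypes(g, cfg)
        whole = full_permutation_pass(p, g, 1_000_000, scheme="beta", R=100, seed=3)
        half = full_permutation_pass(p.subset([3, 4, 5]), g, 1_000_000,
                                     scheme="beta", R=100, seed=3)
        by_id = {r.phenotype_id: r for r in whole}
        for r in half:
            assert r.perm_p == by_id[r.phenotype_id].perm_p
            assert r.beta_p == by_id[r.phenotype_id].beta_p

    def test_goodness_of_fit_on_held_out_nulls(self):
        # Beta fit on one permutation sample should describe a fresh sample:
        # per-phenotype KS rejections at the Bonferroni level stay at the
        # by-chance rate.
        n_pheno, rejections = 15, 0
        for seed in range(n_pheno):
            cfg = SimConfig(n_samples=100, n_variants=25, n_phenotypes=1,
                            ld_rho=0.5, seed=300 + seed)
            g = simulate_genotypes(cfg)
            p = simulate_phenotypes(g, cfg)
            y = p.values[0]
            fit_null = permute_and_scan(y, g.dosages, 400, 2 * seed)
            held_out = permute_and_scan(y, g.dosages, 400, 2 * seed + 1)
            fit = fit_beta_mle(fit_null.null_pvalues)
            ks = stats.kstest(held_out.null_pvalues, "beta", args=(fit.k_hat, fit.n_hat))
            if ks.pvalue < 0.01 / n_pheno:
                rejections += 1
        assert rejections <= 1


def test_phenotype_rng_is_stable_and_distinct():
    a = phenotype_rng(5, "geneA").random(3)
    b = phenotype_rng(5, "geneA").random(3)
    c = phenotype_rng(5, "geneB").random(3)
    np.testing.assert_array_equal(a, b)
    assert not np.allclose(a, c)
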