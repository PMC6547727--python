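"""Mixture-likelihood evaluators: moment identities, normalization, censoring."""

import numpy as np
import pytest
from scipy import stats

import polymix as pm
from polymix.likelihood import (
    SnpContext,
    censored_loglik,
    conv_pdf_biv,
    conv_pdf_uni,
    fast_pdf_biv,
    fast_pdf_uni,
    fast_tail_uni,
    full_pdf,
    full_pdf_uni,
    make_context,
    weighted_loglik,
)
from polymix.params import BivariateParams, UnivariateParams

ZGRID = np.linspace(-38.0, 38.0, 4001)


def _single_ctx(ell=1.0, m4_ratio=0.3, n1=1e4, n2=1e4):
    return SnpContext(ell=[ell], m4_ratio=[m4_ratio], n1=[n1], n2=[n2])


class TestFastUnivariate:
    def test_pi_one_reduces_to_single_gaussian(self):
        """At pi=1 eta reduces to ell and the density is one Gaussian."""
        ctx = _single_ctx(ell=2.0, m4_ratio=0.4)
        p = UnivariateParams(1.0, 1e-4, 1.2)
        var = 1e4 * 2.0 * 1e-4 + 1.2
        z = np.array([0.0, 1.5, -4.0])
        got = fast_pdf_uni(z, p, SnpContext(ell=[2.0] * 3, m4_ratio=[0.4] * 3, n1=[1e4] * 3))
        np.testing.assert_allclose(got, stats.norm.pdf(z, scale=np.sqrt(var)), rtol=1e-12)

    def test_null_model_is_residual_gaussian(self):
        ctx = _single_ctx()
        p = UnivariateParams(0.01, 0.0, 1.3)
        z = np.array([0.7])
        got = fast_pdf_uni(z, p, ctx)
        assert got[0] == pytest.approx(stats.norm.pdf(0.7, scale=np.sqrt(1.3)), rel=1e-10)

    def test_second_moment_identity(self):
        """E[z^2] = n*ell*pi*sigma^2 + sigma0^2 for any parameter setting."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            pi = 10 ** rng.uniform(-4, 0)
            s2 = 10 ** rng.uniform(-6, -4)  # keep component sd within the grid
            s0 = rng.uniform(0.5, 2.0)
            ell = rng.uniform(0.2, 4.0)
            m4r = rng.uniform(0.05, min(ell, 0.5))
            n = 10 ** rng.uniform(3, 4.5)
            ctx = _single_ctx(ell, m4r, n)
            p = UnivariateParams(pi, s2, s0)
            dens = fast_pdf_uni(ZGRID[:, None], p, ctx)[:, 0]
            ez2 = np.trapezoid(ZGRID**2 * dens, ZGRID)
            assert ez2 == pytest.approx(n * ell * pi * s2 + s0, rel=1e-6)

    def test_normalizes_to_one(self):
        ctx = _single_ctx(ell=3.0, m4_ratio=0.2, n1=1e5)
        p = UnivariateParams(3e-3, 1e-4, 1.1)
        dens = fast_pdf_uni(ZGRID[:, None], p, ctx)[:, 0]
        assert np.trapezoid(dens, ZGRID) == pytest.approx(1.0, abs=1e-6)

    def test_moments_match_simulation_oracle(self, toy_panel):
        """Fast-model 2nd/4th moments vs Monte-Carlo z from the convolution model."""
        panel, ld = toy_panel
        scores = pm.ld_scores(ld, panel)
        ctx = make_context(ld, panel, scores, n1=1e4)
        p = UnivariateParams(0.05, 5e-3, 1.0)
        n_mc = 1_000_000
        rng = np.random.default_rng(42)
        j = 5  # a SNP inside the first block
        idx, r = ld.neighbors(j)
        h = np.concatenate([[panel.het[j]], panel.het[idx]])
        rr = np.concatenate([[1.0], r])
        causal = rng.random((n_mc, len(h))) < p.pi1
        beta = causal * rng.normal(0, np.sqrt(p.sigma_beta2), size=(n_mc, len(h)))
        delta = np.sqrt(1e4) * (beta * np.sqrt(h) * rr).sum(axis=1)
        z_mc = delta + rng.standard_normal(n_mc)
        dens = fast_pdf_uni(ZGRID[:, None], p, ctx.subset([j]))[:, 0]
        for k in (2, 4):
            model_mom = np.trapezoid(ZGRID**k * dens, ZGRID)
            mc = z_mc**k
            assert model_mom == pytest.approx(
                mc.mean(), abs=3.0 * mc.std() / np.sqrt(n_mc)
            )

    def test_kurtosis_increases_with_m4_ratio(self):
        """The r^4 shape term controls the heavy tails at fixed ell."""
        p = UnivariateParams(1e-3, 1e-3, 1.0)
        kurts = []
        for m4r in (0.05, 0.15, 0.3, 0.45):
            ctx = _single_ctx(ell=2.0, m4_ratio=m4r, n1=1e4)
            dens = fast_pdf_uni(ZGRID[:, None], p, ctx)[:, 0]
            m2 = np.trapezoid(ZGRID**2 * dens, ZGRID)
            m4 = np.trapezoid(ZGRID**4 * dens, ZGRID)
            kurts.append(m4 / m2**2)
        assert np.all(np.diff(kurts) > 0)


class TestFastBivariate:
    def test_factorizes_when_second_trait_null(self):
        ctx = _single_ctx(ell=1.5, m4_ratio=0.3)
        p = BivariateParams(5e-3, 0.0, 0.0, 1e-3, 0.0, 0.0, 1.1, 0.9, 0.0)
        z1, z2 = np.array([1.2]), np.array([-0.4])
        got = fast_pdf_biv(z1, z2, p, ctx)
        uni = fast_pdf_uni(z1, UnivariateParams(5e-3, 1e-3, 1.1), ctx)
        marg2 = stats.norm.pdf(z2, scale=np.sqrt(0.9))
        assert got[0] == pytest.approx(uni[0] * marg2[0], rel=1e-9)

    def test_cross_moment_formula(self):
        """E[z1 z2] = sqrt(n1 n2) ell pi12 rho12 s1 s2 + rho0 s01 s02 (analytic)."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = BivariateParams(
                pi1=10 ** rng.uniform(-4, -1), pi2=10 ** rng.uniform(-4, -1),
                pi12=10 ** rng.uniform(-4, -1),
                sigma1_2=10 ** rng.uniform(-5, -3), sigma2_2=10 ** rng.uniform(-5, -3),
                rho12=rng.uniform(-0.9, 0.9),
                sigma01_2=rng.uniform(0.8, 1.5), sigma02_2=rng.uniform(0.8, 1.5),
                rho0=rng.uniform(-0.5, 0.5),
            )
            ell, m4r = rng.uniform(0.5, 4.0), rng.uniform(0.05, 0.4)
            n1, n2 = 10 ** rng.uniform(3, 5), 10 ** rng.uniform(3, 5)
            ctx = _single_ctx(ell, m4r, n1, n2)
            # analytic cross moment by summation over the 8 components
            from polymix.likelihood import _biv_components

            w, v1, v2, c12 = _biv_components(p, ctx)
            res_c = p.rho0 * np.sqrt(p.sigma01_2 * p.sigma02_2)
            total = 0.0
            for b1 in (0, 1):
                for b2 in (0, 1):
                    for b12 in (0, 1):
                        wt = 1.0
                        for on, wc in zip((b1, b2, b12), w):
                            wt *= wc[0] if on else 1 - wc[0]
                        total += wt * (res_c + b12 * c12[2][0])
            expected = (
                np.sqrt(n1 * n2) * ell * p.pi12 * p.rho12
                * np.sqrt(p.sigma1_2 * p.sigma2_2) + res_c
            )
            assert total == pytest.approx(expected, abs=1e-8)

    def test_sign_symmetry_without_correlations(self):
        ctx = _single_ctx()
        p = BivariateParams(1e-3, 1e-3, 1e-3, 1e-3, 1e-3, 0.0, 1.0, 1.0, 0.0)
        z = np.array([1.3])
        a = fast_pdf_biv(z, np.array([2.0]), p, ctx)
        b = fast_pdf_biv(z, np.array([-2.0]), p, ctx)
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_pi12_one_reproduces_infinitesimal_covariance(self):
        """pi12 = 1 collapses the mixture to the LDSC-compatible Gaussian."""
        ctx = _single_ctx(ell=2.5, m4_ratio=0.3, n1=2e4, n2=3e4)
        p = BivariateParams(0.0, 0.0, 1.0, 2e-4, 3e-4, 0.6, 1.1, 1.2, 0.2)
        # infinitesimal covariance: ell * n-scaled effect covariance + residual
        v1 = 2.5 * 2e4 * 2e-4 + 1.1
        v2 = 2.5 * 3e4 * 3e-4 + 1.2
        c = 2.5 * np.sqrt(2e4 * 3e4) * 0.6 * np.sqrt(2e-4 * 3e-4) + 0.2 * np.sqrt(1.1 * 1.2)
        cov = np.array([[v1, c], [c, v2]])
        z1, z2 = np.array([1.0, -2.0]), np.array([0.5, 3.0])
        got = fast_pdf_biv(
            z1, z2, p,
            SnpContext(ell=[2.5] * 2, m4_ratio=[0.3] * 2, n1=[2e4] * 2, n2=[3e4] * 2),
        )
        expected = stats.multivariate_normal(cov=cov).pdf(np.column_stack([z1, z2]))
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_bivariate_grid_normalization(self):
        ctx = _single_ctx(ell=1.0, m4_ratio=0.2, n1=1e3, n2=1e3)
        p = BivariateParams(1e-2, 1e-2, 1e-2, 1e-3, 1e-3, 0.5, 1.0, 1.0, 0.1)
        g = np.linspace(-38, 38, 501)
        gx, gy = np.meshgrid(g, g)
        ctxg = SnpContext(ell=np.full(gx.size, 1.0), m4_ratio=np.full(gx.size, 0.2),
                          n1=np.full(gx.size, 1e3), n2=np.full(gx.size, 1e3))
        dens = fast_pdf_biv(gx.ravel(), gy.ravel(), p, ctxg).reshape(gx.shape)
        total = np.trapezoid(np.trapezoid(dens, g, axis=1), g)
        assert total == pytest.approx(1.0, abs=1e-3)


class TestFullModel:
    def test_all_null_gives_residual_gaussian(self, toy_context):
        p = BivariateParams(0.0, 0.0, 0.0, 1e-3, 1e-3, 0.0, 1.2, 0.8, 0.3)
        z1 = np.zeros(len(toy_context))
        z2 = np.full(len(toy_context), 0.7)
        got = full_pdf(z1, z2, p, toy_context, K=3, seed=0)
        res_c = 0.3 * np.sqrt(1.2 * 0.8)
        cov = np.array([[1.2, res_c], [res_c, 0.8]])
        expected = stats.multivariate_normal(cov=cov).pdf(np.column_stack([z1, z2]))
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_pi12_one_degenerate_mixture(self, toy_context):
        """All replicates identical at pi12=1: infinitesimal-model Gaussian."""
        p = BivariateParams(0.0, 0.0, 1.0, 2e-4, 2e-4, 0.5, 1.0, 1.0, 0.0)
        z1 = np.full(len(toy_context), 1.0)
        z2 = np.full(len(toy_context), -0.5)
        a = full_pdf(z1, z2, p, toy_context, K=1, seed=0)
        b = full_pdf(z1, z2, p, toy_context, K=7, seed=123)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_univariate_matches_mc_simulation(self, toy_panel):
        """Full-model moments vs direct Monte-Carlo of causal-configuration draws."""
        panel, ld = toy_panel
        scores = pm.ld_scores(ld, panel)
        ctx = make_context(ld, panel, scores, n1=1e4)
        p = UnivariateParams(0.08, 2e-3, 1.0)
        sub = ctx.subset([4])
        zg = np.linspace(-30, 30, 1201)
        dens = np.array([full_pdf_uni(np.array([z]), p, sub, K=50_000, seed=3)[0]
                         for z in zg[::10]])
        m2_model = np.trapezoid(zg[::10] ** 2 * dens, zg[::10])
        # MC oracle
        rng = np.random.default_rng(7)
        idx, r = ld.neighbors(4)
        h = np.concatenate([[panel.het[4]], panel.het[idx]])
        rr = np.concatenate([[1.0], r])
        n_mc = 400_000
        causal = rng.random((n_mc, len(h))) < p.pi1
        beta = causal * rng.normal(0, np.sqrt(p.sigma_beta2), (n_mc, len(h)))
        z_mc = np.sqrt(1e4) * (beta * np.sqrt(h) * rr).sum(axis=1) + rng.standard_normal(n_mc)
        assert m2_model == pytest.approx(
            (z_mc**2).mean(), abs=3 * (z_mc**2).std() / np.sqrt(n_mc)
        )

    def test_invalid_k_rejected(self, toy_context):
        with pytest.raises(ValueError):
            full_pdf_uni(np.zeros(len(toy_context)), UnivariateParams(0.1, 1e-3, 1.0),
                         toy_context, K=0)


class TestConvModel:
    """The deterministic sparse-regime evaluation of the full-model density."""

    def test_normalizes_per_snp(self, toy_context):
        p = UnivariateParams(0.02, 1e-2, 1.1)
        dens = np.stack([conv_pdf_uni(np.full(len(toy_context), z), p, toy_context)
                         for z in ZGRID[::4]])
        norms = np.trapezoid(dens, ZGRID[::4], axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)

    def test_agrees_with_mc_full_model(self, toy_context):
        p = UnivariateParams(0.02, 1e-2, 1.0)
        z = np.full(len(toy_context), 1.7)
        mc = full_pdf_uni(z, p, toy_context, K=100_000, seed=5)
        det = conv_pdf_uni(z, p, toy_context)
        np.testing.assert_allclose(det, mc, rtol=0.02)

    def test_bivariate_agrees_with_mc_full_model(self, toy_context):
        p = BivariateParams(0.01, 0.01, 0.02, 0.01, 0.02, 0.6, 1.0, 1.2, 0.3)
        z1 = np.full(len(toy_context), 1.5)
        z2 = np.full(len(toy_context), -1.0)
        mc = full_pdf(z1, z2, p, toy_context, K=100_000, seed=5)
        det = conv_pdf_biv(z1, z2, p, toy_context)
        np.testing.assert_allclose(det, mc, rtol=0.05)


class TestWeightedLoglik:
    def test_zero_weights_give_zero(self, toy_context):
        p = UnivariateParams(0.1, 1e-3, 1.0)
        z = np.zeros(len(toy_context))
        assert weighted_loglik(p, z, toy_context, np.zeros(len(toy_context))) == 0.0

    def test_single_iteration_pruning_equals_subset_sum(self, toy_panel, toy_context):
        panel, ld = toy_panel
        w = pm.random_pruning_weights(ld, T=1, seed=9)
        p = UnivariateParams(0.1, 1e-3, 1.0)
        rng = np.random.default_rng(0)
        z = rng.standard_normal(len(toy_context))
        got = weighted_loglik(p, z, toy_context, w)
        keep = w.w == 1.0
        dens = fast_pdf_uni(z[keep], p, toy_context.subset(np.nonzero(keep)[0]))
        assert got == pytest.approx(np.sum(np.log(dens)), rel=1e-12)

    def test_matches_bruteforce_loop(self, toy_context):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(len(toy_context))
        w = rng.random(len(toy_context))
        p = UnivariateParams(0.05, 1e-3, 1.1)
        got = weighted_loglik(p, z, toy_context, w)
        expected = sum(
            w[j] * np.log(fast_pdf_uni(z[j], p, toy_context.subset([j]))[0])
            for j in range(len(z))
        )
        assert got == pytest.approx(expected, abs=1e-10)


class TestCensoredLoglik:
    def test_infinite_threshold_equals_weighted(self, toy_context):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(len(toy_context)) * 3
        w = np.ones(len(toy_context))
        p = UnivariateParams(0.05, 1e-3, 1.0)
        a = censored_loglik(p, z, toy_context, w, z_t=1e9)
        b = weighted_loglik(p, z, toy_context, w)
        assert a == pytest.approx(b, rel=1e-12)

    def test_all_censored_null_model_gaussian_tail(self, toy_context):
        z = np.full(len(toy_context), 8.0)
        w = np.ones(len(toy_context))
        s0 = 1.3
        p = UnivariateParams(0.5, 0.0, s0)
        got = censored_loglik(p, z, toy_context, w, z_t=5.45)
        expected = len(z) * np.log(2 * stats.norm.sf(5.45 / np.sqrt(s0)))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_mixed_fixture_two_pass_oracle(self, toy_context):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(len(toy_context)) * 4
        w = rng.random(len(toy_context))
        p = UnivariateParams(0.05, 1e-3, 1.0)
        z_t = 3.0
        got = censored_loglik(p, z, toy_context, w, z_t=z_t)
        low = np.abs(z) <= z_t
        part1 = weighted_loglik(p, z[low], toy_context.subset(np.nonzero(low)[0]),
                                w[low])
        hi_idx = np.nonzero(~low)[0]
        tails = fast_tail_uni(z_t, p, toy_context.subset(hi_idx))
        part2 = float(np.sum(w[hi_idx] * np.log(tails)))
        assert got == pytest.approx(part1 + part2, abs=1e-10)
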