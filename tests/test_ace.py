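"""Univariate ACE estimation: transform, likelihood, fits, boundary LRT."""

import statistics

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.stats import chi2, norm

from twingrowth.ace import (
    ACEData,
    ace_loglik,
    fit_ace,
    inverse_normal_transform,
    lrt_boundary,
)
from twingrowth.cohort import simulate_anchor_values


class TestInverseNormalTransform:
    def test_three_value_example(self):
        out = inverse_normal_transform([5.0, 1.0, 9.0])
        # Blom scores for n=3 via an independent quantile implementation
        nd = statistics.NormalDist()
        expected = [nd.inv_cdf((r - 0.375) / 3.25) for r in (2, 1, 3)]
        np.testing.assert_allclose(out, expected, atol=1e-10)
        np.testing.assert_allclose(out, [0.0, -0.8694, 0.8694], atol=1e-3)

    def test_median_maps_to_zero(self):
        out = inverse_normal_transform([3.0, 8.0, 1.0, 9.0, 5.0])
        assert out[np.argsort([3.0, 8.0, 1.0, 9.0, 5.0])[2]] == pytest.approx(0.0, abs=1e-12)

    def test_idempotent(self, rng):
        x = rng.normal(size=100)
        once = inverse_normal_transform(x)
        np.testing.assert_allclose(inverse_normal_transform(once), once, atol=1e-10)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(
            inverse_normal_transform(x), inverse_normal_transform(3.2 * x - 7.0), atol=1e-12
        )

    def test_ties_get_average_rank(self):
        out = inverse_normal_transform([1.0, 2.0, 2.0, 3.0])
        assert out[1] == pytest.approx(out[2])

    def test_errors(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([1.0, 2.0])
        with pytest.raises(ValueError):
            inverse_normal_transform([4.0, 4.0, 4.0])

    def test_nan_passthrough(self):
        out = inverse_normal_transform([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()


def _quadrature_pair_density(y1, y2, mu, sa2, sc2, se2, r):
    """2-D quadrature of the generative twin model: integrate over the shared
    genetic factor and the common-environment draw."""

    def integrand(c, u):
        cond_var = (1 - r) * sa2 + se2
        m1 = mu + np.sqrt(r * sa2) * u + c
        d1 = norm.pdf(y1, m1, np.sqrt(cond_var))
        d2 = norm.pdf(y2, m1, np.sqrt(cond_var))
        return d1 * d2 * norm.pdf(u) * norm.pdf(c, 0, np.sqrt(sc2))

    val, _ = dblquad(integrand, -8, 8, -8 * np.sqrt(sc2), 8 * np.sqrt(sc2),
                     epsabs=1e-12, epsrel=1e-10)
    return val


class TestAceLoglik:
    def test_block_diagonal_reduction(self, rng):
        """With sigmaA2 = sigmaC2 = 0 pairs decompose into independent normals."""
        y = rng.normal(0, 1.3, size=(40, 2))
        zyg = np.array(["MZ"] * 15 + ["DZ"] * 25)
        data = ACEData(y, None, zyg)
        se2 = 1.69
        ll = ace_loglik((0.0, 0.0, se2, np.zeros(1)), data)
        expected = norm.logpdf(y, 0, np.sqrt(se2)).sum()
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_gaussian_scale_equivariance(self, rng):
        y = rng.normal(0, 1, size=(30, 2))
        zyg = np.array(["MZ"] * 10 + ["DZ"] * 20)
        params = (0.5, 0.3, 0.4)
        ll1 = ace_loglik((*params, np.zeros(1)), ACEData(y, None, zyg))
        ll2 = ace_loglik(
            (2 * params[0], 2 * params[1], 2 * params[2], np.zeros(1)),
            ACEData(np.sqrt(2) * y, None, zyg),
        )
        n_obs = y.size
        assert ll2 == pytest.approx(ll1 - n_obs * np.log(np.sqrt(2)), abs=1e-9)

    def test_matches_quadrature_oracle(self, rng):
        """Analytic bivariate density vs numerical integration of the
        generative model, on five random pairs."""
        sa2, sc2, se2, mu = 0.6, 0.3, 0.5, 0.4
        for i in range(5):
            zyg = "MZ" if i % 2 else "DZ"
            r = 1.0 if zyg == "MZ" else 0.5
            y = rng.normal(mu, 1.1, size=(1, 2))
            data = ACEData(y, None, np.array([zyg]))
            ll = ace_loglik((sa2, sc2, se2, np.array([mu])), data)
            dens = _quadrature_pair_density(y[0, 0], y[0, 1], mu, sa2, sc2, se2, r)
            assert ll == pytest.approx(np.log(dens), abs=1e-6)

    def test_invalid_covariance_returns_neg_inf(self):
        y = np.zeros((4, 2))
        y[:, 1] = 1.0
        data = ACEData(y, None, np.array(["MZ", "MZ", "DZ", "DZ"]))
        assert ace_loglik((-1.0, 0.0, 1.0, np.zeros(1)), data) == -np.inf
        assert ace_loglik((0.0, 0.0, 0.0, np.zeros(1)), data) == -np.inf


class TestLrtBoundary:
    def test_zero_statistic_gives_p_one(self):
        assert lrt_boundary(10.0, 10.0) == 1.0

    def test_known_quantile(self):
        # 2.706 is the chi2(1) 0.90 quantile, so p = 0.5 * 0.10
        assert lrt_boundary(10.0 + 2.706 / 2, 10.0) == pytest.approx(0.05, abs=1e-3)

    def test_detects_optimizer_violation(self):
        with pytest.raises(ValueError):
            lrt_boundary(9.0, 10.0)

    def test_halves_chi2_tail(self):
        t = 3.7
        assert lrt_boundary(t / 2, 0.0) == pytest.approx(0.5 * chi2.sf(t, 1))


class TestFitAce:
    def test_parameter_recovery_and_falconer_agreement(self):
        y, zyg = simulate_anchor_values(2000, 2000, 0.6, 0.2, 1234)
        res = fit_ace(y, zyg)
        assert res.h2 == pytest.approx(0.6, abs=0.07)
        assert res.c2 == pytest.approx(0.2, abs=0.07)
        assert res.h2 + res.c2 + res.e2 == pytest.approx(1.0, abs=1e-8)
        mzm = zyg == "MZ"
        rmz = np.corrcoef(y[mzm, 0], y[mzm, 1])[0, 1]
        rdz = np.corrcoef(y[~mzm, 0], y[~mzm, 1])[0, 1]
        assert res.h2 == pytest.approx(2 * (rmz - rdz), abs=0.05)
        assert res.c2 == pytest.approx(2 * rdz - rmz, abs=0.05)

    def test_identical_cotwins_push_everything_into_c(self, rng):
        shared = rng.normal(0, 1, 300)
        y = np.column_stack([shared, shared])
        res = fit_ace(y, np.array(["MZ"] * 100 + ["DZ"] * 200))
        assert res.c2 > 0.95
        assert res.h2 < 0.05

    def test_independent_cotwins_show_no_familial_aggregation(self, rng):
        y = rng.normal(0, 1, size=(2000, 2))
        res = fit_ace(y, np.array(["MZ"] * 1000 + ["DZ"] * 1000))
        assert res.h2 < 0.05 and res.c2 < 0.05

    def test_likelihood_ordering(self):
        y, zyg = simulate_anchor_values(300, 300, 0.4, 0.3, 7)
        res = fit_ace(y, zyg)
        assert res.loglik >= res.loglik_ae - 1e-6
        assert res.loglik >= res.loglik_ce - 1e-6
        assert res.loglik_ce >= res.loglik_e - 1e-6
        assert res.loglik_ae >= res.loglik_e - 1e-6
        assert 0 < res.p_h2 <= 1 and 0 < res.p_c2 <= 1

    def test_permutation_and_cotwin_order_invariance(self):
        y, zyg = simulate_anchor_values(100, 150, 0.5, 0.2, 11)
        res1 = fit_ace(y, zyg)
        perm = np.random.default_rng(0).permutation(len(zyg))
        y2, z2 = y[perm].copy(), zyg[perm].copy()
        y2[::2] = y2[::2, ::-1]  # swap co-twins in half the pairs
        res2 = fit_ace(y2, z2)
        assert res1.h2 == pytest.approx(res2.h2, abs=1e-6)
        assert res1.c2 == pytest.approx(res2.c2, abs=1e-6)
        assert res1.loglik == pytest.approx(res2.loglik, abs=1e-6)

    def test_affine_rescaling_after_transform(self):
        y, zyg = simulate_anchor_values(200, 200, 0.5, 0.2, 3)
        t1 = inverse_normal_transform(y.ravel()).reshape(y.shape)
        t2 = inverse_normal_transform((5.0 * y - 2.0).ravel()).reshape(y.shape)
        r1, r2 = fit_ace(t1, zyg), fit_ace(t2, zyg)
        assert r1.h2 == pytest.approx(r2.h2, abs=1e-10)

    def test_requires_both_zygosities(self):
        y = np.zeros((5, 2))
        with pytest.raises(ValueError):
            fit_ace(y, np.array(["MZ"] * 5))

    def test_incomplete_pairs_contribute(self):
        y, zyg = simulate_anchor_values(500, 500, 0.5, 0.2, 21)
        y_missing = y.copy()
        y_missing[::10, 1] = np.nan
        res = fit_ace(y_missing, zyg)
        assert res.converged
        assert res.h2 == pytest.approx(0.5, abs=0.12)


class TestCovariateVarianceExplained:
    def _sim_with_covariate(self, rng, beta, n=2000):
        x = rng.normal(size=(n, 2))
        y, zyg = simulate_anchor_values(n // 2, n // 2, 0.4, 0.3, rng)
        return y + beta * x, x[..., None], zyg

    def test_single_covariate_fraction(self):
        # beta=0.3 on a unit-variance trait: beta^2/(1+beta^2) ~ 0.083
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            y, x, zyg = self._sim_with_covariate(rng, 0.3)
            fracs.append(fit_ace(y, zyg, x).covariate_var_explained)
        assert np.mean(fracs) == pytest.approx(0.09, abs=0.02)

    def test_null_covariate_fraction_small(self, rng):
        y, x, zyg = self._sim_with_covariate(rng, 0.0)
        res = fit_ace(y, zyg, x)
        assert res.covariate_var_explained < 0.02

    def test_irrelevant_covariate_barely_moves_fraction(self, rng):
        y, x, zyg = self._sim_with_covariate(rng, 0.3)
        res1 = fit_ace(y, zyg, x)
        noise = rng.normal(size=(*y.shape, 1))
        res2 = fit_ace(y, zyg, np.concatenate([x, noise], axis=2))
        assert abs(res2.covariate_var_explained - res1.covariate_var_explained) < 0.01

    def test_no_covariates_gives_zero(self):
        y, zyg = simulate_anchor_values(100, 100, 0.4, 0.3, 5)
        assert fit_ace(y, zyg).covariate_var_explained == 0.0
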