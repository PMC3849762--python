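"""Poisson-Tweedie distribution core: parameterizations, pmf, moments, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from ptseq.pt_core import (
    PMFVector,
    PTCanonicalParams,
    PTDomainError,
    PTMeanParams,
    _extended_pmf,
    pt_cdf,
    pt_mean_variance,
    pt_pgf,
    pt_pmf,
    pt_quantile,
    pt_sample,
    to_canonical,
    to_mean_params,
)

# mean-form grid spanning the family members used throughout the suite
GRID = [
    PTMeanParams(mu, phi, a)
    for a in (-5.0, -1.0, 0.0, 0.5, 0.9)
    for phi in (1.2, 2.0, 5.0, 20.0)
    for mu in (0.5, 5.0, 50.0)
]


def _pmf_of(p: PTMeanParams, m: int) -> np.ndarray:
    if p.is_poisson:
        return stats.poisson.pmf(np.arange(m + 1), p.mu)
    return pt_pmf(m, to_canonical(p)).probs


class TestParameterizations:
    @pytest.mark.parametrize(
        "mu,phi,a,c_expect",
        [(10, 2, 0, 0.5), (5, 3, 0.5, 0.8), (7, 1.5, -1, 0.2)],
    )
    def test_canonical_c(self, mu, phi, a, c_expect):
        assert to_canonical(PTMeanParams(mu, phi, a)).c == pytest.approx(c_expect)

    def test_canonical_b_matches_mean(self):
        # b chosen so that the NB special case has mean b*c/(1-c) = mu
        p = to_canonical(PTMeanParams(10, 2, 0))
        assert p.b == pytest.approx(10.0)
        assert p.b * p.c / (1 - p.c) == pytest.approx(10.0)

    def test_mean_params_from_canonical(self):
        mp = to_mean_params(PTCanonicalParams(a=0, b=10, c=0.5))
        assert mp.mu == pytest.approx(10.0)
        assert mp.phi == pytest.approx(2.0)
        mp2 = to_mean_params(PTCanonicalParams(a=0.5, b=1, c=0.8))
        assert mp2.phi == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(mu=-1, phi=2, a=0), dict(mu=10, phi=0.5, a=0), dict(mu=10, phi=2, a=1.5)],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(PTDomainError):
            PTMeanParams(**kwargs)

    def test_poisson_boundary_rejected_by_canonical_map(self):
        with pytest.raises(PTDomainError):
            to_canonical(PTMeanParams(5, 1.0, 0))
        with pytest.raises(PTDomainError):
            to_mean_params(PTCanonicalParams(a=0.5, b=1.0, c=0.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        mu=st.floats(0.1, 500.0),
        phi=st.floats(1.05, 40.0),
        a=st.floats(-20.0, 0.99),
    )
    def test_round_trip_identity(self, mu, phi, a):
        p = PTMeanParams(mu, phi, a)
        back = to_mean_params(to_canonical(p))
        assert back.mu == pytest.approx(mu, rel=1e-10)
        assert back.phi == pytest.approx(phi, rel=1e-10)
        assert back.a == a


class TestPGF:
    def test_normalization_at_one(self):
        for p in GRID:
            if p.is_poisson:
                continue
            assert pt_pgf(1.0, to_canonical(p)) == pytest.approx(1.0, abs=1e-12)

    def test_nb_value_at_zero_is_p0(self):
        p = PTCanonicalParams(a=0, b=10, c=0.5)
        assert pt_pgf(0.0, p) == pytest.approx(0.5 ** 10, rel=1e-12)

    def test_pgf_equals_pmf_series(self):
        p = PTCanonicalParams(a=0.5, b=2, c=0.6)
        probs = pt_pmf(300, p).probs
        k = np.arange(301)
        for y in (0.0, 0.3, 0.5, 0.7, 1.0):
            assert np.sum(probs * y ** k) == pytest.approx(pt_pgf(y, p), abs=1e-8)

    def test_pgf_pmf_consistency_on_grid(self):
        for p in GRID:
            if p.is_poisson:
                continue
            can = to_canonical(p)
            probs = _extended_pmf(can, target=1.0 - 1e-8)
            k = np.arange(probs.size)
            for y in (0.0, 0.3, 0.7, 1.0):
                assert np.sum(probs * y ** k) == pytest.approx(
                    pt_pgf(y, can), abs=1e-8
                ), f"pgf mismatch at y={y} for {p}"

    def test_domain_check(self):
        with pytest.raises(PTDomainError):
            pt_pgf(1.5, PTCanonicalParams(a=0, b=1, c=0.5))


class TestPMF:
    def test_nb_closed_form_equivalence(self):
        """The a=0 member is exactly negative binomial."""
        for b, c in [(10, 0.5), (2, 0.9), (0.5, 0.3)]:
            p = PTCanonicalParams(a=0, b=b, c=c)
            got = pt_pmf(100, p).probs
            want = stats.nbinom.pmf(np.arange(101), b, 1 - c)
            assert np.abs(got - want).max() < 1e-12

    def test_recursion_agrees_with_nb_closed_form(self):
        from ptseq.pt_core import _pmf_recursion

        q, shift, status = _pmf_recursion(0.0, 10.0, 0.5, 80)
        assert status == 0
        want = stats.nbinom.pmf(np.arange(81), 10, 0.5)
        assert np.abs(q * np.exp(shift) - want).max() < 1e-12

    def test_recursion_agrees_with_poisson_closed_form(self):
        from ptseq.pt_core import _pmf_recursion

        # canonical a=1 is Poisson(b c)
        q, shift, status = _pmf_recursion(1.0, 6.0, 0.5, 40)
        want = stats.poisson.pmf(np.arange(41), 3.0)
        assert np.abs(q * np.exp(shift) - want).max() < 1e-12

    def test_p0_poisson_route(self):
        probs = _pmf_of(PTMeanParams(3.0, 1.0, 0.0), 10)
        assert probs[0] == pytest.approx(np.exp(-3.0), rel=1e-12)

    def test_pig_quadrature_oracle(self):
        """a=1/2 matches a numerically integrated Poisson-inverse-Gaussian mixture."""
        p = PTCanonicalParams(a=0.5, b=1.0, c=0.8)
        mp = to_mean_params(p)
        mu, phi = mp.mu, mp.phi
        # inverse-Gaussian mixing density with matched mean and variance
        lam_shape = mu ** 2 / (phi - 1.0)
        ig = stats.invgauss(mu / lam_shape, scale=lam_shape)
        got = pt_pmf(50, p).probs
        for k in range(51):
            want, _ = quad(lambda lam: stats.poisson.pmf(k, lam) * ig.pdf(lam),
                           0, np.inf, limit=200)
            assert got[k] == pytest.approx(want, abs=1e-6)

    def test_tail_extended_mass_sums_to_one_on_grid(self):
        for p in GRID:
            probs = (
                stats.poisson.pmf(np.arange(200), p.mu)
                if p.is_poisson
                else _extended_pmf(to_canonical(p), target=1.0 - 1e-8)
            )
            assert probs.sum() == pytest.approx(1.0, abs=1e-8), f"mass lost for {p}"

    def test_truncation_mass_bookkeeping(self):
        v = pt_pmf(5, PTCanonicalParams(a=0, b=10, c=0.5))
        assert isinstance(v, PMFVector)
        assert v.truncation_mass >= -1e-10
        assert v.probs.sum() + v.truncation_mass == pytest.approx(1.0)


class TestMoments:
    def test_nb_moments(self):
        mean, var = pt_mean_variance(PTCanonicalParams(a=0, b=10, c=0.5))
        assert mean == pytest.approx(10.0, rel=1e-8)
        assert var == pytest.approx(20.0, rel=1e-8)

    def test_variance_at_least_mean_on_grid(self):
        for p in GRID:
            if p.is_poisson:
                continue
            mean, var = pt_mean_variance(to_canonical(p))
            assert var >= mean * (1 - 1e-9)
            assert var / mean == pytest.approx(p.phi, rel=1e-6)

    def test_numerical_derivative_moment_oracle(self):
        """G'(1) and G''(1) by one-sided finite differences reproduce the moments."""
        h = 1e-5
        for p in GRID:
            if p.is_poisson or p.mu < 1:  # tiny means lose relative precision
                continue
            can = to_canonical(p)
            g = np.array([pt_pgf(1.0 - i * h, can) for i in range(4)])
            d1 = (11 * g[0] - 18 * g[1] + 9 * g[2] - 2 * g[3]) / (6 * h)
            d2 = (2 * g[0] - 5 * g[1] + 4 * g[2] - g[3]) / h ** 2
            mean, var = pt_mean_variance(can)
            assert d1 == pytest.approx(mean, rel=1e-4)
            assert d2 + d1 - d1 ** 2 == pytest.approx(var, rel=1e-3)


class TestCDFQuantile:
    P = PTCanonicalParams(a=0, b=10, c=0.5)

    def test_cdf_at_zero(self):
        assert pt_cdf(0, self.P) == pytest.approx(0.5 ** 10)

    def test_cdf_monotone_and_normalized(self):
        vals = [pt_cdf(k, self.P) for k in range(0, 60, 5)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert pt_cdf(500, self.P) == pytest.approx(1.0, abs=1e-8)

    def test_quantile_zero(self):
        assert pt_quantile(0.0, self.P) == 0

    def test_quantile_matches_nb_oracle(self):
        for q in (0.1, 0.25, 0.5, 0.75, 0.9, 0.95, 0.99):
            assert pt_quantile(q, self.P) == int(stats.nbinom.ppf(q, 10, 0.5))

    def test_quantile_galois(self):
        p = PTCanonicalParams(a=0.5, b=2.0, c=0.6)
        for k in (0, 1, 2, 5, 10):
            cdfk = pt_cdf(k, p)
            assert pt_quantile(cdfk, p) == k
            assert pt_cdf(pt_quantile(cdfk, p), p) >= cdfk


class TestSampling:
    def test_seed_determinism(self):
        p = PTMeanParams(10, 3, -1)
        a = pt_sample(100, p, 42)
        b = pt_sample(100, p, 42)
        assert np.array_equal(a, b)

    def test_moments_polya_aeppli(self):
        """Sample moments of PT(mu=10, phi=3, a=-1) match mu and phi within 3 SE."""
        p = PTMeanParams(10, 3, -1)
        x = pt_sample(50_000, p, 7)
        n = x.size
        # standard errors from the exact pmf moments
        probs = _extended_pmf(to_canonical(p))
        k = np.arange(probs.size, dtype=float)
        mean = k @ probs
        cen = k - mean
        m2 = (cen ** 2) @ probs
        m4 = (cen ** 4) @ probs
        se_mean = np.sqrt(m2 / n)
        se_var = np.sqrt((m4 - m2 ** 2) / n)
        assert abs(x.mean() - 10.0) < 3 * se_mean
        assert abs(x.var(ddof=1) - 30.0) < 3 * se_var

    def test_poisson_route_chisquare(self):
        x = pt_sample(20_000, PTMeanParams(4.0, 1.0, 0.0), 5)
        kmax = 12
        obs = np.bincount(np.minimum(x, kmax), minlength=kmax + 1)
        exp = stats.poisson.pmf(np.arange(kmax + 1), 4.0)
        exp[kmax] = stats.poisson.sf(kmax - 1, 4.0)
        res = stats.chisquare(obs, exp * x.size)
        assert res.pvalue > 0.01

    def test_general_shape_mean(self, rng):
        x = pt_sample(20_000, PTMeanParams(20, 5, 0.5), rng)
        assert x.mean() == pytest.approx(20.0, rel=0.05)
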