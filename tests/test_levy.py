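"""Component Lévy processes: exponent invariants and increment laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fellersim import (NumericalError, ParameterError, empirical_cf, levy)

from conftest import component_matrix

DETERMINISTIC_GRID = np.linspace(-100.0, 100.0, 401)


@pytest.mark.parametrize("comp", component_matrix(),
                         ids=lambda c: f"{c.name}-{list(c.params.values())}")
def test_exponent_invariants(comp):
    """ψ(0) = 0, Re ψ ≥ 0 and Hermitian symmetry on a deterministic grid."""
    psi0 = comp.exponent(np.array([0.0]))[0]
    assert abs(psi0) < 1e-12
    vals = comp.exponent(DETERMINISTIC_GRID)
    assert np.all(vals.real >= -1e-12)
    neg = comp.exponent(-DETERMINISTIC_GRID)
    assert np.max(np.abs(neg - np.conj(vals))) < 1e-12


@pytest.mark.parametrize("comp", component_matrix(),
                         ids=lambda c: f"{c.name}-{list(c.params.values())}")
@pytest.mark.parametrize("h", [0.1, 1.0])
def test_sampler_matches_exponent(comp, h, xi_grid):
    """Empirical CF of increment draws matches e^{−hψ} within 5/√n."""
    n = 20_000
    rng = np.random.default_rng(11)
    draws = comp.increments(h, n, rng)
    ecf = empirical_cf(draws, xi_grid)
    model = np.exp(-h * comp.exponent(xi_grid))
    assert np.max(np.abs(ecf - model)) < 5.0 / math.sqrt(n)


@pytest.mark.parametrize("comp", component_matrix(),
                         ids=lambda c: f"{c.name}-{list(c.params.values())}")
def test_infinite_divisibility_in_h(comp):
    """A draw at h agrees in law with the sum of two independent draws at h/2."""
    n, h = 10_000, 0.8
    rng = np.random.default_rng(5)
    full = comp.increments(h, n, rng)
    halves = comp.increments(h / 2, n, rng) + comp.increments(h / 2, n, rng)
    if comp.name == "poisson":
        # discrete law: compare binned counts
        kmax = int(max(full.max(), halves.max()))
        obs_f = np.bincount(full.astype(int), minlength=kmax + 1)
        obs_h = np.bincount(halves.astype(int), minlength=kmax + 1)
        keep = (obs_f + obs_h) >= 10
        chi2 = stats.chisquare(obs_f[keep], obs_h[keep] * obs_f[keep].sum()
                               / obs_h[keep].sum())
        assert chi2.pvalue > 0.01
    else:
        assert stats.ks_2samp(full, halves).pvalue > 0.01


@pytest.mark.parametrize("ctor, args", [
    (levy.make_brownian, (0.0, -1.0)),
    (levy.make_brownian, (0.0, 0.0)),
    (levy.make_poisson, (0.0,)),
    (levy.make_poisson, (-2.0,)),
    (levy.make_symmetric_stable, (0.0, 1.0)),
    (levy.make_symmetric_stable, (2.1, 1.0)),
    (levy.make_symmetric_stable, (1.5, -1.0)),
    (levy.make_gamma, (0.0, 1.0)),
    (levy.make_gamma, (1.0, 0.0)),
    (levy.make_nig, (1.0, 1.5, 1.0, 0.0)),
    (levy.make_nig, (1.0, 0.0, -1.0, 0.0)),
    (levy.make_meixner, (0.0, 0.0, 1.0, 0.0)),
    (levy.make_meixner, (1.0, 3.5, 1.0, 0.0)),
    (levy.make_meixner, (1.0, 0.0, -1.0, 0.0)),
])
def test_invalid_parameters_rejected(ctor, args):
    with pytest.raises(ParameterError):
        ctor(*args)


def test_brownian_moments():
    """Unit Brownian increments at h=1 have sample variance ≈ 1 (3 SE)."""
    n = 100_000
    x = levy.make_brownian(0.0, 1.0).increments(1.0, n, np.random.default_rng(1))
    assert abs(np.var(x) - 1.0) < 3.0 * math.sqrt(2.0 / n)


def test_poisson_support_and_mean():
    comp = levy.make_poisson(1.0)
    x = comp.increments(2.0, 100_000, np.random.default_rng(2))
    assert np.all(x >= 0) and np.all(x == np.round(x))
    assert abs(np.mean(x) - 2.0) < 3.0 * math.sqrt(2.0 / 100_000)


def test_stable_alpha2_is_gaussian():
    """α=2 with scale 1/√2 gives ψ(ξ) = ξ²/2, i.e. standard normal at h=1."""
    comp = levy.make_symmetric_stable(2.0, 1.0 / math.sqrt(2.0))
    x = comp.increments(1.0, 10_000, np.random.default_rng(3))
    assert stats.kstest(x, stats.norm(0, 1).cdf).pvalue > 0.01


def test_stable_alpha1_is_cauchy():
    """α=1 increments at h=1 are Cauchy(0,1): P(|X|<1) = 1/2."""
    n = 100_000
    comp = levy.make_symmetric_stable(1.0, 1.0)
    x = comp.increments(1.0, n, np.random.default_rng(4))
    frac = np.mean(np.abs(x) < 1.0)
    assert abs(frac - 0.5) < 3.0 * 0.5 / math.sqrt(n)


@pytest.mark.parametrize("alpha", [0.7, 1.0, 1.5, 1.9])
def test_stable_self_similarity(alpha):
    """Draws at h agree in law with h^{1/α} times draws at 1."""
    n, h = 10_000, 0.3
    comp = levy.make_symmetric_stable(alpha, 1.0)
    rng = np.random.default_rng(6)
    at_h = comp.increments(h, n, rng)
    scaled = h ** (1.0 / alpha) * comp.increments(1.0, n, rng)
    assert stats.ks_2samp(at_h, scaled).pvalue > 0.01


def test_stable_sampler_against_scipy_oracle():
    """CMS draws match scipy's independent levy_stable implementation."""
    comp = levy.make_symmetric_stable(1.5, 0.8)
    x = comp.increments(1.0, 10_000, np.random.default_rng(7))
    ref = stats.levy_stable(1.5, 0.0, scale=0.8)
    assert stats.kstest(x, ref.cdf).pvalue > 0.01


def test_gamma_subordinator():
    comp = levy.make_gamma(2.0, 1.0)
    x = comp.increments(1.0, 100_000, np.random.default_rng(8))
    assert np.all(x > 0)
    assert abs(np.mean(x) - 2.0) < 3.0 * math.sqrt(2.0 / 100_000)
    assert stats.kstest(x, stats.gamma(2.0, scale=1.0).cdf).pvalue > 0.01


def test_nig_symmetric_when_beta_zero():
    from fellersim.diagnostics import skewness_with_se
    comp = levy.make_nig(2.0, 0.0, 1.0, 0.0)
    x = comp.increments(1.0, 100_000, np.random.default_rng(9))
    g1, se = skewness_with_se(x)
    assert abs(g1) < 3.0 * se


def test_nig_mean_matches_cf_oracle():
    from fellersim.diagnostics import cf_moment_oracle
    comp = levy.make_nig(2.0, 1.0, 1.0, 0.0)
    n = 100_000
    x = comp.increments(1.0, n, np.random.default_rng(10))
    oracle_mean, oracle_var = cf_moment_oracle(comp.exponent, 1.0)
    assert abs(np.mean(x) - oracle_mean) < 3.0 * np.std(x) / math.sqrt(n)
    # closed-form cross-check of the oracle itself
    mean_cf, var_cf = comp.unit_moments
    assert abs(oracle_mean - mean_cf) < 1e-6
    assert abs(oracle_var - var_cf) < 1e-6


def test_meixner_symmetric_when_b_zero():
    comp = levy.make_meixner(1.0, 0.0, 1.0, 0.0)
    n = 100_000
    x = comp.increments(1.0, n, np.random.default_rng(12))
    assert abs(np.mean(x)) < 3.0 * np.std(x) / math.sqrt(n)


def test_meixner_moments_match_cf_oracle():
    from fellersim.diagnostics import cf_moment_oracle
    comp = levy.make_meixner(1.0, 1.0, 1.0, 0.0)
    n = 100_000
    x = comp.increments(1.0, n, np.random.default_rng(13))
    o_mean, o_var = cf_moment_oracle(comp.exponent, 1.0)
    assert abs(np.mean(x) - o_mean) < 3.0 * np.std(x) / math.sqrt(n)
    s_var = np.var(x, ddof=1)
    m4 = np.mean((x - np.mean(x)) ** 4)
    se_var = math.sqrt((m4 - s_var**2) / n)
    assert abs(s_var - o_var) < 3.0 * se_var


@settings(derandomize=True, max_examples=30, deadline=None)
@given(drift=st.floats(-5, 5), sigma=st.floats(0.1, 5),
       xi=st.floats(-50, 50))
def test_brownian_exponent_properties(drift, sigma, xi):
    """Hermitian symmetry and non-negative real part for arbitrary params."""
    comp = levy.make_brownian(drift, sigma)
    v = comp.exponent(np.array([xi, -xi, 0.0]))
    assert abs(v[2]) < 1e-12
    assert v[0].real >= 0
    assert abs(v[1] - np.conj(v[0])) < 1e-9


def test_growth_bound_brownian():
    """|ξ²/2|/(1+ξ²) increases to 1/2, so the estimate is ≤ 1/2."""
    grid = np.linspace(-200, 200, 2001)
    bound = levy.exponent_growth_bound(levy.make_brownian(0.0, 1.0).exponent, grid)
    assert bound <= 0.5 + 1e-12
    assert bound > 0.49


def test_growth_bound_poisson():
    grid = np.linspace(-150, 150, 2001)
    lam = 3.0
    bound = levy.exponent_growth_bound(levy.make_poisson(lam).exponent, grid)
    assert bound <= 2.0 * lam


def test_growth_bound_zero_exponent_and_errors():
    grid = np.linspace(-100, 100, 201)
    assert levy.exponent_growth_bound(lambda xi: np.zeros_like(xi), grid) == 0.0
    with pytest.raises(ParameterError):
        levy.exponent_growth_bound(lambda xi: np.zeros_like(xi), np.array([]))
    with pytest.raises(NumericalError):
        levy.exponent_growth_bound(lambda xi: np.full_like(xi, np.nan), grid)
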