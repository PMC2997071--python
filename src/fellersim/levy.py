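"""Component Lévy processes: characteristic exponents paired with exact
increment samplers.

Every component follows the sign convention

    E[exp(i ξ L_h)] = exp(−h ψ(ξ)),

so ψ(0) = 0, Re ψ ≥ 0 and ψ(−ξ) = conj(ψ(ξ)).  The sampler of a component
draws ``n`` increments of the process over an elapsed time ``h`` that are
exact in law (the Meixner sampler is exact up to the tolerance of its
inverse-CDF grid, certified at build time).

Components provided: Brownian motion, Poisson process, symmetric α-stable
process, Gamma subordinator, normal inverse Gaussian (NIG) process and the
Meixner process.  These are the building blocks that state-dependent mixing
turns into Feller families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.special import gammaln, loggamma

from .errors import NumericalError, ParameterError

__all__ = [
    "LevyComponent",
    "make_brownian",
    "make_poisson",
    "make_symmetric_stable",
    "make_gamma",
    "make_nig",
    "make_meixner",
    "exponent_growth_bound",
]


@dataclass(frozen=True)
class LevyComponent:
    """A named Lévy process: exponent ψ and an exact increment sampler.

    Attributes
    ----------
    name:
        Component kind (``"brownian"``, ``"poisson"``, ...).
    params:
        The validated constructor parameters.
    exponent:
        Vectorised map ξ → ψ(ξ) ∈ ℂ.
    sampler:
        Map ``(h, n, rng)`` → ``n`` draws distributed as ``L_h``.
    unit_moments:
        ``(mean, variance)`` per unit time, or ``None`` when undefined
        (e.g. the Cauchy case α = 1).
    """

    name: str
    params: dict
    exponent: Callable[[np.ndarray], np.ndarray]
    sampler: Callable[[float, int, np.random.Generator], np.ndarray]
    unit_moments: Optional[Tuple[float, float]] = field(default=None)

    def increments(self, h: float, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` increments of the process over elapsed time ``h``."""
        if h <= 0:
            raise ParameterError(f"elapsed time h must be > 0, got {h}")
        if n < 1:
            raise ParameterError(f"number of draws n must be >= 1, got {n}")
        return self.sampler(float(h), int(n), rng)


def _as_xi(xi) -> np.ndarray:
    return np.asarray(xi, dtype=float)


def make_brownian(drift: float, sigma: float) -> LevyComponent:
    """Brownian motion with drift: ψ(ξ) = −i·drift·ξ + σ²ξ²/2.

    Increments over ``h`` are Gaussian with mean ``drift·h`` and variance
    ``σ²·h``.
    """
    if not sigma > 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    drift, sigma = float(drift), float(sigma)

    def exponent(xi):
        xi = _as_xi(xi)
        return -1j * drift * xi + 0.5 * sigma**2 * xi**2

    def sampler(h, n, rng):
        return rng.normal(drift * h, sigma * math.sqrt(h), n)

    return LevyComponent("brownian", {"drift": drift, "sigma": sigma},
                         exponent, sampler, (drift, sigma**2))


def make_poisson(rate: float) -> LevyComponent:
    """Standard Poisson process: ψ(ξ) = rate·(1 − e^{iξ}).

    Increments over ``h`` are Poisson counts with mean ``rate·h``; all draws
    are non-negative integers (returned as floats).
    """
    if not rate > 0:
        raise ParameterError(f"rate must be > 0, got {rate}")
    rate = float(rate)

    def exponent(xi):
        xi = _as_xi(xi)
        return rate * (1.0 - np.exp(1j * xi))

    def sampler(h, n, rng):
        return rng.poisson(rate * h, n).astype(float)

    return LevyComponent("poisson", {"rate": rate}, exponent, sampler,
                         (rate, rate))


def _standard_symmetric_stable(alpha: float, n: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Standard symmetric α-stable draws with CF exp(−|ξ|^α).

    Chambers–Mallows–Stuck for α ∉ {1, 2}; dedicated Cauchy branch at α = 1
    (tan of a uniform angle); Gaussian with variance 2 at α = 2.
    """
    if alpha == 2.0:
        return rng.normal(0.0, math.sqrt(2.0), n)
    u = rng.uniform(-math.pi / 2, math.pi / 2, n)
    if alpha == 1.0:
        return np.tan(u)
    w = rng.exponential(1.0, n)
    return (np.sin(alpha * u) / np.cos(u) ** (1.0 / alpha)
            * (np.cos((1.0 - alpha) * u) / w) ** ((1.0 - alpha) / alpha))


def make_symmetric_stable(alpha: float, scale: float) -> LevyComponent:
    """Symmetric α-stable process: ψ(ξ) = (scale·|ξ|)^α, 0 < α ≤ 2.

    Increments over ``h`` equal ``h^{1/α}·scale·S`` with ``S`` standard
    symmetric α-stable.  α = 1 gives Cauchy increments with scale
    ``scale·h``; α = 2 gives Gaussian increments with variance ``2·scale²·h``
    (note ψ(ξ) = scale²ξ² at α = 2, twice the Brownian convention).
    """
    if not (0 < alpha <= 2):
        raise ParameterError(f"alpha must lie in (0, 2], got {alpha}")
    if not scale > 0:
        raise ParameterError(f"scale must be > 0, got {scale}")
    alpha, scale = float(alpha), float(scale)

    def exponent(xi):
        xi = _as_xi(xi)
        return ((scale * np.abs(xi)) ** alpha).astype(complex)

    def sampler(h, n, rng):
        return h ** (1.0 / alpha) * scale * _standard_symmetric_stable(alpha, n, rng)

    moments = (0.0, 2.0 * scale**2) if alpha == 2.0 else None
    return LevyComponent("stable", {"alpha": alpha, "scale": scale},
                         exponent, sampler, moments)


def make_gamma(shape_rate: float, scale_rate: float) -> LevyComponent:
    """Gamma subordinator: ψ(ξ) = shape_rate·Log(1 − iξ/scale_rate).

    Increments over ``h`` are Gamma(shape_rate·h, rate = scale_rate); all
    draws are strictly positive.
    """
    if not shape_rate > 0 or not scale_rate > 0:
        raise ParameterError(
            f"shape_rate and scale_rate must be > 0, got {shape_rate}, {scale_rate}")
    shape_rate, scale_rate = float(shape_rate), float(scale_rate)

    def exponent(xi):
        xi = _as_xi(xi)
        return shape_rate * np.log(1.0 - 1j * xi / scale_rate)

    def sampler(h, n, rng):
        return rng.gamma(shape_rate * h, 1.0 / scale_rate, n)

    return LevyComponent("gamma", {"shape_rate": shape_rate, "scale_rate": scale_rate},
                         exponent, sampler,
                         (shape_rate / scale_rate, shape_rate / scale_rate**2))


def make_nig(alpha: float, beta: float, delta: float, mu: float) -> LevyComponent:
    """Normal inverse Gaussian process.

    ψ(ξ) = −i·μ·ξ + δ·(√(α² − (β + iξ)²) − √(α² − β²)), principal root.
    Increments over ``h`` follow NIG(α, β, δ·h, μ·h), drawn exactly as a
    normal variance–mean mixture over an inverse-Gaussian subordinator:
    Z ~ IG(mean δh/γ, shape (δh)²) with γ = √(α²−β²), then
    X = μh + βZ + √Z·N(0,1).
    """
    if not abs(beta) < alpha:
        raise ParameterError(f"need |beta| < alpha, got beta={beta}, alpha={alpha}")
    if not delta > 0:
        raise ParameterError(f"delta must be > 0, got {delta}")
    alpha, beta, delta, mu = map(float, (alpha, beta, delta, mu))
    gamma_ = math.sqrt(alpha**2 - beta**2)

    def exponent(xi):
        xi = _as_xi(xi)
        root = np.sqrt((alpha**2 - (beta + 1j * xi) ** 2).astype(complex))
        return -1j * mu * xi + delta * (root - gamma_)

    def sampler(h, n, rng):
        z = rng.wald(delta * h / gamma_, (delta * h) ** 2, n)
        return mu * h + beta * z + np.sqrt(z) * rng.standard_normal(n)

    # mean = μ + δβ/γ, var = δα²/γ³ per unit time
    moments = (mu + delta * beta / gamma_, delta * alpha**2 / gamma_**3)
    return LevyComponent("nig", {"alpha": alpha, "beta": beta,
                                 "delta": delta, "mu": mu},
                         exponent, sampler, moments)


# --- Meixner ----------------------------------------------------------------

_MEIXNER_NORM_TOL = 1e-6
_MEIXNER_TAIL_FRAC = 1e-12
_MEIXNER_MIN_POINTS = 2**12
_MEIXNER_MAX_POINTS = 2**18


def _meixner_log_density(y: np.ndarray, a: float, b: float, d: float) -> np.ndarray:
    """log density of Meixner(a, b, d, 0) at y, via the complex log-gamma."""
    return (2 * d * math.log(2 * math.cos(b / 2))
            - math.log(2 * a * math.pi) - gammaln(2 * d)
            + b * y / a
            + 2 * np.real(loggamma(d + 1j * y / a)))


def _meixner_grid(a: float, b: float, d: float):
    """Inverse-CDF grid for Meixner(a, b, d, 0), certified to tolerance.

    The grid is centred at the mean a·d·tan(b/2) and extended until the
    density at both ends falls below 1e−12 of its mode (the tails decay
    exponentially at rate (π ∓ b)/a, so this terminates quickly).  The
    number of points adapts to the standard deviation so the peak is
    resolved; total mass is required to match 1 within 1e−6.
    """
    mean = a * d * math.tan(b / 2)
    sd = math.sqrt(a**2 * d / (2 * math.cos(b / 2) ** 2))
    half = max(10.0 * sd, 5.0 * a, 2.0)
    for _ in range(60):
        lo, hi = mean - half, mean + half
        probe = np.array([lo, hi])
        logf = _meixner_log_density(probe, a, b, d)
        peak = _meixner_log_density(np.array([mean]), a, b, d)[0]
        if np.all(logf - peak < math.log(_MEIXNER_TAIL_FRAC)):
            break
        half *= 2.0
    npts = int(min(_MEIXNER_MAX_POINTS,
                   max(_MEIXNER_MIN_POINTS, math.ceil(2 * half / (sd / 64)))))
    xs = np.linspace(mean - half, mean + half, npts)
    dens = np.exp(_meixner_log_density(xs, a, b, d))
    dx = xs[1] - xs[0]
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * dx)])
    total = cdf[-1]
    if abs(total - 1.0) > _MEIXNER_NORM_TOL:
        raise NumericalError(
            "Meixner density grid failed normalisation tolerance",
            payload={"total_mass": float(total), "a": a, "b": b, "d": d,
                     "points": npts, "half_width": half})
    return xs, cdf / total


def make_meixner(a: float, b: float, d: float, m: float) -> LevyComponent:
    """Meixner process.

    ψ(ξ) = −i·m·ξ + 2d·Log( cosh((aξ − ib)/2) / cos(b/2) ), principal branch
    (the log argument has strictly positive real part for |b| < π, so no
    branch tracking is needed).  Increments over ``h`` follow
    Meixner(a, b, d·h, m·h); they are drawn by inverse-CDF interpolation on
    an adaptive grid of the Meixner density, which involves |Γ(dh + iy/a)|².
    """
    if not a > 0:
        raise ParameterError(f"a must be > 0, got {a}")
    if not abs(b) < math.pi:
        raise ParameterError(f"need |b| < pi, got {b}")
    if not d > 0:
        raise ParameterError(f"d must be > 0, got {d}")
    a, b, d, m = map(float, (a, b, d, m))

    def exponent(xi):
        xi = _as_xi(xi)
        arg = np.cosh((a * xi - 1j * b) / 2.0) / math.cos(b / 2.0)
        return -1j * m * xi + 2.0 * d * np.log(arg)

    def sampler(h, n, rng):
        xs, cdf = _meixner_grid(a, b, d * h)
        u = rng.uniform(0.0, 1.0, n)
        return m * h + np.interp(u, cdf, xs)

    moments = (m + a * d * math.tan(b / 2),
               a**2 * d / (2 * math.cos(b / 2) ** 2))
    return LevyComponent("meixner", {"a": a, "b": b, "d": d, "m": m},
                         exponent, sampler, moments)


def exponent_growth_bound(exponent: Callable[[np.ndarray], np.ndarray],
                          xi_grid: np.ndarray) -> float:
    """Estimate sup_ξ |ψ(ξ)| / (1 + ξ²) on a grid.

    This is the constant in the growth condition under which the fixed-step
    scheme converges weakly; it is finite for every built-in component.  The
    grid should contain 0 and values of large modulus (≥ 100) so the
    quadratic regime is probed.
    """
    xi_grid = np.asarray(xi_grid, dtype=float)
    if xi_grid.size == 0:
        raise ParameterError("xi_grid must be non-empty")
    vals = np.asarray(exponent(xi_grid))
    if not np.all(np.isfinite(vals.real)) or not np.all(np.isfinite(vals.imag)):
        raise NumericalError("exponent returned non-finite values on the grid")
    return float(np.max(np.abs(vals) / (1.0 + xi_grid**2)))
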