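"""Preconfigured Feller families (the model registry).

``bpc``
    Brownian–Poisson–Cauchy mixture: Brownian motion below −6, a Poisson
    counting process around the origin ([−5, 5]) and a Cauchy process above
    6, glued with linear ramps of width ε = 1 that form a partition of unity
    on the gaps.  A single process that diffuses in one part of space,
    counts in another and takes heavy-tailed flights in a third.

``stable_like``
    Symmetric stable-like process whose index α(x) = 1.5 + 0.49·tri(x) is a
    triangle wave (period 2π) ranging over [1.01, 1.99]: Lipschitz but not
    smooth, oscillating between nearly-Cauchy and nearly-Gaussian behaviour.

``nig_like``
    Mean-reverting NIG-like process: α = 2, δ = 1, μ = 0 with asymmetry
    β(x) = −tanh(x).  There is no drift term — for x > 0 the increment law
    is negatively skewed (its mean has the sign of β), which pulls the
    process back towards 0, and symmetrically for x < 0.

``meixner_like``
    Meixner-like process with b = 0, d = 1, m = 0 and scale parameter
    a(x) = 0.5 + 1.5·e^{−x²/8}: the exponential decay rate of the increment
    density is inversely proportional to a, so the process moves with bigger
    steps near the origin.
"""

from __future__ import annotations

import numpy as np

from . import levy
from .errors import ConstructionError
from .family import LevyFamily, make_mixture_family, make_parameter_field_family
from .functions import unit_triangle_wave
from .mixing import RegionSpec, build_region_mixers

__all__ = ["MODEL_NAMES", "make_named_example", "example_colour_fn"]

MODEL_NAMES = ("bpc", "stable_like", "nig_like", "meixner_like")


def _make_bpc() -> LevyFamily:
    spec = RegionSpec([(-np.inf, -6.0), (-5.0, 5.0), (6.0, np.inf)], epsilon=1.0)
    mixers = build_region_mixers(spec)
    components = [levy.make_brownian(0.0, 1.0),
                  levy.make_poisson(1.0),
                  levy.make_symmetric_stable(1.0, 1.0)]
    fam = make_mixture_family(components, mixers)
    fam.metadata["region_spec"] = spec
    return fam


def stable_like_alpha(x) -> np.ndarray:
    """Default oscillating stable index, range [1.01, 1.99]."""
    return 1.5 + 0.49 * unit_triangle_wave(x)


def _make_stable_like() -> LevyFamily:
    return make_parameter_field_family(
        "stable", {"alpha": stable_like_alpha, "scale": 1.0},
        constraints={"alpha_lo": 1.01, "alpha_hi": 1.99})


def nig_like_beta(x) -> np.ndarray:
    """Default state-dependent NIG asymmetry (mean-reversion mechanism)."""
    return -np.tanh(np.asarray(x, dtype=float))


def _make_nig_like() -> LevyFamily:
    return make_parameter_field_family(
        "nig", {"alpha": 2.0, "beta": nig_like_beta, "delta": 1.0, "mu": 0.0},
        constraints={"eps0": 0.5})


def meixner_like_a(x) -> np.ndarray:
    """Default Meixner scale: larger near the origin, hence bigger steps."""
    return 0.5 + 1.5 * np.exp(-np.asarray(x, dtype=float) ** 2 / 8.0)


def _make_meixner_like() -> LevyFamily:
    return make_parameter_field_family(
        "meixner", {"a": meixner_like_a, "b": 0.0, "d": 1.0, "m": 0.0})


_FACTORIES = {
    "bpc": _make_bpc,
    "stable_like": _make_stable_like,
    "nig_like": _make_nig_like,
    "meixner_like": _make_meixner_like,
}


def make_named_example(name: str) -> LevyFamily:
    """Build a registry family by name; unknown names list the registry."""
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise ConstructionError(
            f"unknown model {name!r}; registered models: {', '.join(MODEL_NAMES)}")
    fam = factory()
    fam.metadata["model"] = name
    return fam


def example_colour_fn(family: LevyFamily):
    """The state functional used to colour-code plots of a registry family.

    For parameter-field families this is the varying parameter (the stable
    index α(x), the NIG asymmetry β(x), the Meixner scale a(x)); for the
    mixture example it is the index of the dominant mixing function.
    """
    name = family.metadata.get("model")
    if name == "stable_like":
        return stable_like_alpha
    if name == "nig_like":
        return nig_like_beta
    if name == "meixner_like":
        return meixner_like_a
    if family.kind == "mixture":
        mixers = family.mixers

        def dominant(x):
            w = np.stack([m(np.asarray(x, dtype=float)) for m in mixers])
            return np.argmax(w, axis=0).astype(float)
        return dominant
    return lambda x: np.zeros_like(np.asarray(x, dtype=float))
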