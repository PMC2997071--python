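"""State-indexed families of Lévy processes.

Two realisations are supported:

* **mixture** — the exponent is a weighted sum ψ_x(ξ) = Σ_i φ_i(x)·ψ_i(ξ)
  of component exponents with mixing-function weights.  Because independent
  exponents add, the increment Z_x(h) equals in distribution the sum of the
  component increments each run for the weighted time φ_i(x)·h, which gives
  an exact sampler from the component samplers alone.

* **parameter-field** — one component kind whose parameters are functions of
  the state (a stable index α(x), an NIG asymmetry β(x), Meixner (a, b, d,
  m)(x)); the increment at x is an increment of the component instantiated
  at x.

Both carry admissibility constraints that are screened on a dense state grid
at construction time — a family that would be invalid somewhere is rejected
before any sampling happens, with the offending state reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import math

import numpy as np

from . import levy
from .errors import ConstructionError, ParameterError
from .levy import LevyComponent
from .mixing import DEFAULT_STATE_GRID, MixingFunction
from .rng import as_generator

__all__ = ["LevyFamily", "make_mixture_family", "make_parameter_field_family",
           "sample_increment"]


@dataclass(frozen=True)
class LevyFamily:
    """A state-indexed family {L^(x)}: exponent ψ_x and sampler of Z_x(h)."""

    kind: str  # "mixture" | "parameter_field"
    exponent: Callable[[float, np.ndarray], np.ndarray]
    increment_sampler: Callable[[float, float, int, np.random.Generator], np.ndarray]
    constraints: dict = field(default_factory=dict)
    components: Optional[tuple] = None          # mixture only
    mixers: Optional[tuple] = None              # mixture only
    param_fns: Optional[dict] = None            # parameter-field only
    metadata: dict = field(default_factory=dict)


def _as_param_fn(value) -> Callable[[np.ndarray], np.ndarray]:
    if callable(value):
        return value
    const = float(value)
    return lambda x: np.full_like(np.asarray(x, dtype=float), const)


def make_mixture_family(components: Sequence[LevyComponent],
                        mixers: Sequence[MixingFunction],
                        grid: np.ndarray | None = None) -> LevyFamily:
    """Mix component Lévy processes with state-dependent weights.

    The mixed exponent is ψ_x(ξ) = Σ_i φ_i(x)ψ_i(ξ) and increments are drawn
    as Z_x(h) = Σ_i L_i(φ_i(x)·h) with independent component draws taken in
    component order from the supplied stream; components with φ_i(x)·h = 0
    contribute exactly 0 and consume no random numbers.

    Each mixer must pass its own validation, and the total weight Σ_i φ_i(x)
    must be strictly positive on the verification grid (a vanishing total
    weight would freeze the process — the pathological case excluded by the
    construction).
    """
    components = tuple(components)
    mixers = tuple(mixers)
    if len(components) != len(mixers) or not components:
        raise ConstructionError(
            f"need equally many components and mixers (>= 1), got "
            f"{len(components)} and {len(mixers)}")
    if grid is None:
        grid = DEFAULT_STATE_GRID
    grid = np.asarray(grid, dtype=float)
    for m in mixers:
        m.validate(grid)
    total = np.sum([m(grid) for m in mixers], axis=0)
    if np.any(total <= 0.0):
        x = float(grid[int(np.argmin(total))])
        raise ConstructionError(
            f"total mixing weight vanishes at x={x}; the family is "
            f"degenerate there", state=x)

    def exponent(x, xi):
        xi = np.asarray(xi, dtype=float)
        out = np.zeros(xi.shape, dtype=complex)
        for comp, mix in zip(components, mixers):
            w = float(mix(x))
            if w != 0.0:
                out = out + w * comp.exponent(xi)
        return out

    def sampler(x, h, n, rng):
        out = np.zeros(n)
        for comp, mix in zip(components, mixers):
            hw = float(mix(x)) * h
            if hw > 0.0:
                out += comp.sampler(hw, n, rng)
        return out

    return LevyFamily("mixture", exponent, sampler,
                      components=components, mixers=mixers)


def sample_increment(family: LevyFamily, x: float, h: float, n: int,
                     rng_or_seed) -> np.ndarray:
    """Draw ``n`` independent increments Z_x(h) of the family at state ``x``.

    Deterministic given the generator state (or seed); any admissibility
    violation at ``x`` surfaces as a :class:`ConstructionError` from the
    family's sampler.
    """
    if h <= 0:
        raise ParameterError(f"elapsed time h must be > 0, got {h}")
    if n < 1:
        raise ParameterError(f"number of draws n must be >= 1, got {n}")
    rng = as_generator(rng_or_seed)
    return family.increment_sampler(float(x), float(h), int(n), rng)


# --- parameter-field families ----------------------------------------------

_FIELD_KINDS = ("stable", "nig", "meixner")


def _check_field_constraints(kind: str, fns: Mapping[str, Callable],
                             constraints: dict, grid: np.ndarray) -> None:
    """Screen parameter functions on a grid; name the first offending x."""

    def offending(mask, what):
        x = float(grid[np.nonzero(mask)[0][0]])
        raise ConstructionError(f"{what} at x={x}", state=x)

    if kind == "stable":
        lo, hi = constraints["alpha_lo"], constraints["alpha_hi"]
        if not (0.0 < lo <= hi < 2.0):
            raise ConstructionError(
                f"stable index bounds must satisfy 0 < alpha_lo <= alpha_hi < 2, "
                f"got [{lo}, {hi}]")
        a = np.asarray(fns["alpha"](grid), dtype=float)
        if np.any(a < lo) or np.any(a > hi):
            offending((a < lo) | (a > hi),
                      f"stable index alpha(x) leaves [{lo}, {hi}]")
        s = np.asarray(fns["scale"](grid), dtype=float)
        if np.any(s <= 0):
            offending(s <= 0, "stable scale(x) non-positive")
    elif kind == "nig":
        eps0 = constraints["eps0"]
        al = np.asarray(fns["alpha"](grid), dtype=float)
        be = np.asarray(fns["beta"](grid), dtype=float)
        de = np.asarray(fns["delta"](grid), dtype=float)
        if np.any(al <= 0):
            offending(al <= 0, "NIG alpha(x) non-positive")
        bad = np.abs(be) > al - eps0
        if np.any(bad):
            offending(bad, f"NIG asymmetry |beta(x)| > alpha(x) - {eps0}")
        if np.any(de <= 0):
            offending(de <= 0, "NIG delta(x) non-positive")
    elif kind == "meixner":
        eps0 = constraints["eps0"]
        a = np.asarray(fns["a"](grid), dtype=float)
        b = np.asarray(fns["b"](grid), dtype=float)
        d = np.asarray(fns["d"](grid), dtype=float)
        if np.any(a < eps0):
            offending(a < eps0, f"Meixner a(x) < {eps0}")
        bad = np.abs(b) > math.pi - eps0
        if np.any(bad):
            offending(bad, f"Meixner |b(x)| > pi - {eps0}")
        if np.any(d < eps0):
            offending(d < eps0, f"Meixner d(x) < {eps0}")
    else:  # pragma: no cover - guarded by caller
        raise ConstructionError(f"unknown component kind {kind!r}")


_DEFAULT_CONSTRAINTS = {
    "stable": {"alpha_lo": 0.01, "alpha_hi": 1.99},
    "nig": {"eps0": 0.5},
    "meixner": {"eps0": 0.05},
}

_FIELD_PARAMS = {
    "stable": ("alpha", "scale"),
    "nig": ("alpha", "beta", "delta", "mu"),
    "meixner": ("a", "b", "d", "m"),
}

_FIELD_CONSTRUCTORS = {
    "stable": lambda p: levy.make_symmetric_stable(p["alpha"], p["scale"]),
    "nig": lambda p: levy.make_nig(p["alpha"], p["beta"], p["delta"], p["mu"]),
    "meixner": lambda p: levy.make_meixner(p["a"], p["b"], p["d"], p["m"]),
}


def make_parameter_field_family(component_kind: str,
                                param_fns: Mapping[str, object],
                                constraints: dict | None = None,
                                grid: np.ndarray | None = None) -> LevyFamily:
    """A family obtained by making a component's parameters state dependent.

    ``component_kind`` is one of ``"stable"``, ``"nig"``, ``"meixner"``.
    ``param_fns`` maps parameter names to callables of the state (or to
    constants).  Missing parameters default to their neutral values
    (``scale=1``, ``mu=0`` / ``m=0``, ``delta=1`` / ``d=1``, ``alpha=2`` for
    NIG, ``b=0``).

    Admissibility is verified on a dense grid at construction — the stable
    index must stay inside a closed sub-interval of (0, 2), the NIG
    asymmetry must keep |β(x)| ≤ α(x) − ε₀, and the Meixner parameters must
    stay bounded away from their critical values — so that every state the
    simulator can visit yields a valid component.
    """
    if component_kind not in _FIELD_KINDS:
        raise ConstructionError(
            f"unknown component kind {component_kind!r}; "
            f"choose one of {_FIELD_KINDS}")
    defaults = {"stable": {"scale": 1.0},
                "nig": {"alpha": 2.0, "beta": 0.0, "delta": 1.0, "mu": 0.0},
                "meixner": {"a": 1.0, "b": 0.0, "d": 1.0, "m": 0.0}}
    merged = dict(defaults[component_kind])
    merged.update(param_fns)
    names = _FIELD_PARAMS[component_kind]
    missing = [k for k in names if k not in merged]
    if missing:
        raise ConstructionError(f"missing parameter functions: {missing}")
    fns = {k: _as_param_fn(merged[k]) for k in names}
    cons = dict(_DEFAULT_CONSTRAINTS[component_kind])
    if constraints:
        cons.update(constraints)
    if grid is None:
        grid = DEFAULT_STATE_GRID
    _check_field_constraints(component_kind, fns, cons, np.asarray(grid, dtype=float))

    build = _FIELD_CONSTRUCTORS[component_kind]

    def component_at(x: float) -> LevyComponent:
        params = {k: float(fns[k](np.asarray([x]))[0]) for k in names}
        return build(params)

    def exponent(x, xi):
        return component_at(x).exponent(xi)

    def sampler(x, h, n, rng):
        return component_at(x).sampler(h, n, rng)

    return LevyFamily("parameter_field", exponent, sampler,
                      constraints=cons, param_fns=fns,
                      metadata={"component_kind": component_kind,
                                "component_at": component_at})
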