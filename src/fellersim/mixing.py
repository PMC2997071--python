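"""Mixing functions and separated-region geometry.

A Feller family is built from component Lévy processes by weighting their
exponents with non-negative, bounded, Lipschitz functions of the state
(mixing functions).  For uniformly separated regions the canonical mixers
are mollified indicators: 1 on the region, 0 at distance ≥ ε, linear ramp in
between (Lipschitz constant 1/ε).  When adjacent gaps have width exactly ε
the ramps form a partition of unity on the gaps, so the total weight never
vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence, Tuple

import numpy as np

from .errors import ConstructionError

__all__ = ["MixingFunction", "RegionSpec", "build_region_mixers",
           "DEFAULT_STATE_GRID"]

#: grid on which family-level constraints are verified numerically
DEFAULT_STATE_GRID = np.linspace(-50.0, 50.0, 10_000)

_VALIDATION_TOL = 1e-8


@dataclass(frozen=True)
class MixingFunction:
    """A state-space weight φ with declared sup bound and Lipschitz constant.

    ``validate`` checks non-negativity, the bound and a finite-difference
    Lipschitz estimate on a grid; this is a sampled check, not a proof.
    """

    fn: Callable[[np.ndarray], np.ndarray]
    bound: float
    lipschitz: float
    name: str = field(default="mixer")

    def __call__(self, x):
        return self.fn(np.asarray(x, dtype=float))

    def validate(self, grid: np.ndarray = DEFAULT_STATE_GRID,
                 tol: float = _VALIDATION_TOL) -> None:
        grid = np.asarray(grid, dtype=float)
        vals = np.asarray(self(grid), dtype=float)
        if np.any(vals < -tol):
            x = float(grid[int(np.argmin(vals))])
            raise ConstructionError(
                f"mixing function {self.name!r} negative at x={x}", state=x)
        if np.any(vals > self.bound + tol):
            x = float(grid[int(np.argmax(vals))])
            raise ConstructionError(
                f"mixing function {self.name!r} exceeds its bound {self.bound} "
                f"at x={x}", state=x)
        dx = np.diff(grid)
        slopes = np.abs(np.diff(vals)) / dx
        bad = slopes > self.lipschitz * (1.0 + 1e-9) + tol / np.min(dx)
        if np.any(bad):
            x = float(grid[:-1][bad][0])
            raise ConstructionError(
                f"mixing function {self.name!r} violates its Lipschitz "
                f"constant {self.lipschitz} near x={x}", state=x)


@dataclass(frozen=True)
class RegionSpec:
    """Disjoint closed intervals with a uniform separation distance ε > 0.

    Intervals may be half-infinite (``-inf`` / ``inf`` endpoints).  The
    pairwise distance between regions must be at least ε.
    """

    regions: Tuple[Tuple[float, float], ...]
    epsilon: float

    def __init__(self, regions: Sequence[Sequence[float]], epsilon: float):
        if epsilon <= 0:
            raise ConstructionError(f"epsilon must be > 0, got {epsilon}")
        regs = tuple(sorted((float(lo), float(hi)) for lo, hi in regions))
        if not regs:
            raise ConstructionError("at least one region is required")
        for lo, hi in regs:
            if not lo <= hi:
                raise ConstructionError(f"invalid interval [{lo}, {hi}]")
        for (lo1, hi1), (lo2, hi2) in zip(regs, regs[1:]):
            gap = lo2 - hi1
            if gap < epsilon:
                raise ConstructionError(
                    f"regions [{lo1}, {hi1}] and [{lo2}, {hi2}] are separated "
                    f"by {gap} < epsilon={epsilon}")
        object.__setattr__(self, "regions", regs)
        object.__setattr__(self, "epsilon", float(epsilon))

    def endpoints(self) -> np.ndarray:
        pts = [p for lo, hi in self.regions for p in (lo, hi)
               if math.isfinite(p)]
        return np.asarray(pts, dtype=float)


def _interval_distance(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.maximum(0.0, np.maximum(lo - x, x - hi))


def build_region_mixers(spec: RegionSpec) -> list[MixingFunction]:
    """Mollified indicators of the regions: φ_i(x) = max(0, 1 − d(x, R_i)/ε).

    Each mixer is identically 1 on its region, 0 at distance ≥ ε from it and
    piecewise linear in between (bound 1, Lipschitz constant 1/ε).  On a gap
    of width exactly ε the two neighbouring mixers sum to 1.
    """
    eps = spec.epsilon
    mixers = []
    for i, (lo, hi) in enumerate(spec.regions):
        def fn(x, lo=lo, hi=hi):
            x = np.asarray(x, dtype=float)
            return np.clip(1.0 - _interval_distance(x, lo, hi) / eps, 0.0, 1.0)
        mixers.append(MixingFunction(fn, bound=1.0, lipschitz=1.0 / eps,
                                     name=f"region[{lo}, {hi}]"))
    return mixers
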