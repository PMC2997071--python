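"""Fixed-step Markov-chain (Euler-type) scheme for Feller sample paths.

Given a state-indexed family {L^(x)} the scheme starts at x₀ and repeats

    x_{k+1} = x_k + z_k,   z_k ~ Z_{x_k}(h),

re-resolving the increment law at the *current* position each step, until
K = floor(T/h) steps have been taken.  As h → 0 the chain converges weakly
to the Feller process with local exponents ψ_x, provided the process is
unique for its restricted generator and sup_x |ψ_x(ξ)|/(1 + ξ²) is finite
(the growth bound surfaced by :func:`fellersim.levy.exponent_growth_bound`;
uniqueness cannot be checked numerically and is an assumption).

For a state-independent family the chain is *exact* in law at every grid
time regardless of h, because Lévy increments compose exactly.

Reproducibility contract: path ``j`` of a run with root seed ``s`` draws all
its increments, in step order, from the substream keyed ``(j,)`` of ``s``,
so a path is bit-identical no matter how many other paths are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import math

import numpy as np
import pandas as pd

from .errors import FellerSimError, ParameterError, SimulationError
from .family import LevyFamily
from .rng import substream

__all__ = ["SimulationConfig", "SamplePath", "simulate_path",
           "simulate_ensemble", "weak_convergence_probe"]


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters: start x0, horizon T, step h, number of paths, seed."""

    x0: float
    T: float
    h: float
    n_paths: int = 1
    seed: int = 0

    def __post_init__(self):
        if not self.T > 0:
            raise ParameterError(f"horizon T must be > 0, got {self.T}")
        if not 0 < self.h <= self.T:
            raise ParameterError(
                f"step size h must lie in (0, T], got h={self.h}, T={self.T}")
        if self.n_paths < 1:
            raise ParameterError(f"n_paths must be >= 1, got {self.n_paths}")

    @property
    def n_steps(self) -> int:
        """K = floor(T/h); no partial final step is taken."""
        return int(math.floor(self.T / self.h + 1e-12))


@dataclass(frozen=True)
class SamplePath:
    """A discrete trajectory (t_k = k·h, x_k), k = 0..K.

    Interpreted as a càdlàg step function: the process sits at x_k on
    [t_k, t_{k+1}).  ``seed_info`` records the root seed and substream key
    so the path can be regenerated exactly.
    """

    times: np.ndarray
    states: np.ndarray
    path_id: int = 0
    seed_info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.times.shape != self.states.shape or self.times.ndim != 1:
            raise ParameterError("times and states must be matching 1-d arrays")

    @property
    def terminal(self) -> float:
        return float(self.states[-1])


def simulate_path(family: LevyFamily, config: SimulationConfig,
                  path_id: int = 0) -> SamplePath:
    """Generate one approximate sample path by the fixed-step scheme."""
    k_steps = config.n_steps
    rng = substream(config.seed, path_id)
    states = np.empty(k_steps + 1)
    states[0] = config.x0
    x = float(config.x0)
    for k in range(k_steps):
        try:
            z = family.increment_sampler(x, config.h, 1, rng)
        except FellerSimError as exc:
            raise SimulationError(
                f"increment sampling failed at step {k}, state {x}: {exc}",
                step=k, state=x) from exc
        x += float(z[0])
        states[k + 1] = x
    times = np.arange(k_steps + 1) * config.h
    return SamplePath(times, states, path_id,
                      seed_info={"seed": config.seed, "spawn_key": (path_id,)})


def simulate_ensemble(family: LevyFamily,
                      config: SimulationConfig) -> list[SamplePath]:
    """Generate ``config.n_paths`` mutually independent paths.

    Path ``j`` uses the substream keyed ``(j,)``, so it is identical whether
    or not the other paths are generated.
    """
    return [simulate_path(family, config, path_id=j)
            for j in range(config.n_paths)]


def weak_convergence_probe(family: LevyFamily, x0: float, T: float,
                           h_list: Sequence[float],
                           f: Callable[[np.ndarray], np.ndarray],
                           n_paths: int, seed: int) -> pd.DataFrame:
    """Monte Carlo estimates of E[f(X_T)] across decreasing step sizes.

    Returns one row per h with the estimate and its standard error.  The
    output is evidence of weak convergence (estimates stabilising within
    Monte Carlo resolution), not a proof; each h uses its own independent
    seed substreams.
    """
    h_list = list(h_list)
    if not h_list:
        raise ParameterError("h_list must be non-empty")
    if any(h2 >= h1 for h1, h2 in zip(h_list, h_list[1:])):
        raise ParameterError(f"h_list must be strictly decreasing, got {h_list}")
    rows = []
    for i, h in enumerate(h_list):
        cfg = SimulationConfig(x0=x0, T=T, h=h, n_paths=n_paths, seed=seed)
        terminals = np.empty(n_paths)
        for j in range(n_paths):
            k_steps = cfg.n_steps
            rng = substream(seed, i, j)
            x = float(x0)
            for _ in range(k_steps):
                x += float(family.increment_sampler(x, h, 1, rng)[0])
            terminals[j] = x
        vals = np.asarray(f(terminals), dtype=float)
        est = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / math.sqrt(n_paths))
        rows.append({"h": h, "estimate": est, "se": se, "n_paths": n_paths})
    return pd.DataFrame(rows)
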