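"""Named one-dimensional function forms for config-defined families.

Custom families in a JSON run configuration describe their mixing and
parameter functions with small descriptor objects instead of code.  The
available forms cover everything the built-in examples use:

``constant``         {"form": "constant", "value": c}
``triangle``         {"form": "triangle", "base": b, "amplitude": A, "period": P}
                     b + A·tri(2πx/P) with tri the unit triangle wave
                     (period 2π, range [−1, 1], Lipschitz, not smooth)
``tanh``             {"form": "tanh", "amplitude": A, "width": w, "offset": c}
                     c + A·tanh(x/w)
``gaussian_bump``    {"form": "gaussian_bump", "base": b, "height": H, "width": w}
                     b + H·exp(−x²/w)
``piecewise_linear`` {"form": "piecewise_linear", "x": [...], "y": [...]}
                     linear interpolation, end values held outside the knots
"""

from __future__ import annotations

import math
from typing import Callable, Mapping

import numpy as np

from .errors import ConstructionError

__all__ = ["make_function", "unit_triangle_wave"]


def unit_triangle_wave(x) -> np.ndarray:
    """Triangle wave with period 2π and range [−1, 1]; slope magnitude 2/π."""
    return 2.0 / math.pi * np.arcsin(np.sin(np.asarray(x, dtype=float)))


def make_function(desc: Mapping) -> Callable[[np.ndarray], np.ndarray]:
    """Build the callable described by ``desc`` (see module docstring)."""
    try:
        form = desc["form"]
    except (KeyError, TypeError):
        raise ConstructionError(f"function descriptor needs a 'form': {desc!r}")
    if form == "constant":
        c = float(desc["value"])
        return lambda x: np.full_like(np.asarray(x, dtype=float), c)
    if form == "triangle":
        base = float(desc["base"])
        amp = float(desc["amplitude"])
        period = float(desc.get("period", 2 * math.pi))
        if period <= 0:
            raise ConstructionError(f"triangle period must be > 0, got {period}")
        w = 2 * math.pi / period
        return lambda x: base + amp * unit_triangle_wave(w * np.asarray(x, dtype=float))
    if form == "tanh":
        amp = float(desc["amplitude"])
        width = float(desc.get("width", 1.0))
        offset = float(desc.get("offset", 0.0))
        if width <= 0:
            raise ConstructionError(f"tanh width must be > 0, got {width}")
        return lambda x: offset + amp * np.tanh(np.asarray(x, dtype=float) / width)
    if form == "gaussian_bump":
        base = float(desc["base"])
        height = float(desc["height"])
        width = float(desc["width"])
        if width <= 0:
            raise ConstructionError(f"bump width must be > 0, got {width}")
        return lambda x: base + height * np.exp(-np.asarray(x, dtype=float) ** 2 / width)
    if form == "piecewise_linear":
        xs = np.asarray(desc["x"], dtype=float)
        ys = np.asarray(desc["y"], dtype=float)
        if xs.ndim != 1 or xs.shape != ys.shape or xs.size < 2:
            raise ConstructionError("piecewise_linear needs matching x/y arrays "
                                    "with at least two knots")
        if np.any(np.diff(xs) <= 0):
            raise ConstructionError("piecewise_linear knots must be strictly increasing")
        return lambda x: np.interp(np.asarray(x, dtype=float), xs, ys)
    raise ConstructionError(f"unknown function form {form!r}")
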