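"""Trajectory serialisation and colour-coded path plots.

Trajectories are written as long-format CSV (``path_id,step,time,state``)
with shortest round-trip float formatting, so identical configurations give
byte-identical files and reading a file back reproduces the states exactly.

Plots render each path as a right-continuous step function (the càdlàg
convention: the process sits at x_k on [t_k, t_{k+1})) with segments
coloured by a user functional of the state — for a stable-like family the
local index α(x), rendered on a red (low) → yellow (high) map.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .family import LevyFamily
from .simulate import SamplePath

__all__ = ["write_paths_csv", "read_paths_csv", "plot_paths_colorcoded"]

CSV_HEADER = "path_id,step,time,state"


def write_paths_csv(paths: Sequence[SamplePath], destination) -> None:
    """Write paths in long format; one row per grid point, full precision."""
    paths = list(paths)
    if not paths:
        raise ParameterError("no paths to write")
    lines = [CSV_HEADER]
    for p in paths:
        for k, (t, s) in enumerate(zip(p.times, p.states)):
            lines.append(f"{p.path_id},{k},{float(t)!r},{float(s)!r}")
    text = "\n".join(lines) + "\n"
    with open(destination, "w", newline="") as fh:
        fh.write(text)


def read_paths_csv(source) -> pd.DataFrame:
    """Read a trajectory CSV back into a DataFrame (exact float round-trip)."""
    return pd.read_csv(source, dtype={"path_id": int, "step": int,
                                      "time": float, "state": float},
                       float_precision="round_trip")


def plot_paths_colorcoded(paths: Sequence[SamplePath],
                          family: LevyFamily,
                          value_fn: Callable[[np.ndarray], np.ndarray],
                          destination,
                          cmap: str = "autumn") -> None:
    """One figure: time vs state, càdlàg steps coloured by ``value_fn(x)``.

    The default ``autumn`` colormap runs red → yellow, so the low end of the
    functional is red and the high end yellow.  Raises before any file is
    written if the path list is empty or the functional is non-finite on the
    visited states.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    paths = list(paths)
    if not paths:
        raise ParameterError("no paths to plot")
    all_states = np.concatenate([p.states for p in paths])
    values = np.asarray(value_fn(all_states), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ParameterError("value_fn is non-finite on the plotted state range")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        vmax = vmin + 1.0  # constant functional: single-colour rendering
    norm = plt.Normalize(vmin, vmax)

    fig, ax = plt.subplots(figsize=(9, 5))
    for p in paths:
        t, s = p.times, p.states
        # horizontal càdlàg segments (t_k, x_k) -> (t_{k+1}, x_k)
        segs = np.stack([
            np.column_stack([t[:-1], s[:-1]]),
            np.column_stack([t[1:], s[:-1]]),
        ], axis=1)
        lc = LineCollection(segs, cmap=cmap, norm=norm)
        lc.set_array(np.asarray(value_fn(s[:-1]), dtype=float))
        ax.add_collection(lc)
        # thin connectors at the jumps, coloured by the post-jump state
        vsegs = np.stack([
            np.column_stack([t[1:], s[:-1]]),
            np.column_stack([t[1:], s[1:]]),
        ], axis=1)
        vlc = LineCollection(vsegs, cmap=cmap, norm=norm, linewidths=0.4)
        vlc.set_array(np.asarray(value_fn(s[1:]), dtype=float))
        ax.add_collection(vlc)
    ax.autoscale()
    ax.set_xlabel("time")
    ax.set_ylabel("state")
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax,
                 label="state functional")
    fig.tight_layout()
    fig.savefig(destination)
    plt.close(fig)
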