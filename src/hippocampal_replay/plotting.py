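"""Signal-propagation map rendering.

Each free cell of the arena is drawn as a green ring whose radius is
proportional to the strength of the position information returned by the
map there, and whose line width is proportional to how often the place
cells at that position were reactivated during replay.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .env import GridWorld

__all__ = ["render_signal_map", "plot_learning_curves"]


def render_signal_map(world: GridWorld, strength: np.ndarray,
                      reactivation: np.ndarray, path=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    react = reactivation.astype(float)
    react_peak = react.max() if react.max() > 0 else 1.0
    for x, y in world.free_cells():
        radius = 0.45 * strength[x, y]
        if radius <= 0:
            continue
        width = 0.5 + 2.5 * react[x, y] / react_peak
        ax.add_patch(plt.Circle((x, y), radius, fill=False,
                                color="green", linewidth=width))
    for x, y in world.obstacles:
        ax.add_patch(plt.Rectangle((x - 0.5, y - 0.5), 1, 1, color="black"))
    ax.plot(*world.start, "ro", markersize=8)
    ax.plot(*world.goal, "bs", markersize=8)
    ax.set_xlim(-1, world.width)
    ax.set_ylim(-1, world.height)
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_learning_curves(results: dict, window: int = 30, path=None, ax=None):
    """Smoothed per-episode return curves, one line per labelled run."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    kernel = np.ones(window) / window
    for label, returns in results.items():
        returns = np.asarray(returns, dtype=float)
        if len(returns) >= window:
            smooth = np.convolve(returns, kernel, mode="valid")
            ax.plot(np.arange(window, len(returns) + 1), smooth, label=label)
        else:
            ax.plot(np.arange(1, len(returns) + 1), returns, label=label)
    ax.set_xlabel("episode")
    ax.set_ylabel(f"return ({window}-episode moving average)")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
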