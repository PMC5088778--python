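"""Minimal static scalp-map export."""

from __future__ import annotations

import numpy as np

from .layout import ChannelLayout

__all__ = ["plot_topomap"]


def plot_topomap(values, layout: ChannelLayout, ax=None, highlight=(), cmap="RdBu_r"):
    """Scatter-style scalp map of one value per channel.

    ``highlight`` names channels to mark (e.g. cluster members).  Returns the
    matplotlib axes.  Intentionally schematic: sensors on a unit head circle,
    no interpolation.
    """
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    if values.shape != (layout.n_channels,):
        raise ValueError("need one value per channel")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="k", lw=1)
    ax.plot([-0.08, 0, 0.08], [1.0, 1.08, 1.0], color="k", lw=1)  # nose
    vmax = np.nanmax(np.abs(values)) or 1.0
    sc = ax.scatter(
        layout.positions[:, 0], layout.positions[:, 1],
        c=values, cmap=cmap, vmin=-vmax, vmax=vmax, s=160, edgecolors="k",
    )
    for name in highlight:
        i = layout.index(name)
        ax.scatter(*layout.positions[i], facecolors="none", edgecolors="w", s=40, zorder=3)
    for i, name in enumerate(layout.names):
        ax.annotate(name, layout.positions[i], fontsize=6, ha="center", va="center")
    ax.set_aspect("equal")
    ax.set_axis_off()
    plt.colorbar(sc, ax=ax, shrink=0.7)
    return ax
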