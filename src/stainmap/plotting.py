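"""Plot mean +/- SD radial fraction curves (three stacked class panels)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .classes import CLASS_NAMES, StainClass
from .profiler import AggregateProfile

_COLORS = {StainClass.ADIPOGENIC: "tab:red", StainClass.OSTEOGENIC: "tab:blue", StainClass.NEGATIVE: "0.5"}


def plot_aggregate_profile(
    aggregate: AggregateProfile,
    path: str | Path | None = None,
    coordinate: str = "center",
):
    """Plot per-class mean fraction vs radius with SD error bars.

    ``coordinate`` selects the x axis: distance from the confinement
    center, or distance from the confining wall.
    """
    if coordinate == "center":
        x = aggregate.mid_radii_um
        xlabel = "distance from center (μm)"
    elif coordinate == "wall":
        x = aggregate.distance_from_wall_um
        xlabel = "distance from wall (μm)"
    else:
        raise ValueError("coordinate must be 'center' or 'wall'")

    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(5, 7))
    for ax, cls, name in zip(axes, StainClass, CLASS_NAMES):
        ax.errorbar(
            x,
            aggregate.mean_fraction(cls),
            yerr=aggregate.sd_fraction(cls),
            fmt="o-",
            capsize=3,
            color=_COLORS[cls],
        )
        ax.set_ylabel(f"{name}\nfraction")
        ax.set_ylim(-0.05, 1.05)
    axes[-1].set_xlabel(xlabel)
    fig.suptitle(f"N = {aggregate.n_replicates} replicates")
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=150)
        plt.close(fig)
    return fig


__all__ = ["plot_aggregate_profile"]
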