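"""Optional plotting companions for trajectories and power curves.

Matplotlib is imported lazily so headless/pipeline use of the simulators
never touches a plotting backend.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_fitness_trajectories", "plot_power_curve"]


def plot_fitness_trajectories(trajectories: pd.DataFrame, ax=None):
    """Plot mean fitness per iteration for each scenario.

    ``trajectories`` is the long frame written by the ``figure2`` preset
    (columns ``scenario, iteration, mean_fitness``).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, grp in trajectories.groupby("scenario"):
        ax.plot(grp["iteration"], grp["mean_fitness"], label=name, lw=1.2)
    ax.set_xlabel("iteration")
    ax.set_ylabel("mean fitness (party 1)")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_power_curve(summary: pd.DataFrame, x: str, ax=None):
    """Plot aggregated fitness power against a grid axis (e.g. ``f`` or ``r``).

    ``summary`` is the long table written by :func:`~fgmconflict.experiments.
    run_experiment`; rows with ``statistic == "power_party1"`` are used, with
    4-SE error bars.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    rows = summary[summary["statistic"] == "power_party1"].sort_values(x)
    ax.errorbar(rows[x], rows["mean"], yerr=4 * rows["se"], marker="o", capsize=3)
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(x)
    ax.set_ylabel("fitness power of party 1")
    ax.set_ylim(0, 1)
    return ax
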