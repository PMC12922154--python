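"""Polar visualizations: direction line plots, joint heatmaps, raw scatter.

All plots use the mathematical polar convention (0 degrees at "3 o'clock",
counter-clockwise), matching the direction convention of the rest of the
package; pass ``clockwise=True`` to mirror into the screen convention some
eye-tracking vendors use.  Figures are presentation only - every number a
figure shows is available from the CSV/JSON outputs, so nothing downstream
ever needs to parse an image.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .density import DirectionDensity, HistogramResult, JointDensityGrid, bin_center_polyline
from .io import SaccadeTable

__all__ = [
    "plot_direction_polar",
    "plot_joint_heatmap",
    "plot_joint_panels",
    "plot_raw_scatter",
    "plot_histogram_polar",
]

_KERNEL_COLORS = {"von_mises": "tab:blue", "gaussian_linear": "tab:orange"}


def _polar_axis(ax, clockwise: bool):
    ax.set_theta_zero_location("E")
    ax.set_theta_direction(-1 if clockwise else 1)
    return ax


def _closed(theta_deg: np.ndarray, values: np.ndarray):
    t = np.deg2rad(np.append(theta_deg, theta_deg[0] + 360.0))
    v = np.append(values, values[0])
    return t, v


def plot_direction_polar(
    densities: DirectionDensity | list[DirectionDensity],
    out,
    labels: list[str] | None = None,
    clockwise: bool = False,
):
    """Closed polar line plot of one or more direction densities.

    Density (per radian) is on the radial axis.  Passing two densities
    overlays them (e.g. a von Mises estimate against its Gaussian-linear
    baseline).  Writes SVG or PNG depending on the extension of ``out``;
    returns the figure for further inspection.
    """
    if isinstance(densities, DirectionDensity):
        densities = [densities]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    _polar_axis(ax, clockwise)
    for i, d in enumerate(densities):
        t, v = _closed(d.theta_grid_deg, d.values)
        label = labels[i] if labels else d.kernel.value
        ax.plot(t, v, color=_KERNEL_COLORS.get(d.kernel.value), label=label)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1))
    ax.set_title("Saccade direction density (per radian)")
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    return fig


def plot_joint_heatmap(grid: JointDensityGrid, out, clockwise: bool = False, ax=None):
    """Polar heatmap of a joint (direction, amplitude) density with colorbar.

    The plotted matrix is exactly ``grid.values`` - no re-smoothing or
    interpolation beyond the cell fill.
    """
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    else:
        fig = ax.figure
    _polar_axis(ax, clockwise)
    # pcolormesh needs cell edges; extend the periodic theta grid by one step
    dtheta = grid.theta_grid_deg[1] - grid.theta_grid_deg[0]
    theta_edges = np.deg2rad(np.append(grid.theta_grid_deg, grid.theta_grid_deg[-1] + dtheta))
    dr = grid.dr
    r_edges = np.append(grid.r_grid, grid.r_grid[-1] + dr)
    mesh = ax.pcolormesh(theta_edges, r_edges, grid.values.T, shading="flat", cmap="viridis")
    fig.colorbar(mesh, ax=ax, label="density")
    ax.set_title(f"direction x amplitude ({grid.r_unit.value})")
    if own_fig:
        fig.savefig(out, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_raw_scatter(table: SaccadeTable, out=None, clockwise: bool = False, ax=None):
    """Polar scatter of raw saccades: one point per saccade at (direction, amplitude)."""
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    else:
        fig = ax.figure
    _polar_axis(ax, clockwise)
    ax.scatter(
        np.deg2rad(table.directions_deg), table.amplitudes, s=6, alpha=0.5, color="tab:purple"
    )
    ax.set_title(f"raw saccades (n={len(table)})")
    if own_fig and out is not None:
        fig.savefig(out, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_joint_panels(
    mixed: JointDensityGrid,
    table: SaccadeTable,
    gaussian_only: JointDensityGrid,
    out,
    clockwise: bool = False,
):
    """Side-by-side panels: mixed KDE, raw scatter, Gaussian-only KDE."""
    fig, axes = plt.subplots(
        1, 3, subplot_kw={"projection": "polar"}, figsize=(17, 6)
    )
    plot_joint_heatmap(mixed, None, clockwise=clockwise, ax=axes[0])
    axes[0].set_title("(a) mixed KDE")
    plot_raw_scatter(table, None, clockwise=clockwise, ax=axes[1])
    axes[1].set_title("(b) raw saccades")
    plot_joint_heatmap(gaussian_only, None, clockwise=clockwise, ax=axes[2])
    axes[2].set_title("(c) Gaussian-only KDE")
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    return fig


def plot_histogram_polar(
    hist: HistogramResult, out, polyline: bool = False, clockwise: bool = False
):
    """Polar bar chart of a direction histogram.

    With ``polyline=True`` the legacy bin-center connecting line is overlaid
    and labelled as such: it implies values between bins that the data do
    not contain, which is exactly why the KDE display replaced it.
    """
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    _polar_axis(ax, clockwise)
    centers = np.deg2rad(hist.bin_centers_deg())
    width = np.deg2rad(hist.bin_edges_deg[1] - hist.bin_edges_deg[0])
    ax.bar(centers, hist.counts, width=width, alpha=0.6, edgecolor="k")
    if polyline:
        verts = bin_center_polyline(hist)
        t = np.deg2rad([v[0] for v in verts])
        r = [v[1] for v in verts]
        ax.plot(t, r, "r.-", label="bin-center polyline (legacy)")
        ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1))
    ax.set_title(f"direction histogram ({hist.mode})")
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    return fig
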