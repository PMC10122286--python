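"""Figure helpers: tessellation maps, probability heatmaps, cohort plots."""

from __future__ import annotations

from .gam import ProbabilitySurface
from .geometry import SectionGeometry
from .section_io import FiberSection

__all__ = [
    "plot_tessellation",
    "plot_triangulation",
    "plot_probability_surface",
    "plot_param_scatter",
    "plot_param_boxplots",
]


def _get_ax(ax):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    return ax


def _type_colors(types):
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap("tab10")
    return {t: cmap(i % 10) for i, t in enumerate(types)}


def plot_tessellation(geometry: SectionGeometry, section: FiberSection, ax=None):
    """Voronoi cells colored by fiber type."""
    ax = _get_ax(ax)
    colors = _type_colors(section.types)
    for i, cell in enumerate(geometry.cells):
        xs, ys = cell.exterior.xy
        ax.fill(xs, ys, color=colors[section.type_label[i]], ec="white", lw=0.2)
    bx, by = geometry.boundary.exterior.xy
    ax.plot(bx, by, color="black", lw=0.8)
    ax.set_aspect("equal")
    _type_legend(ax, colors)
    return ax


def plot_triangulation(network, section: FiberSection, ax=None):
    """Neighbor network edges with type-colored fiber centroids."""
    ax = _get_ax(ax)
    coords = section.coords
    segs = coords[network.edges]  # (m, 2, 2)
    from matplotlib.collections import LineCollection

    ax.add_collection(LineCollection(segs, colors="0.7", linewidths=0.4))
    colors = _type_colors(section.types)
    for t in section.types:
        m = section.type_label == t
        ax.scatter(coords[m, 0], coords[m, 1], s=6, color=colors[t], label=t)
    ax.set_aspect("equal")
    ax.legend(fontsize="small", markerscale=2)
    return ax


def _type_legend(ax, colors):
    from matplotlib.patches import Patch

    ax.legend(handles=[Patch(color=c, label=t) for t, c in colors.items()],
              fontsize="small")


def plot_probability_surface(surface: ProbabilitySurface, section: FiberSection | None = None,
                             ax=None, title: str | None = None):
    """Heatmap of a type-probability surface with optional fiber overlay."""
    ax = _get_ax(ax)
    pc = ax.pcolormesh(surface.grid_x, surface.grid_y, surface.prob,
                       vmin=0, vmax=1, cmap="viridis", shading="auto")
    ax.figure.colorbar(pc, ax=ax, label="probability")
    if section is not None:
        ax.scatter(section.x, section.y, s=2, c="white", alpha=0.25)
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    return ax


def plot_param_scatter(fit_table, ax=None):
    """Per-section (alpha, beta) estimates colored by group."""
    ax = _get_ax(ax)
    for g, sub in fit_table.groupby("group"):
        ax.scatter(sub["alpha"], sub["beta"], label=str(g))
    ax.axhline(0, color="0.8", lw=0.8)
    ax.set_xlabel(r"$\hat\alpha$")
    ax.set_ylabel(r"$\hat\beta$")
    ax.legend()
    return ax


def plot_param_boxplots(fit_table, axes=None):
    """Side-by-side boxplots of alpha and beta estimates per group."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(8, 4))
    groups = sorted(fit_table["group"].unique())
    for ax, param in zip(axes, ("alpha", "beta")):
        data = [fit_table.loc[fit_table["group"] == g, param] for g in groups]
        ax.boxplot(data, tick_labels=[str(g) for g in groups])
        ax.set_title(rf"$\hat\{param}$")
    return axes
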