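"""Triangular surface plots.

Each admissible window is drawn as one marker: abscissa = the window's
median sorting-variable value (or its center quantile alpha), ordinate =
the fraction 2*beta of the population included, color = the correlation
coefficient on a diverging scale anchored to [-1, 1] (neutral at 0).
Windows whose correlation is not significant at the chosen threshold are
filled white; windows with too few observations for a valid estimate are
omitted entirely.  The apex of the triangle is always the global
correlation of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe; no-op if a GUI backend is active

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import Normalize

from .mca import MCASurface

__all__ = ["PlotOptions", "RenderResult", "render", "summarize_regions"]

_FORMATS = ("png", "pdf", "svg")


@dataclass(frozen=True)
class PlotOptions:
    """Rendering options for a surface plot.

    ``color_scale`` must be a diverging matplotlib colormap name; it is
    always normalized to [-1, 1] so that 0 maps to the neutral midpoint.
    The default ``"RdBu_r"`` paints negative correlations blue and
    positive red; pass ``"RdBu"`` to flip the orientation.
    """

    color_scale: str = "RdBu_r"
    p_threshold: float = 0.05
    abscissa_mode: Literal["median_value", "quantile"] = "median_value"
    annotate_regions: bool = False
    output_format: Literal["png", "pdf", "svg"] | None = None  # None: from extension


@dataclass
class RenderResult:
    """What was drawn: the output path plus one row per plotted marker."""

    path: Path
    drawn: pd.DataFrame  # columns: alpha, beta, x, y, coefficient, significant


def _marker_edge(ax, resolution: int, x_span: float) -> float:
    """Square marker area (points^2) tiling a grid of pitch x_span/R."""
    fig = ax.figure
    bbox = ax.get_window_extent(renderer=fig.canvas.get_renderer())
    width_pts = bbox.width * 72.0 / fig.dpi
    return (0.95 * width_pts / max(resolution, 1)) ** 2


def render(
    surface: MCASurface,
    options: PlotOptions | None = None,
    destination=None,
    *,
    data: pd.DataFrame | None = None,
    ax=None,
) -> RenderResult:
    """Render ``surface`` to ``destination`` (PNG/PDF/SVG by extension).

    When ``data`` is given, a companion scatter plot of the analyzed
    pair (colored by the sorting variable) is drawn alongside the
    triangle.  Returns a :class:`RenderResult` whose ``drawn`` table
    lists every marker (position, color value, significance) — identical
    inputs yield identical tables.
    """
    options = options or PlotOptions()
    if not surface.cells:
        raise ValueError("cannot render an empty surface")
    cells = [c for c in surface.cells if c.estimate.valid]
    if destination is None and ax is None:
        raise ValueError("destination (or ax) required")

    rows = []
    for c in sorted(cells, key=lambda c: (-c.beta, c.alpha)):
        x = c.median_sorter if options.abscissa_mode == "median_value" else c.alpha
        rows.append(
            {
                "alpha": c.alpha,
                "beta": c.beta,
                "x": x,
                "y": 2 * c.beta,
                "n": c.n,
                "coefficient": c.estimate.coefficient,
                "significant": c.significant(options.p_threshold),
            }
        )
    drawn = pd.DataFrame(
        rows,
        columns=["alpha", "beta", "x", "y", "n", "coefficient", "significant"],
    )

    own_fig = ax is None
    if own_fig:
        if data is not None:
            fig, (ax, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        else:
            fig, ax = plt.subplots(figsize=(5, 4))
            ax2 = None
    else:
        fig, ax2 = ax.figure, None

    norm = Normalize(-1.0, 1.0)
    cmap = plt.get_cmap(options.color_scale)
    if len(drawn):
        colors = np.array([
            cmap(norm(c)) if sig else (1.0, 1.0, 1.0, 1.0)
            for c, sig in zip(drawn["coefficient"], drawn["significant"])
        ])
        size = _marker_edge(ax, surface.resolution, 1.0)
        ax.scatter(
            drawn["x"], drawn["y"], c=colors, marker="s", s=size,
            edgecolors="0.8", linewidths=0.2,
        )
    ax.set_ylim(0, 1.05)
    ax.set_xlabel(
        f"median {surface.sorting_variable}"
        if options.abscissa_mode == "median_value"
        else f"{surface.sorting_variable} quantile (alpha)"
    )
    ax.set_ylabel("fraction of population (2*beta)")
    ax.set_title(
        f"{surface.pair[0]} vs {surface.pair[1]} sorted by "
        f"{surface.sorting_variable} (R={surface.resolution}, {surface.method})"
    )
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, label="correlation")

    if options.annotate_regions:
        for reg in summarize_regions(surface):
            a = 0.5 * (reg["alpha_range"][0] + reg["alpha_range"][1])
            b = reg["beta_range"][1]
            xpos = a if options.abscissa_mode == "quantile" else np.interp(
                a, drawn["alpha"], drawn["x"]
            )
            ax.annotate(
                f"{reg['sign']} ({reg['n_cells']})", (xpos, 2 * b),
                fontsize=8, ha="center",
            )

    if ax2 is not None and data is not None:
        a, b = surface.pair
        sc = ax2.scatter(
            data[a], data[b], c=data[surface.sorting_variable],
            s=12, cmap="viridis",
        )
        ax2.set_xlabel(a)
        ax2.set_ylabel(b)
        fig.colorbar(sc, ax=ax2, label=surface.sorting_variable)

    path = Path(destination) if destination is not None else Path("<axes>")
    if destination is not None:
        fmt = options.output_format or (path.suffix.lstrip(".").lower() or "png")
        if fmt not in _FORMATS:
            raise ValueError(f"unsupported output format {fmt!r}; use {_FORMATS}")
        if not path.suffix:
            path = path.with_suffix("." + fmt)
        fig.savefig(path, format=fmt, dpi=150, bbox_inches="tight")
        if own_fig:
            plt.close(fig)
    return RenderResult(path=path, drawn=drawn)


def _neighbors(c1, c2, resolution: int) -> bool:
    """4-neighbor contiguity on the triangular lattice (apex half-offset ok)."""
    step = 1.0 / resolution
    tol = 1e-9
    da = abs(c1.alpha - c2.alpha)
    db = abs(c1.beta - c2.beta)
    same_row = db < tol
    if same_row:
        return abs(da - step) < tol
    # consecutive beta levels are step apart, except apex at step/2
    if db > step + tol:
        return False
    return da < step - tol


def summarize_regions(surface: MCASurface) -> list[dict]:
    """Connected same-sign significant regions of the surface.

    Cells are grouped by coefficient sign over 4-neighbor contiguity on
    the (alpha, beta) lattice (the apex row, offset by half a step,
    neighbors the row below it).  Each region is reported with its sign,
    cell count and alpha/beta extent; regions are ordered largest first,
    ties by alpha then beta.
    """
    sig = [
        c for c in surface.cells
        if c.significant(surface.p_threshold) and c.estimate.coefficient != 0
    ]
    unassigned = set(range(len(sig)))
    regions = []
    while unassigned:
        seed_idx = min(unassigned)
        sign = np.sign(sig[seed_idx].estimate.coefficient)
        stack, comp = [seed_idx], {seed_idx}
        unassigned.discard(seed_idx)
        while stack:
            i = stack.pop()
            for j in list(unassigned):
                if (
                    np.sign(sig[j].estimate.coefficient) == sign
                    and _neighbors(sig[i], sig[j], surface.resolution)
                ):
                    unassigned.discard(j)
                    comp.add(j)
                    stack.append(j)
        cells = [sig[i] for i in comp]
        regions.append(
            {
                "sign": "positive" if sign > 0 else "negative",
                "n_cells": len(cells),
                "alpha_range": (
                    min(c.alpha for c in cells), max(c.alpha for c in cells)
                ),
                "beta_range": (
                    min(c.beta for c in cells), max(c.beta for c in cells)
                ),
            }
        )
    regions.sort(key=lambda r: (-r["n_cells"], r["alpha_range"], r["beta_range"]))
    return regions
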