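"""Parametric microplot grids: generation, numbering, margin trimming, Shapefile I/O.

A microplot grid is defined headlessly by an anchor point, a rotation angle,
plot rectangle dimensions, row/column counts, and gaps — the scriptable
equivalent of drawing a rotated rectangular grid over the orthomosaic.  In
the grid's local frame, plot width runs along local x and plot length along
local y; plot (r, c) has its lower-left corner at
``(c*(plot_width+col_gap), r*(plot_length+row_gap))``, after which the whole
layout is rotated about the anchor and translated to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from plotpheno import _shapefile
from plotpheno.errors import ShapefileError

NUMBERING_SCHEMES = ("row_major", "column_major", "serpentine_rows")


@dataclass(frozen=True)
class GridSpec:
    anchor_x: float
    anchor_y: float
    angle: float  # degrees counterclockwise from east
    plot_length: float  # meters, along local y
    plot_width: float  # meters, along local x
    n_rows: int
    n_cols: int
    row_gap: float = 0.0
    col_gap: float = 0.0
    numbering: str = "row_major"
    start_number: int = 1

    def __post_init__(self) -> None:
        if self.plot_length <= 0 or self.plot_width <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid counts must be >= 1")
        if self.row_gap < 0 or self.col_gap < 0:
            raise ValueError("gaps must be >= 0")
        if self.numbering not in NUMBERING_SCHEMES:
            raise ValueError(f"unknown numbering scheme: {self.numbering!r}")


@dataclass(frozen=True)
class Microplot:
    """A numbered rotated-rectangle plot polygon in world coordinates.

    ``polygon`` is the 4-vertex open ring; vertex 0 -> 1 runs along the plot
    width, vertex 1 -> 2 along the plot length.  ``row``/``col`` record the
    grid position when the plot came from :func:`generate_grid`.
    """

    plot_id: int
    polygon: tuple  # ((x, y), ...) 4 vertices
    row: int | None = None
    col: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.polygon, dtype=float)
        if p.shape != (4, 2):
            raise ValueError("microplot polygon must have exactly 4 vertices")
        sides = np.roll(p, -1, axis=0) - p
        lengths = np.hypot(sides[:, 0], sides[:, 1])
        if abs(lengths[0] - lengths[2]) > 1e-9 or abs(lengths[1] - lengths[3]) > 1e-9:
            raise ValueError("opposite sides of a microplot must be equal")
        for i in range(4):
            if abs(np.dot(sides[i], sides[(i + 1) % 4])) > 1e-9 * max(1.0, lengths[i] * lengths[(i + 1) % 4]):
                raise ValueError("microplot corners must be right angles")

    @property
    def center(self) -> tuple[float, float]:
        p = np.asarray(self.polygon, dtype=float)
        return float(p[:, 0].mean()), float(p[:, 1].mean())

    @property
    def width(self) -> float:
        p = np.asarray(self.polygon, dtype=float)
        return float(np.hypot(*(p[1] - p[0])))

    @property
    def length(self) -> float:
        p = np.asarray(self.polygon, dtype=float)
        return float(np.hypot(*(p[2] - p[1])))

    def area(self) -> float:
        """Shoelace area of the plot polygon (m^2)."""
        p = np.asarray(self.polygon, dtype=float)
        x, y = p[:, 0], p[:, 1]
        return abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2.0


def _assign_id(spec: GridSpec, r: int, c: int) -> int:
    if spec.numbering == "row_major":
        k = r * spec.n_cols + c
    elif spec.numbering == "column_major":
        k = c * spec.n_rows + r
    else:  # serpentine_rows
        k = r * spec.n_cols + (c if r % 2 == 0 else spec.n_cols - 1 - c)
    return spec.start_number + k


def generate_grid(spec: GridSpec) -> list[Microplot]:
    """Lay out ``n_rows x n_cols`` rotated rectangular plots.

    Plots are returned in row-major geometric order; ids follow the spec's
    numbering scheme starting at ``start_number``.
    """
    theta = math.radians(spec.angle % 360.0)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    plots = []
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            x0 = c * (spec.plot_width + spec.col_gap)
            y0 = r * (spec.plot_length + spec.row_gap)
            local = [
                (x0, y0),
                (x0 + spec.plot_width, y0),
                (x0 + spec.plot_width, y0 + spec.plot_length),
                (x0, y0 + spec.plot_length),
            ]
            world = tuple(
                (
                    spec.anchor_x + lx * cos_t - ly * sin_t,
                    spec.anchor_y + lx * sin_t + ly * cos_t,
                )
                for lx, ly in local
            )
            plots.append(Microplot(plot_id=_assign_id(spec, r, c), polygon=world, row=r, col=c))
    return plots


def renumber(plots: list[Microplot], numbering: str, start_number: int = 1) -> list[Microplot]:
    """Reassign plot ids by the given scheme; geometry untouched.

    Requires plots that carry their grid (row, col) position, i.e. plots
    produced by :func:`generate_grid`.
    """
    if numbering not in NUMBERING_SCHEMES:
        raise ValueError(f"unknown numbering scheme: {numbering!r}")
    if any(p.row is None or p.col is None for p in plots):
        raise ValueError("renumber requires plots with grid (row, col) positions")
    n_rows = max(p.row for p in plots) + 1
    n_cols = max(p.col for p in plots) + 1
    out = []
    for p in plots:
        if numbering == "row_major":
            k = p.row * n_cols + p.col
        elif numbering == "column_major":
            k = p.col * n_rows + p.row
        else:
            k = p.row * n_cols + (p.col if p.row % 2 == 0 else n_cols - 1 - p.col)
        out.append(replace(p, plot_id=start_number + k))
    return out


def trim_margin(plot: Microplot, fraction: float, side: str = "width") -> Microplot:
    """Shrink the plot to a concentric rectangle.

    The selected dimension(s) are scaled by ``(1 - fraction)`` about the
    plot center, so a total of ``fraction`` is removed, split equally
    between the two opposing edges.  ``side='width'`` (the default) trims
    across the plot's short axis — the edges where field machinery runs.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if side not in ("width", "length", "both"):
        raise ValueError(f"unknown side: {side!r}")
    if fraction == 0.0:
        return plot
    p = np.asarray(plot.polygon, dtype=float)
    center = p.mean(axis=0)
    u_w = p[1] - p[0]
    u_w = u_w / np.linalg.norm(u_w)
    u_l = p[2] - p[1]
    u_l = u_l / np.linalg.norm(u_l)
    s_w = 1.0 - fraction if side in ("width", "both") else 1.0
    s_l = 1.0 - fraction if side in ("length", "both") else 1.0
    rel = p - center
    new = center + (rel @ u_w)[:, None] * u_w * s_w + (rel @ u_l)[:, None] * u_l * s_l
    return replace(plot, polygon=tuple(map(tuple, new)))


def write_shapefile(plots: list[Microplot], path, crs_id: int | None = None) -> None:
    """Write plots as an ESRI polygon Shapefile with an integer plot_id field."""
    if not plots:
        raise ShapefileError("cannot write an empty plot list")
    _shapefile.write_polygons(
        path, [p.polygon for p in plots], [p.plot_id for p in plots], crs_id=crs_id
    )


def read_shapefile(path) -> list[Microplot]:
    """Read microplots back from a polygon Shapefile.

    Rings are returned counterclockwise starting at the stored first vertex
    (the exact inverse of :func:`write_shapefile` on files it wrote).  A
    missing plot_id attribute falls back to record order with a warning.
    """
    rings, ids, _ = _shapefile.read_polygons(path)
    plots = []
    for ring, pid in zip(rings, ids):
        if len(ring) >= 2 and ring[0] == ring[-1]:
            ring = ring[:-1]
        if len(ring) != 4:
            raise ShapefileError(
                f"record with {len(ring)} vertices is not a rectangular microplot"
            )
        if _shapefile._signed_area(ring) < 0:
            ring = [ring[0]] + ring[1:][::-1]
        plots.append(Microplot(plot_id=pid, polygon=tuple(ring)))
    return plots
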