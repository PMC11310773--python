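"""Synthetic field generator: raster pairs with known ground truth.

Emulates the inputs the pipeline consumes — an RGB orthomosaic and a DSM of
a sloped field carrying rectangular microplots — with every quantity the
pipeline estimates known by construction: the ground (or ridge-crest) base
plane, per-plot canopy height and cover fraction, and the vegetation pixel
mask.  Canopies are axis-aligned concentric rectangles or unions of
non-overlapping discs so true cover fractions are exact up to pixel
quantization.  Ridges have a triangular cross-profile running along the
plot rows, with crest lines placed exactly on pixel-center rows; on ridged
fields the canopy top sits at crest plane + canopy height (a flat canopy
top), so the true trimmed-maximum height above the crest base plane equals
the canopy height exactly.  Per-pixel Gaussian elevation noise is an
intentional simplification of photogrammetric error (no doming, no melt,
no spatial correlation).

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from plotpheno.baseplane import BasePlane
from plotpheno.errors import PlotOutsideRasterError
from plotpheno.geodata import (
    GeoGrid,
    GeoRasterPair,
    OrthoImage,
    SurfaceModel,
    pixels_in_polygon,
    write_dsm_geotiff,
    write_ortho_geotiff,
)
from plotpheno.microplots import GridSpec, Microplot, generate_grid, write_shapefile


@dataclass(frozen=True)
class RidgeSpec:
    """Triangular-profile ridging along the x axis (crest lines run east-west)."""

    spacing: float = 0.75  # meters between crests
    height: float = 0.15  # crest height above the ground plane, meters


@dataclass(frozen=True)
class FieldSpec:
    """Study conditions for one synthetic field.

    Defaults describe a small potato-like trial: a 10 m x 6 m field imaged
    at 2.5 cm GSD, one row of three 3 m x 2.25 m plots, a gently sloped
    ground plane, 5 mm elevation noise, 0.5 m canopies covering 30% of each
    plot, and crop/soil colors separated by ~12 channel standard deviations.
    """

    # raster grid
    n_cols: int = 400
    n_rows: int = 240
    pixel_size: float = 0.025
    origin_x: float = 500000.0
    origin_y: float = 4400000.0
    crs_id: int = 32654
    # ground
    ground_a: float = 0.01
    ground_b: float = -0.005
    ground_c: float = 100.0
    noise_sd: float = 0.005
    ridges: RidgeSpec | None = None
    # plots
    plots: GridSpec = field(
        default_factory=lambda: GridSpec(
            anchor_x=500001.0,
            anchor_y=4399995.5,
            angle=0.0,
            plot_length=3.0,
            plot_width=2.25,
            n_rows=1,
            n_cols=3,
            col_gap=0.5,
        )
    )
    # per-plot canopy truth (scalars apply to every plot)
    canopy_height: float = 0.5
    cover_fraction: float = 0.30
    canopy_shape: str = "rectangle"  # or "discs"
    # colors (8-bit means and channel sd)
    crop_color: tuple = (60, 140, 50)
    soil_color: tuple = (150, 110, 80)
    color_sd: float = 8.0
    seed: int = 17

    def __post_init__(self) -> None:
        if not 0.0 <= self.cover_fraction <= 1.0:
            raise ValueError("cover_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.canopy_shape not in ("rectangle", "discs"):
            raise ValueError(f"unknown canopy shape: {self.canopy_shape!r}")
        sep = math.dist(self.crop_color, self.soil_color)
        if self.color_sd > 0 and sep < 6 * self.color_sd:
            raise ValueError(
                f"crop/soil color mean separation {sep:.1f} < 6 sd ({6 * self.color_sd:.1f})"
            )

    @property
    def grid(self) -> GeoGrid:
        return GeoGrid(
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            pixel_size_x=self.pixel_size,
            pixel_size_y=self.pixel_size,
            n_cols=self.n_cols,
            n_rows=self.n_rows,
            crs_id=self.crs_id,
        )


@dataclass
class GroundTruth:
    """Everything the pipeline should recover, known by construction."""

    base_plane: BasePlane  # ground plane, or crest plane on ridged fields
    plot_truth: list  # per plot: {plot_id, canopy_height, cover_fraction, cover_nominal}
    vegetation_mask: np.ndarray
    ground_rectangles: list  # bare-ground rectangles suitable for the rectangle method
    crest_lines: list  # (p1, p2, half_width) crest segments for the line method

    def to_dict(self) -> dict:
        return {
            "base_plane": self.base_plane.to_dict(),
            "plot_truth": self.plot_truth,
            "n_vegetation_pixels": int(self.vegetation_mask.sum()),
            "ground_rectangles": [[list(v) for v in r] for r in self.ground_rectangles],
            "crest_lines": [
                {"p1": list(p1), "p2": list(p2), "half_width_m": hw}
                for p1, p2, hw in self.crest_lines
            ],
        }


def _canopy_polygons(plot: Microplot, spec: FieldSpec):
    """Closed-form canopy footprint(s) with area = cover_fraction * plot area."""
    p = np.asarray(plot.polygon, dtype=float)
    center = p.mean(axis=0)
    u_w = (p[1] - p[0]) / np.linalg.norm(p[1] - p[0])
    u_l = (p[2] - p[1]) / np.linalg.norm(p[2] - p[1])
    w, length = plot.width, plot.length
    if spec.cover_fraction == 0.0:
        return []
    if spec.canopy_shape == "rectangle":
        s = math.sqrt(spec.cover_fraction)
        hw, hl = s * w / 2.0, s * length / 2.0
        return [
            [
                tuple(center - hw * u_w - hl * u_l),
                tuple(center + hw * u_w - hl * u_l),
                tuple(center + hw * u_w + hl * u_l),
                tuple(center - hw * u_w + hl * u_l),
            ]
        ]
    # four non-overlapping discs at the quadrant centers
    area = spec.cover_fraction * w * length
    r = math.sqrt(area / (4.0 * math.pi))
    if 2.0 * r >= min(w, length) / 2.0:
        raise ValueError("cover_fraction too large for non-overlapping discs")
    polys = []
    for sw in (-0.25, 0.25):
        for sl in (-0.25, 0.25):
            c = center + sw * w * u_w + sl * length * u_l
            theta = np.linspace(0.0, 2.0 * math.pi, 64, endpoint=False)
            polys.append([tuple(c + r * np.array([math.cos(t), math.sin(t)])) for t in theta])
    return polys


def _ridge_profile(spec: FieldSpec) -> tuple[np.ndarray, list[int]]:
    """Per-row ridge elevation and the crest row indices.

    Crests are placed on pixel-center rows: period m = round(spacing / px)
    rows, crest at row offset m // 2 within each period.
    """
    m = max(2, round(spec.ridges.spacing / spec.pixel_size))
    offset = m // 2
    rows = np.arange(spec.n_rows)
    u = (rows - offset) % m
    d = np.minimum(u, m - u)
    profile = spec.ridges.height * np.maximum(0.0, 1.0 - 2.0 * d / m)
    crest_rows = [r for r in range(spec.n_rows) if (r - offset) % m == 0]
    return profile, crest_rows


def make_field(spec: FieldSpec, outdir=None):
    """Render the field: returns (GeoRasterPair, plots, GroundTruth).

    With ``outdir`` set, also writes ortho.tif, dsm.tif, plots.shp and
    truth.json there.
    """
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    plots = generate_grid(spec.plots)

    xmin, ymin, xmax, ymax = grid.extent()
    for plot in plots:
        p = np.asarray(plot.polygon)
        if (
            p[:, 0].min() < xmin
            or p[:, 0].max() > xmax
            or p[:, 1].min() < ymin
            or p[:, 1].max() > ymax
        ):
            raise PlotOutsideRasterError(f"plot {plot.plot_id} is not inside the field extent")

    cols = np.arange(grid.n_cols)
    rows = np.arange(grid.n_rows)
    X, Y = np.meshgrid(
        grid.origin_x + (cols + 0.5) * grid.pixel_size_x,
        grid.origin_y - (rows + 0.5) * grid.pixel_size_y,
    )
    ground = spec.ground_a * X + spec.ground_b * Y + spec.ground_c

    crest_lines: list = []
    ridge = np.zeros(grid.shape)
    crest_offset = 0.0
    if spec.ridges is not None:
        profile, crest_rows = _ridge_profile(spec)
        ridge = np.broadcast_to(profile[:, None], grid.shape).copy()
        crest_offset = spec.ridges.height
        hw = spec.pixel_size / 2.0
        for r in crest_rows:
            y = grid.origin_y - (r + 0.5) * grid.pixel_size_y
            crest_lines.append(((xmin + 0.1, y), (xmax - 0.1, y), hw))

    veg_mask = np.zeros(grid.shape, dtype=bool)
    plot_truth = []
    for plot in plots:
        plot_mask = pixels_in_polygon(grid, plot.polygon)
        canopy_mask = np.zeros(grid.shape, dtype=bool)
        for poly in _canopy_polygons(plot, spec):
            canopy_mask |= pixels_in_polygon(grid, poly)
        canopy_mask &= plot_mask
        veg_mask |= canopy_mask
        n_plot = int(plot_mask.sum())
        plot_truth.append(
            {
                "plot_id": plot.plot_id,
                "canopy_height": spec.canopy_height,
                "cover_nominal": spec.cover_fraction,
                "cover_fraction": (int(canopy_mask.sum()) / n_plot) if n_plot else 0.0,
            }
        )

    # canopy top is flat: crest plane + canopy height
    elevation = ground + ridge
    elevation[veg_mask] = (ground + crest_offset + spec.canopy_height)[veg_mask]
    if spec.noise_sd > 0:
        elevation = elevation + rng.normal(0.0, spec.noise_sd, grid.shape)

    rgb = np.empty(grid.shape + (3,))
    for ch in range(3):
        rgb[..., ch] = np.where(veg_mask, spec.crop_color[ch], spec.soil_color[ch])
    if spec.color_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.color_sd, rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    ortho = OrthoImage(grid=grid, red=rgb[..., 0], green=rgb[..., 1], blue=rgb[..., 2])
    dsm = SurfaceModel(grid=grid, elevation=elevation)
    pair = GeoRasterPair(ortho=ortho, dsm=dsm)

    base_plane = BasePlane(
        a=spec.ground_a,
        b=spec.ground_b,
        c=spec.ground_c + crest_offset,
        frame=spec.crs_id,
    )
    margin = 0.4
    axmin = float(min(np.asarray(p.polygon)[:, 0].min() for p in plots))
    axmax = float(max(np.asarray(p.polygon)[:, 0].max() for p in plots))
    ground_rectangles = [
        # left and right bare margins, spanning the field's full height
        [(xmin + 0.1, ymin + 0.1), (axmin - margin, ymin + 0.1),
         (axmin - margin, ymax - 0.1), (xmin + 0.1, ymax - 0.1)],
        [(axmax + margin, ymin + 0.1), (xmax - 0.1, ymin + 0.1),
         (xmax - 0.1, ymax - 0.1), (axmax + margin, ymax - 0.1)],
    ]
    truth = GroundTruth(
        base_plane=base_plane,
        plot_truth=plot_truth,
        vegetation_mask=veg_mask,
        ground_rectangles=ground_rectangles,
        crest_lines=crest_lines,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ortho_geotiff(outdir / "ortho.tif", ortho)
        write_dsm_geotiff(outdir / "dsm.tif", dsm)
        write_shapefile(plots, outdir / "plots.shp", crs_id=spec.crs_id)
        with open(outdir / "truth.json", "w") as f:
            json.dump(truth.to_dict(), f, indent=1)
    return pair, plots, truth


def make_training_samples(
    spec: FieldSpec, n_per_class: int = 200, path=None
) -> pd.DataFrame:
    """Labeled color samples standing in for mouse-marked pixels.

    Draws ``n_per_class`` 8-bit RGB samples per class from the spec's crop
    and soil color distributions; deterministic given the spec seed.
    Returns a ``class_label,r,g,b`` table and optionally writes it as CSV.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed + 1)
    frames = []
    for label, mean in (("crop", spec.crop_color), ("soil", spec.soil_color)):
        rgb = rng.normal(np.asarray(mean, float), spec.color_sd, size=(n_per_class, 3))
        rgb = np.clip(np.rint(rgb), 0, 255).astype(int)
        frames.append(
            pd.DataFrame(
                {"class_label": label, "r": rgb[:, 0], "g": rgb[:, 1], "b": rgb[:, 2]}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if path is not None:
        df.to_csv(path, index=False)
    return df
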