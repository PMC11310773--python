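"""Per-plot trait extraction: percentile heights, coverage, volume index.

HeightP (P in {100, 95, 90, 80}) is the maximum per-pixel height above the
base plane after discarding the ``ceil((1 - P/100) * N)`` tallest pixels —
Height100 is the plot's tallest point; the trimmed variants are robust to
localized reconstruction spikes.  Heights are computed over all valid
pixels of the (margin-trimmed) plot, not just vegetation pixels; negative
heights (pixels below the base plane) stay in the distribution since maxima
ignore them anyway.

The volume index is the vegetation-pixel height sum divided by the total
number of plot pixels — the average canopy height per unit ground area,
with units cm^3/cm^2 = cm.  Vegetation heights below the base plane
contribute zero so soil pits cannot subtract volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plotpheno.baseplane import BasePlane, height_above
from plotpheno.coverage import UNLABELED, CoverageModel, class_fractions, classify_pixels
from plotpheno.errors import NoValidPixelsError, PlotOutsideRasterError
from plotpheno.geodata import GeoRasterPair, pixel_center_mesh, pixels_in_polygon
from plotpheno.microplots import Microplot, trim_margin

HEIGHT_PERCENTILES = (100, 95, 90, 80)


@dataclass(frozen=True)
class HeightMetrics:
    """Trimmed-maximum canopy heights in meters; h100 >= h95 >= h90 >= h80."""

    h100: float
    h95: float
    h90: float
    h80: float

    def as_cm(self) -> tuple[float, float, float, float]:
        return tuple(h * 100.0 for h in (self.h100, self.h95, self.h90, self.h80))


@dataclass
class PlotTraits:
    plot_id: int
    capture_date: str
    heights: HeightMetrics
    class_fractions: dict[str, float] = field(default_factory=dict)
    coverage: float = 0.0
    volume_index: float = 0.0  # meters
    n_pixels_total: int = 0
    n_pixels_valid: int = 0


def height_metrics(heights) -> HeightMetrics:
    """Compute Height100/95/90/80 from per-pixel heights above the base plane.

    hP = max after discarding the ``ceil((1 - P/100) * N)`` largest values
    (ties: larger value first, then scan order — achieved by a stable
    descending sort).  Heights are not clipped; the input must be non-empty.
    """
    h = np.asarray(heights, dtype=float)
    h = h[np.isfinite(h)]
    n = h.size
    if n == 0:
        raise NoValidPixelsError("height_metrics requires at least one valid height")
    desc = np.sort(h)[::-1]
    values = {}
    for p in HEIGHT_PERCENTILES:
        k = -(-((100 - p) * n) // 100)  # ceil((1 - p/100) * n), exactly
        values[p] = float(desc[min(k, n - 1)])
    return HeightMetrics(h100=values[100], h95=values[95], h90=values[90], h80=values[80])


def volume_index(heights, vegetation_mask, plot_mask) -> float:
    """Vegetation height sum over the plot pixel count, in meters.

    ``heights`` is aligned with the masks (2-D) or with the flattened plot
    pixels; vegetation heights are clipped at zero before summing, and the
    denominator is the number of plot pixels.
    """
    plot_mask = np.asarray(plot_mask, dtype=bool)
    vegetation_mask = np.asarray(vegetation_mask, dtype=bool)
    n_plot = int(plot_mask.sum())
    if n_plot == 0:
        raise NoValidPixelsError("volume_index requires a non-empty plot mask")
    if (vegetation_mask & ~plot_mask).any():
        raise ValueError("vegetation_mask must be a subset of plot_mask")
    h = np.asarray(heights, dtype=float)
    veg_h = h[vegetation_mask]
    return float(np.clip(veg_h, 0.0, None).sum()) / n_plot


def analyze_plot(
    pair: GeoRasterPair,
    plot: Microplot,
    plane: BasePlane,
    model: CoverageModel | None = None,
    margin_fraction: float = 0.0,
    margin_side: str = "width",
    heights_on_vegetation_only: bool = False,
) -> PlotTraits:
    """Extract all traits for one microplot from one capture date.

    The plot is margin-trimmed, rasterized (pixel centers inside the
    polygon), heights above the base plane computed on valid pixels, pixels
    classified by the coverage model, and the three trait families
    assembled.  A pixel is valid when both the orthomosaic and DSM carry
    data there.  ``heights_on_vegetation_only`` restricts the height
    distribution to vegetation pixels (off by default: the standard metrics
    use every valid plot pixel).
    """
    trimmed = trim_margin(plot, margin_fraction, margin_side) if margin_fraction else plot
    grid = pair.ortho.grid
    mask = pixels_in_polygon(grid, trimmed.polygon)
    n_total = int(mask.sum())
    if n_total == 0:
        raise PlotOutsideRasterError(
            f"plot {plot.plot_id} does not cover any pixel of the raster"
        )
    valid = mask & pair.ortho.valid & pair.dsm.valid
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise NoValidPixelsError(f"plot {plot.plot_id} has no valid pixels")

    X, Y = pixel_center_mesh(grid)
    heights = np.full(grid.shape, np.nan)
    heights[valid] = height_above(plane, X[valid], Y[valid], pair.dsm.elevation[valid])

    fractions: dict[str, float] = {}
    coverage = 0.0
    veg_mask = np.zeros(grid.shape, dtype=bool)
    if model is not None:
        class_map = classify_pixels(model, pair.ortho, valid)
        fractions, coverage = class_fractions(
            class_map, model.classes, model.vegetation_classes
        )
        veg_idx = [model.classes.index(c) for c in model.vegetation_classes]
        if veg_idx:
            veg_mask = np.isin(class_map, veg_idx) & (class_map != UNLABELED)

    hm = height_metrics(heights[veg_mask] if heights_on_vegetation_only else heights[valid])
    vi = volume_index(heights=np.nan_to_num(heights), vegetation_mask=veg_mask, plot_mask=valid)
    return PlotTraits(
        plot_id=plot.plot_id,
        capture_date=pair.capture_date,
        heights=hm,
        class_fractions=fractions,
        coverage=coverage,
        volume_index=vi,
        n_pixels_total=n_total,
        n_pixels_valid=n_valid,
    )
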