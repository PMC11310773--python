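"""GeoTIFF raster I/O and world <-> pixel coordinate plumbing.

All rasters follow the north-up GeoTIFF convention: the geotransform origin
is the outer corner of the top-left pixel, world y decreases as the pixel
row index increases, and indices are 0-based ``(row, col)``.  Elevations and
ground sampling distances are in meters, which is why a projected (metric)
CRS is mandatory and a geographic (degree) CRS is a hard error.

GeoTIFF georeferencing is read and written through the standard tag set
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA) on top of
:mod:`tifffile`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

from plotpheno.errors import (
    DisjointExtentsError,
    GeographicCRSError,
    MissingCRSError,
    RasterReadError,
)

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024  # 1 = projected, 2 = geographic
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072

_DEFAULT_NODATA = -9999.0


def _looks_geographic(epsg: int) -> bool:
    # EPSG reserves 4000-4999 for geographic 2D CRSs (4326 = WGS 84 etc.).
    return 4000 <= epsg <= 4999


@dataclass(frozen=True)
class GeoGrid:
    """Affine north-up raster grid in a projected CRS.

    ``origin_x, origin_y`` are the world coordinates of the raster's
    top-left *corner*; ``pixel_size_x/y`` are positive ground sampling
    distances in meters per pixel (y increases downward in pixel space).
    """

    origin_x: float
    origin_y: float
    pixel_size_x: float
    pixel_size_y: float
    n_cols: int
    n_rows: int
    crs_id: int

    def __post_init__(self) -> None:
        if self.pixel_size_x <= 0 or self.pixel_size_y <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("raster dimensions must be >= 1")
        if _looks_geographic(self.crs_id):
            raise GeographicCRSError(
                f"EPSG:{self.crs_id} is a geographic (degree) CRS; "
                "a projected metric CRS is required"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint in world coords."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size_y,
            self.origin_x + self.n_cols * self.pixel_size_x,
            self.origin_y,
        )


def world_to_pixel(grid: GeoGrid, x, y) -> tuple:
    """Map world coordinates to the 0-based (row, col) of the containing pixel.

    Pixel footprints are half-open — ``[left, right)`` in x and
    ``(bottom, top]`` in y — so a point exactly on a shared edge belongs to
    the pixel with the larger index.  Indices may fall outside the raster;
    callers bound-check.
    """
    # 1e-9-pixel epsilon keeps decimal edge coordinates on the larger-index
    # side despite binary float representation error
    col = np.floor((np.asarray(x, dtype=float) - grid.origin_x) / grid.pixel_size_x + 1e-9)
    row = np.floor((grid.origin_y - np.asarray(y, dtype=float)) / grid.pixel_size_y + 1e-9)
    if np.ndim(col) == 0:
        return int(row), int(col)
    return row.astype(np.int64), col.astype(np.int64)


def pixel_to_world(grid: GeoGrid, row, col) -> tuple:
    """World coordinates of the center of pixel (row, col)."""
    x = grid.origin_x + (np.asarray(col, dtype=float) + 0.5) * grid.pixel_size_x
    y = grid.origin_y - (np.asarray(row, dtype=float) + 0.5) * grid.pixel_size_y
    if np.ndim(x) == 0:
        return float(x), float(y)
    return x, y


def pixel_center_mesh(grid: GeoGrid) -> tuple[np.ndarray, np.ndarray]:
    """(X, Y) world coordinates of every pixel center, each of shape (n_rows, n_cols)."""
    cols = np.arange(grid.n_cols)
    rows = np.arange(grid.n_rows)
    x = grid.origin_x + (cols + 0.5) * grid.pixel_size_x
    y = grid.origin_y - (rows + 0.5) * grid.pixel_size_y
    return np.meshgrid(x, y)


def pixels_in_polygon(grid: GeoGrid, polygon) -> np.ndarray:
    """Boolean mask of pixels whose *center* lies inside or on the polygon.

    ``polygon`` is a closed ring of (x, y) world vertices or a shapely
    Polygon.  A degenerate (zero-area) polygon yields an all-false mask with
    a warning rather than an error.
    """
    poly = polygon if isinstance(polygon, Polygon) else Polygon(polygon)
    mask = np.zeros(grid.shape, dtype=bool)
    if poly.area == 0:
        warnings.warn("degenerate (zero-area) polygon: empty pixel mask", stacklevel=2)
        return mask
    xmin, ymin, xmax, ymax = poly.bounds
    # candidate pixel block covering the polygon bbox (clipped to the raster)
    c0 = max(0, int(math.floor((xmin - grid.origin_x) / grid.pixel_size_x)))
    c1 = min(grid.n_cols, int(math.ceil((xmax - grid.origin_x) / grid.pixel_size_x)) + 1)
    r0 = max(0, int(math.floor((grid.origin_y - ymax) / grid.pixel_size_y)))
    r1 = min(grid.n_rows, int(math.ceil((grid.origin_y - ymin) / grid.pixel_size_y)) + 1)
    if c0 >= c1 or r0 >= r1:
        return mask
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    cx = grid.origin_x + (cols + 0.5) * grid.pixel_size_x
    cy = grid.origin_y - (rows + 0.5) * grid.pixel_size_y
    X, Y = np.meshgrid(cx, cy)
    inside = shapely.intersects_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    mask[r0:r1, c0:c1] = inside
    return mask


@dataclass
class OrthoImage:
    """RGB orthomosaic: uint8 bands plus a per-pixel validity mask."""

    grid: GeoGrid
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        for band in (self.red, self.green, self.blue, self.valid):
            if band.shape != self.grid.shape:
                raise ValueError("band dimensions must equal grid dimensions")

    def rgb_stack(self) -> np.ndarray:
        """(n_rows, n_cols, 3) uint8 array."""
        return np.stack([self.red, self.green, self.blue], axis=-1)


@dataclass
class SurfaceModel:
    """Single-band DSM: float elevation in meters above datum."""

    grid: GeoGrid
    elevation: np.ndarray
    nodata: float = _DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.elevation.shape != self.grid.shape:
            raise ValueError("elevation dimensions must equal grid dimensions")

    @property
    def valid(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.elevation) & (self.elevation != self.nodata)


@dataclass
class GeoRasterPair:
    """Co-registered orthomosaic + DSM sharing one grid."""

    ortho: OrthoImage
    dsm: SurfaceModel
    capture_date: str = ""

    def __post_init__(self) -> None:
        if self.ortho.grid != self.dsm.grid:
            raise ValueError("ortho and dsm must share one grid after loading")


# ---------------------------------------------------------------------------
# GeoTIFF read/write


def _geo_extratags(grid: GeoGrid, nodata: float | None = None) -> list:
    keys = [1, 1, 0, 2, _KEY_MODEL_TYPE, 0, 1, 1, _KEY_PROJECTED_CS, 0, 1, int(grid.crs_id)]
    tags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.pixel_size_x, grid.pixel_size_y, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0), True),
        (_TAG_GEOKEYS, "H", len(keys), tuple(keys), True),
    ]
    if nodata is not None:
        tags.append((_TAG_GDAL_NODATA, "s", 0, repr(float(nodata)), True))
    return tags


def write_ortho_geotiff(path, ortho: OrthoImage) -> None:
    """Write an 8-bit RGBA GeoTIFF (alpha carries the validity mask)."""
    alpha = np.where(ortho.valid, 255, 0).astype(np.uint8)
    data = np.dstack([ortho.rgb_stack(), alpha])
    tifffile.imwrite(
        str(path),
        data,
        photometric="rgb",
        extrasamples=["unassalpha"],
        extratags=_geo_extratags(ortho.grid),
    )


def write_dsm_geotiff(path, dsm: SurfaceModel) -> None:
    """Write a 32-bit float single-band GeoTIFF with a GDAL nodata tag."""
    data = np.where(dsm.valid, dsm.elevation, dsm.nodata).astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        extratags=_geo_extratags(dsm.grid, nodata=dsm.nodata),
    )


def _parse_geokeys(values) -> dict[int, int]:
    keys = {}
    n = values[3]
    for i in range(n):
        key_id, location, count, value = values[4 + 4 * i : 8 + 4 * i]
        if location == 0:
            keys[key_id] = value
    return keys


def _read_geotiff(path):
    """Return (array, GeoGrid, nodata) from a GeoTIFF file."""
    path = Path(path)
    if not path.exists():
        raise RasterReadError(f"file not found: {path}")
    def tag_value(tags, code):
        tag = tags.get(code)
        return None if tag is None else tag.value

    try:
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            data = page.asarray()
            scale = tag_value(page.tags, _TAG_PIXEL_SCALE)
            tiepoint = tag_value(page.tags, _TAG_TIEPOINT)
            geokeys = tag_value(page.tags, _TAG_GEOKEYS)
            nodata_tag = tag_value(page.tags, _TAG_GDAL_NODATA)
    except RasterReadError:
        raise
    except Exception as exc:  # malformed TIFF
        raise RasterReadError(f"cannot read {path}: {exc}") from exc
    if scale is None or tiepoint is None:
        raise RasterReadError(f"{path} has no affine geotransform (ModelPixelScale/Tiepoint)")
    if geokeys is None:
        raise MissingCRSError(f"{path} has no CRS tag (GeoKeyDirectory absent)")
    keys = _parse_geokeys(geokeys)
    model_type = keys.get(_KEY_MODEL_TYPE)
    if model_type == 2 or (_KEY_GEOGRAPHIC_CS in keys and _KEY_PROJECTED_CS not in keys):
        raise GeographicCRSError(f"{path} is georeferenced in a geographic (degree) CRS")
    crs_id = keys.get(_KEY_PROJECTED_CS)
    if crs_id is None:
        raise MissingCRSError(f"{path} has no projected CS geokey")
    sx, sy = float(scale[0]), float(scale[1])
    i, j, _, gx, gy, _ = (float(v) for v in tiepoint[:6])
    # tiepoint maps raster point (i, j) to world (gx, gy)
    origin_x = gx - i * sx
    origin_y = gy + j * sy
    n_rows, n_cols = data.shape[0], data.shape[1]
    grid = GeoGrid(origin_x, origin_y, sx, sy, n_cols, n_rows, int(crs_id))
    nodata = float(nodata_tag) if nodata_tag is not None else None
    return data, grid, nodata


def _resample_nearest(src: np.ndarray, src_grid: GeoGrid, dst_grid: GeoGrid, fill):
    """Nearest-neighbor lookup of src values at dst pixel centers."""
    X, Y = pixel_center_mesh(dst_grid)
    rows, cols = world_to_pixel(src_grid, X, Y)
    inside = (rows >= 0) & (rows < src_grid.n_rows) & (cols >= 0) & (cols < src_grid.n_cols)
    out = np.full(dst_grid.shape, fill, dtype=src.dtype)
    out[inside] = src[rows[inside], cols[inside]]
    return out


def read_raster_pair(ortho_path, dsm_path, capture_date: str = "") -> GeoRasterPair:
    """Read an orthomosaic + DSM GeoTIFF pair onto one common grid.

    When the grids differ, the DSM is resampled to the orthomosaic grid by
    nearest-neighbor (no elevations are invented); DSM pixels falling
    outside the source extent become nodata.
    """
    ortho_data, ortho_grid, _ = _read_geotiff(ortho_path)
    dsm_data, dsm_grid, dsm_nodata = _read_geotiff(dsm_path)
    if ortho_data.ndim != 3 or ortho_data.shape[2] < 3:
        raise RasterReadError(f"{ortho_path} is not a 3-band (or RGBA) orthomosaic")
    if dsm_data.ndim != 2:
        raise RasterReadError(f"{dsm_path} is not a single-band DSM")
    if ortho_grid.crs_id != dsm_grid.crs_id:
        raise RasterReadError(
            f"CRS mismatch: ortho EPSG:{ortho_grid.crs_id} vs dsm EPSG:{dsm_grid.crs_id}"
        )
    ox0, oy0, ox1, oy1 = ortho_grid.extent()
    dx0, dy0, dx1, dy1 = dsm_grid.extent()
    if ox0 >= dx1 or dx0 >= ox1 or oy0 >= dy1 or dy0 >= oy1:
        raise DisjointExtentsError("orthomosaic and DSM extents do not overlap")

    valid = (
        ortho_data[:, :, 3] > 0
        if ortho_data.shape[2] >= 4
        else np.ones(ortho_grid.shape, dtype=bool)
    )
    ortho = OrthoImage(
        grid=ortho_grid,
        red=ortho_data[:, :, 0],
        green=ortho_data[:, :, 1],
        blue=ortho_data[:, :, 2],
        valid=valid,
    )
    nodata = dsm_nodata if dsm_nodata is not None else _DEFAULT_NODATA
    dsm_data = dsm_data.astype(np.float64)
    if dsm_grid != ortho_grid:
        dsm_data = _resample_nearest(dsm_data, dsm_grid, ortho_grid, fill=nodata)
    dsm = SurfaceModel(grid=ortho_grid, elevation=dsm_data, nodata=nodata)
    return GeoRasterPair(ortho=ortho, dsm=dsm, capture_date=capture_date)
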