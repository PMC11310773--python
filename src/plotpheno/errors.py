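"""Named error types for the raster/vector contracts."""


class PlotPhenoError(Exception):
    """Base class for all package errors."""


class RasterReadError(PlotPhenoError):
    """File missing, unreadable, or not a GeoTIFF with an affine geotransform."""


class MissingCRSError(PlotPhenoError):
    """GeoTIFF carries no CRS tag (GeoKeyDirectory absent or without a CS key)."""


class GeographicCRSError(PlotPhenoError):
    """CRS is geographic (degrees); all computations require a projected, metric CRS."""


class DisjointExtentsError(PlotPhenoError):
    """Orthomosaic and DSM world extents do not overlap."""


class DegenerateFitError(PlotPhenoError):
    """Too few or collinear points for a plane fit."""


class ShapefileError(PlotPhenoError):
    """Shapefile is not a polygon file or is structurally invalid."""


class PlotOutsideRasterError(PlotPhenoError):
    """Microplot polygon does not intersect the raster extent."""


class NoValidPixelsError(PlotPhenoError):
    """No valid (non-nodata) pixels available for the requested statistic."""
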