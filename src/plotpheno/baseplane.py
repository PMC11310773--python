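"""Ground base-plane estimation from bare-ground rectangles or ridge crest lines.

Crop height is the vertical distance of a DSM pixel above an inferred
ground reference plane ``z = a*x + b*y + c`` in the projected (UTM-like)
frame.  The plane is fitted by least squares to DSM samples inside
user-designated bare-ground regions, then shifted parallel downward so it
touches the lowest retained sample: the deepest ``exclude_fraction`` of
samples (by vertical distance *below* the plane) are discarded first so that
local pits and reconstruction noise cannot drag the reference down.  Because
the plane lives in absolute world coordinates it serves as one fixed
reference for every capture date of a time series.

For crops grown on ridges, the reference is the ridge crest: crest
centerlines are sampled within a half-width and a 1-D regression of
elevation on the along-line coordinate gives the plane's slope along the
line, while the slope normal to the line is pinned to zero — a thin strip
of samples cannot support a cross-slope estimate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon

from plotpheno.errors import DegenerateFitError, NoValidPixelsError
from plotpheno.geodata import SurfaceModel, pixel_center_mesh, pixels_in_polygon

DEFAULT_EXCLUDE_FRACTION = 0.05
LINE_PARALLEL_TOL_DEG = 5.0


@dataclass(frozen=True)
class BasePlane:
    """Ground reference plane ``z = a*x + b*y + c`` (meters, projected frame)."""

    a: float
    b: float
    c: float
    frame: int | None = None  # EPSG id of the projected CRS, when known

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.a, self.b, self.c))):
            raise ValueError("plane coefficients must be finite")

    def evaluate(self, x, y):
        return self.a * np.asarray(x, dtype=float) + self.b * np.asarray(y, dtype=float) + self.c

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "crs": self.frame}

    @classmethod
    def from_dict(cls, d: dict) -> "BasePlane":
        return cls(a=float(d["a"]), b=float(d["b"]), c=float(d["c"]), frame=d.get("crs"))

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=1)

    @classmethod
    def load(cls, path) -> "BasePlane":
        with open(path) as f:
            return cls.from_dict(json.load(f))


def fit_lsq_plane(points, frame: int | None = None) -> BasePlane:
    """Least-squares plane minimizing vertical residuals sum((z - a*x - b*y - c)^2).

    Requires at least 3 points that are not collinear in (x, y).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateFitError("plane fit requires >= 3 (x, y, z) points")
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    # center x/y for conditioning; rank check catches collinear configurations
    x0, y0 = pts[:, 0].mean(), pts[:, 1].mean()
    Ac = np.column_stack([pts[:, 0] - x0, pts[:, 1] - y0, np.ones(len(pts))])
    coef, _, rank, _ = np.linalg.lstsq(Ac, pts[:, 2], rcond=None)
    if rank < 3:
        raise DegenerateFitError("points are collinear/degenerate in (x, y)")
    a, b, c0 = coef
    return BasePlane(a=float(a), b=float(b), c=float(c0 - a * x0 - b * y0), frame=frame)


def shift_to_base(
    plane: BasePlane, points, exclude_fraction: float = DEFAULT_EXCLUDE_FRACTION
) -> BasePlane:
    """Shift the plane parallel down onto the deepest retained point.

    For each point the vertical downward distance ``d = plane(x, y) - z``
    (positive = point below the plane) is computed; the ``ceil(f * N)``
    deepest points are excluded (ties: deeper first, then input order) and
    the plane is lowered by the largest remaining d when that is positive.
    The plane is never shifted upward, and at least one point is always
    retained even when ``ceil(f * N) = N``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("shift_to_base requires a non-empty (x, y, z) point list")
    if not 0.0 <= exclude_fraction < 1.0:
        raise ValueError("exclude_fraction must be in [0, 1)")
    d = plane.evaluate(pts[:, 0], pts[:, 1]) - pts[:, 2]
    n = len(d)
    # round before ceil so 0.05 * 100 cannot spill to 6 through float error
    k = min(math.ceil(round(exclude_fraction * n, 9)), n - 1)
    order = np.argsort(-d, kind="stable")  # deepest first, input order breaks ties
    retained = order[k:]
    d_star = float(d[retained].max())
    if d_star <= 0:
        return plane
    return BasePlane(a=plane.a, b=plane.b, c=plane.c - d_star, frame=plane.frame)


def _dsm_points_in_polygons(dsm: SurfaceModel, polygons) -> np.ndarray:
    mask = np.zeros(dsm.grid.shape, dtype=bool)
    for poly in polygons:
        mask |= pixels_in_polygon(dsm.grid, poly)
    mask &= dsm.valid
    if not mask.any():
        raise NoValidPixelsError("no valid DSM pixels inside the ground regions")
    X, Y = pixel_center_mesh(dsm.grid)
    return np.column_stack([X[mask], Y[mask], dsm.elevation[mask]])


def base_plane_from_rectangles(
    dsm: SurfaceModel,
    rectangles,
    exclude_fraction: float = DEFAULT_EXCLUDE_FRACTION,
) -> BasePlane:
    """Base plane from bare-ground rectangles (rotated rectangles in world coords).

    Gathers every valid DSM pixel center inside the union of the rectangles,
    fits the least-squares plane and shifts it onto the deepest retained
    sample.  More rectangles, spread wider, constrain the slopes better.
    """
    pts = _dsm_points_in_polygons(dsm, rectangles)
    if len(pts) < 3:
        raise DegenerateFitError("fewer than 3 valid DSM pixels in the ground rectangles")
    plane = fit_lsq_plane(pts, frame=dsm.grid.crs_id)
    return shift_to_base(plane, pts, exclude_fraction)


def _line_direction(p1, p2) -> np.ndarray:
    v = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("line segment endpoints coincide")
    v = v / norm
    # canonicalize direction modulo 180 degrees
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    return v


def base_plane_from_lines(
    dsm: SurfaceModel,
    lines,
    exclude_fraction: float = DEFAULT_EXCLUDE_FRACTION,
) -> BasePlane:
    """Base plane from ridge crest centerlines.

    ``lines`` is a list of ``(p1, p2, half_width_m)`` segments (half_width
    defaults to one pixel when given as ``(p1, p2)``).  Segments must be
    parallel within 5 degrees; their mean direction defines the along-line
    axis.  Elevation is regressed on the along-line coordinate with one
    shared slope and a separate intercept per segment (crests share slope
    but not offset); intercepts are averaged.  The returned plane's gradient
    normal to the line is exactly zero.
    """
    default_hw = min(dsm.grid.pixel_size_x, dsm.grid.pixel_size_y)
    segs = []
    for line in lines:
        if len(line) == 3:
            p1, p2, hw = line
        else:
            (p1, p2), hw = line, default_hw
        segs.append((np.asarray(p1, float), np.asarray(p2, float), float(hw)))
    if not segs:
        raise ValueError("at least one line segment is required")

    dirs = [_line_direction(p1, p2) for p1, p2, _ in segs]
    ref = dirs[0]
    for v in dirs[1:]:
        ang = math.degrees(math.acos(np.clip(abs(np.dot(ref, v)), -1.0, 1.0)))
        if ang > LINE_PARALLEL_TOL_DEG:
            raise ValueError(
                f"line segments differ in direction by {ang:.1f} deg (> {LINE_PARALLEL_TOL_DEG})"
            )
    u = np.mean(dirs, axis=0)
    u = u / np.linalg.norm(u)

    sample_groups = []
    for p1, p2, hw in segs:
        strip = LineString([tuple(p1), tuple(p2)]).buffer(hw)
        pts = _dsm_points_in_polygons(dsm, [Polygon(strip.exterior.coords)])
        sample_groups.append(pts)

    # shared slope along u, per-segment intercept
    all_pts = np.vstack(sample_groups)
    t = all_pts[:, 0] * u[0] + all_pts[:, 1] * u[1]
    n_seg = len(sample_groups)
    design = np.zeros((len(all_pts), 1 + n_seg))
    design[:, 0] = t
    start = 0
    for j, pts in enumerate(sample_groups):
        design[start : start + len(pts), 1 + j] = 1.0
        start += len(pts)
    if len({round(v, 12) for v in t.tolist()}) < 2:
        raise DegenerateFitError("need >= 2 distinct sample stations along the line")
    coef, _, _, _ = np.linalg.lstsq(design, all_pts[:, 2], rcond=None)
    slope = float(coef[0])
    intercept = float(np.mean(coef[1:]))
    plane = BasePlane(
        a=slope * float(u[0]), b=slope * float(u[1]), c=intercept, frame=dsm.grid.crs_id
    )
    return shift_to_base(plane, all_pts, exclude_fraction)


def height_above(plane: BasePlane, x, y, z):
    """Vertical distance of point(s) above the plane: ``z - (a*x + b*y + c)``."""
    return np.asarray(z, dtype=float) - plane.evaluate(x, y)
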