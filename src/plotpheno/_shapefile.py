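"""Minimal ESRI Shapefile polygon codec (.shp/.shx/.dbf, optional .prj).

Covers exactly what the microplot workflow needs: polygon records
(shape type 5) with a single integer ``plot_id`` DBF attribute.  Outer rings
are written in clockwise vertex order as the Shapefile polygon spec
requires, regardless of the caller's ring orientation.
"""

from __future__ import annotations

import re
import struct
import warnings
from pathlib import Path

from plotpheno.errors import ShapefileError

SHAPE_POLYGON = 5


def _signed_area(ring) -> float:
    area = 0.0
    n = len(ring)
    for i in range(n):
        x0, y0 = ring[i]
        x1, y1 = ring[(i + 1) % n]
        area += x0 * y1 - x1 * y0
    return area / 2.0


def _ensure_clockwise(ring):
    return ring[::-1] if _signed_area(ring) > 0 else list(ring)


def _close_ring(ring):
    ring = list(ring)
    if ring[0] != ring[-1]:
        ring.append(ring[0])
    return ring


def write_polygons(path, polygons, ids, crs_id: int | None = None) -> None:
    """Write polygon rings with integer plot ids as a Shapefile.

    ``polygons`` is a list of rings, each a sequence of (x, y) vertices
    (closed or open; closed on write).  ``ids`` are the plot_id attribute
    values, one per polygon.
    """
    if not polygons:
        raise ShapefileError("cannot write an empty shapefile")
    if len(ids) != len(polygons):
        raise ShapefileError("one id per polygon required")
    path = Path(path)
    base = path.with_suffix("")

    records = []
    for ring in polygons:
        ring = _ensure_clockwise(_close_ring([(float(x), float(y)) for x, y in ring]))
        xs = [p[0] for p in ring]
        ys = [p[1] for p in ring]
        box = (min(xs), min(ys), max(xs), max(ys))
        content = struct.pack("<i", SHAPE_POLYGON)
        content += struct.pack("<4d", *box)
        content += struct.pack("<2i", 1, len(ring))  # numparts, numpoints
        content += struct.pack("<i", 0)  # part start index
        for x, y in ring:
            content += struct.pack("<2d", x, y)
        records.append((content, box))

    gxmin = min(b[0] for _, b in records)
    gymin = min(b[1] for _, b in records)
    gxmax = max(b[2] for _, b in records)
    gymax = max(b[3] for _, b in records)

    def header(file_len_words: int) -> bytes:
        h = struct.pack(">i", 9994) + b"\x00" * 20 + struct.pack(">i", file_len_words)
        h += struct.pack("<2i", 1000, SHAPE_POLYGON)
        h += struct.pack("<4d", gxmin, gymin, gxmax, gymax)
        h += struct.pack("<4d", 0.0, 0.0, 0.0, 0.0)
        return h

    shp_len = 50 + sum(4 + len(c) // 2 for c, _ in records)
    with open(base.with_suffix(".shp"), "wb") as f:
        f.write(header(shp_len))
        for i, (content, _) in enumerate(records):
            f.write(struct.pack(">2i", i + 1, len(content) // 2))
            f.write(content)

    with open(base.with_suffix(".shx"), "wb") as f:
        f.write(header(50 + 4 * len(records)))
        offset = 50
        for content, _ in records:
            f.write(struct.pack(">2i", offset, len(content) // 2))
            offset += 4 + len(content) // 2

    _write_dbf(base.with_suffix(".dbf"), ids)

    if crs_id is not None:
        wkt = (
            f'PROJCS["EPSG {crs_id}",GEOGCS["GCS_unknown",DATUM["D_unknown",'
            f'SPHEROID["unknown",6378137,298.257223563]],PRIMEM["Greenwich",0],'
            f'UNIT["Degree",0.0174532925199433]],PROJECTION["Transverse_Mercator"],'
            f'UNIT["Meter",1.0],AUTHORITY["EPSG","{crs_id}"]]'
        )
        base.with_suffix(".prj").write_text(wkt)


def _write_dbf(path, ids) -> None:
    n = len(ids)
    field_len = 18
    header_size = 32 + 32 + 1
    record_size = 1 + field_len
    head = struct.pack(
        "<4B I 2H 20x", 3, 99, 1, 1, n, header_size, record_size
    )
    fdesc = b"plot_id".ljust(11, b"\x00") + b"N" + b"\x00" * 4
    fdesc += struct.pack("<2B", field_len, 0) + b"\x00" * 14
    with open(path, "wb") as f:
        f.write(head)
        f.write(fdesc)
        f.write(b"\x0d")
        for pid in ids:
            f.write(b" " + str(int(pid)).rjust(field_len).encode("ascii"))
        f.write(b"\x1a")


def read_polygons(path):
    """Read (rings, ids, crs_id) back from a polygon Shapefile.

    Only the outer ring (first part) of each record is returned.  A missing
    or non-numeric plot_id attribute falls back to 1-based record order with
    a warning.
    """
    path = Path(path)
    base = path.with_suffix("")
    shp = base.with_suffix(".shp")
    if not shp.exists():
        raise ShapefileError(f"file not found: {shp}")
    buf = shp.read_bytes()
    if len(buf) < 100 or struct.unpack(">i", buf[:4])[0] != 9994:
        raise ShapefileError(f"{shp} is not a shapefile")
    shape_type = struct.unpack("<i", buf[32:36])[0]
    if shape_type != SHAPE_POLYGON:
        raise ShapefileError(
            f"{shp} is a non-polygon shapefile (shape type {shape_type})"
        )
    rings = []
    pos = 100
    while pos < len(buf):
        _, content_len = struct.unpack(">2i", buf[pos : pos + 8])
        pos += 8
        rec = buf[pos : pos + content_len * 2]
        pos += content_len * 2
        rtype = struct.unpack("<i", rec[:4])[0]
        if rtype == 0:  # null shape
            rings.append([])
            continue
        if rtype != SHAPE_POLYGON:
            raise ShapefileError(f"record shape type {rtype} is not polygon")
        numparts, numpoints = struct.unpack("<2i", rec[36:44])
        parts = struct.unpack(f"<{numparts}i", rec[44 : 44 + 4 * numparts])
        pts_off = 44 + 4 * numparts
        pts = struct.unpack(f"<{2 * numpoints}d", rec[pts_off : pts_off + 16 * numpoints])
        end = parts[1] if numparts > 1 else numpoints
        ring = [(pts[2 * i], pts[2 * i + 1]) for i in range(parts[0], end)]
        rings.append(ring)

    ids = _read_dbf_ids(base.with_suffix(".dbf"), len(rings))

    crs_id = None
    prj = base.with_suffix(".prj")
    if prj.exists():
        m = re.search(r'AUTHORITY\["EPSG","?(\d+)"?\]\s*\]?\s*$', prj.read_text())
        if m:
            crs_id = int(m.group(1))
    return rings, ids, crs_id


def _read_dbf_ids(path, n_records):
    fallback = list(range(1, n_records + 1))
    if not Path(path).exists():
        warnings.warn("missing .dbf: plot ids fall back to record order", stacklevel=3)
        return fallback
    buf = Path(path).read_bytes()
    n = struct.unpack("<I", buf[4:8])[0]
    header_size, record_size = struct.unpack("<2H", buf[8:12])
    fields = []
    pos = 32
    while pos < header_size - 1 and buf[pos] != 0x0D:
        name = buf[pos : pos + 11].split(b"\x00")[0].decode("ascii", "replace")
        ftype = chr(buf[pos + 11])
        flen = buf[pos + 16]
        fields.append((name, ftype, flen))
        pos += 32
    offset = 1
    id_field = None
    for name, ftype, flen in fields:
        if name.lower() == "plot_id" and ftype in ("N", "F"):
            id_field = (offset, flen)
            break
        offset += flen
    if id_field is None:
        warnings.warn(
            "no numeric plot_id attribute: plot ids fall back to record order",
            stacklevel=3,
        )
        return fallback
    off, flen = id_field
    ids = []
    for i in range(min(n, n_records)):
        rec = buf[header_size + i * record_size : header_size + (i + 1) * record_size]
        try:
            ids.append(int(float(rec[off : off + flen].decode("ascii").strip() or "0")))
        except ValueError:
            ids.append(i + 1)
    while len(ids) < n_records:
        ids.append(len(ids) + 1)
    return ids
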