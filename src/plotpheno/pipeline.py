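"""Batch processing of time-series raster pairs over all microplots.

A project is a serializable config: dated orthomosaic/DSM pairs, a plot
Shapefile, one base plane (serialized, or derived once from ground regions
on a reference date — the same plane is the absolute reference for every
date), per-date or shared coverage models, and margin-trim settings.
``run_batch`` produces one trait row per (date, plot) and ``write_csv``
emits the tidy RFC-4180 table.  Per-plot failures are logged and skipped so
one bad plot never aborts a season.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from plotpheno.baseplane import (
    BasePlane,
    base_plane_from_lines,
    base_plane_from_rectangles,
)
from plotpheno.coverage import CoverageModel
from plotpheno.errors import PlotPhenoError
from plotpheno.geodata import read_raster_pair
from plotpheno.microplots import read_shapefile
from plotpheno.traits import PlotTraits, analyze_plot

logger = logging.getLogger("plotpheno")

DEFAULT_SEED = 17


@dataclass
class DateEntry:
    capture_date: str
    ortho_path: str
    dsm_path: str
    model_path: str | None = None


@dataclass
class ProjectConfig:
    entries: list[DateEntry]
    plots_path: str
    baseplane: dict  # {"plane": {...}} or {"regions": {...}, "reference_date": d}
    default_model_path: str | None = None
    vegetation_classes: list[str] = field(default_factory=list)
    margin_fraction: float = 0.0
    margin_side: str = "width"
    output_path: str | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("project config lists no dates")
        dates = [e.capture_date for e in self.entries]
        if len(set(dates)) != len(dates):
            raise ValueError("capture dates must be unique")

    @classmethod
    def from_dict(cls, d: dict, base_dir=None) -> "ProjectConfig":
        base = Path(base_dir) if base_dir else Path(".")

        def resolve(p):
            return str(base / p) if p else p

        entries = [
            DateEntry(
                capture_date=str(e["capture_date"]),
                ortho_path=resolve(e["ortho_path"]),
                dsm_path=resolve(e["dsm_path"]),
                model_path=resolve(e.get("model_path")),
            )
            for e in d["entries"]
        ]
        return cls(
            entries=entries,
            plots_path=resolve(d["plots_path"]),
            baseplane=d["baseplane"],
            default_model_path=resolve(d.get("default_model_path")),
            vegetation_classes=list(d.get("vegetation_classes", [])),
            margin_fraction=float(d.get("margin_fraction", 0.0)),
            margin_side=d.get("margin_side", "width"),
            output_path=resolve(d.get("output_path")),
            seed=int(d.get("seed", DEFAULT_SEED)),
        )

    @classmethod
    def load(cls, path) -> "ProjectConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data, base_dir=path.parent)


@dataclass
class TraitsTable:
    rows: list[PlotTraits]
    class_labels: list[str]
    seed: int = DEFAULT_SEED


def _resolve_base_plane(config: ProjectConfig) -> BasePlane:
    spec = config.baseplane
    if "plane" in spec:
        return BasePlane.from_dict(spec["plane"])
    if "plane_path" in spec:
        return BasePlane.load(spec["plane_path"])
    if "regions" not in spec:
        raise ValueError("baseplane config needs 'plane', 'plane_path', or 'regions'")
    ref_date = spec.get("reference_date", config.entries[0].capture_date)
    entry = next((e for e in config.entries if e.capture_date == ref_date), None)
    if entry is None:
        raise ValueError(f"reference_date {ref_date!r} is not a configured capture date")
    pair = read_raster_pair(entry.ortho_path, entry.dsm_path, capture_date=ref_date)
    return base_plane_from_regions(pair.dsm, spec["regions"])


def base_plane_from_regions(dsm, regions: dict) -> BasePlane:
    """Compute the base plane from a ground-regions spec block.

    ``regions`` is ``{"rectangles": [ring, ...]}`` and/or
    ``{"lines": [{"p1": [x,y], "p2": [x,y], "half_width_m": w}, ...]}``;
    rectangle samples and line constraints cannot be mixed — lines win.
    """
    lines = regions.get("lines") or []
    rects = regions.get("rectangles") or []
    if lines:
        segs = [
            (tuple(ln["p1"]), tuple(ln["p2"]), float(ln.get("half_width_m", 0.0)) or None)
            for ln in lines
        ]
        segs = [(p1, p2, hw) if hw else (p1, p2) for p1, p2, hw in segs]
        return base_plane_from_lines(dsm, segs)
    if rects:
        return base_plane_from_rectangles(dsm, rects)
    raise ValueError("ground regions spec lists neither rectangles nor lines")


def _load_model(path, vegetation_classes) -> CoverageModel:
    model = CoverageModel.load(path)
    if vegetation_classes and not model.vegetation_classes:
        model.vegetation_classes = list(vegetation_classes)
    return model


def run_batch(config: ProjectConfig) -> TraitsTable:
    """Analyze every plot on every date; returns rows ordered (date, plot_id)."""
    plane = _resolve_base_plane(config)
    plots = sorted(read_shapefile(config.plots_path), key=lambda p: p.plot_id)
    rows: list[PlotTraits] = []
    class_labels: list[str] = []
    for entry in sorted(config.entries, key=lambda e: e.capture_date):
        try:
            pair = read_raster_pair(
                entry.ortho_path, entry.dsm_path, capture_date=entry.capture_date
            )
            model_path = entry.model_path or config.default_model_path
            model = (
                _load_model(model_path, config.vegetation_classes) if model_path else None
            )
        except (PlotPhenoError, OSError, ValueError) as exc:
            logger.error("date %s skipped: %s", entry.capture_date, exc)
            continue
        if model is not None and not class_labels:
            class_labels = list(model.classes)
        for plot in plots:
            try:
                rows.append(
                    analyze_plot(
                        pair,
                        plot,
                        plane,
                        model=model,
                        margin_fraction=config.margin_fraction,
                        margin_side=config.margin_side,
                    )
                )
            except PlotPhenoError as exc:
                logger.error(
                    "plot %s on %s skipped: %s", plot.plot_id, entry.capture_date, exc
                )
    return TraitsTable(rows=rows, class_labels=class_labels, seed=config.seed)


def write_csv(table: TraitsTable, path) -> None:
    """Write the tidy trait table: heights and volume index in cm (2 decimals),
    fractions in [0, 1] (4 decimals); RFC-4180 quoting; seed recorded in a
    leading comment line."""
    if not table.rows:
        raise ValueError("cannot write an empty traits table")
    header = [
        "date",
        "plot_id",
        "height100_cm",
        "height95_cm",
        "height90_cm",
        "height80_cm",
        "coverage",
        *[f"class_{c}_fraction" for c in table.class_labels],
        "volume_index_cm",
        "n_pixels_total",
        "n_pixels_valid",
    ]
    with open(path, "w", newline="", encoding="utf-8") as f:
        f.write(f"# seed={table.seed}\n")
        writer = csv.writer(f)
        writer.writerow(header)
        for row in table.rows:
            h = row.heights.as_cm()
            writer.writerow(
                [
                    row.capture_date,
                    row.plot_id,
                    *[f"{v:.2f}" for v in h],
                    f"{row.coverage:.4f}",
                    *[f"{row.class_fractions.get(c, 0.0):.4f}" for c in table.class_labels],
                    f"{row.volume_index * 100.0:.2f}",
                    row.n_pixels_total,
                    row.n_pixels_valid,
                ]
            )
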