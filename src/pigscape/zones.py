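"""Sub-district zones: raster membership, polygon form, GeoJSON round-trip.

Zones are used in two equivalent representations: a zone-id raster (one
integer id per grid cell, -1 outside any zone) and a set of shapely
polygons tagged with ``subdistrict_id``.  Conversion between them uses the
cell-center rule: a cell belongs to the zone whose polygon contains its
center, ties broken by the lowest zone id.
"""

from __future__ import annotations

import json

import numpy as np
import shapely
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union

from .raster import RasterGrid


def voronoi_zone_raster(template: RasterGrid, seed_points: np.ndarray) -> np.ndarray:
    """Partition the grid into discrete Voronoi cells of ``seed_points``.

    Each grid cell is assigned to the nearest seed (Euclidean distance
    between cell center and seed, ties to the lowest seed index), which
    yields irregular, administrative-unit-like zones that exactly
    partition the grid.
    """
    rows, cols = template.shape
    cs = template.cell_size_km
    x0, y0 = template.origin
    xs = x0 + np.arange(cols) * cs
    ys = y0 + np.arange(rows) * cs
    cx, cy = np.meshgrid(xs, ys)
    pts = np.asarray(seed_points, dtype=float)
    # distance stack (n_seeds, rows, cols); argmin takes the lowest index on ties
    d2 = (cx[None] - pts[:, 0, None, None]) ** 2 + (cy[None] - pts[:, 1, None, None]) ** 2
    return np.argmin(d2, axis=0).astype(np.int64)


def zone_polygons(zone_raster: np.ndarray, template: RasterGrid) -> dict[int, shapely.Geometry]:
    """Union the square footprints of each zone's cells into one polygon."""
    cs = template.cell_size_km
    x0, y0 = template.origin
    polys: dict[int, shapely.Geometry] = {}
    for zid in np.unique(zone_raster):
        if zid < 0:
            continue
        rr, cc = np.nonzero(zone_raster == zid)
        cells = [
            box(x0 + c * cs - cs / 2, y0 + r * cs - cs / 2,
                x0 + c * cs + cs / 2, y0 + r * cs + cs / 2)
            for r, c in zip(rr, cc)
        ]
        polys[int(zid)] = unary_union(cells)
    return polys


def rasterize_zones(polygons: dict[int, shapely.Geometry], template: RasterGrid) -> np.ndarray:
    """Zone-id raster from polygons by the cell-center rule.

    Ties (a center on a shared boundary) go to the lowest zone id; cells
    in no polygon get -1.
    """
    rows, cols = template.shape
    cs = template.cell_size_km
    x0, y0 = template.origin
    xs = x0 + np.arange(cols) * cs
    ys = y0 + np.arange(rows) * cs
    cx, cy = np.meshgrid(xs, ys)
    points = shapely.points(cx.ravel(), cy.ravel())
    out = np.full(rows * cols, -1, dtype=np.int64)
    for zid in sorted(polygons):
        geom = polygons[zid]
        hit = shapely.intersects(geom, points)
        unassigned = out == -1
        out[hit & unassigned] = zid
    return out.reshape(rows, cols)


def zone_areas_km2(zone_raster: np.ndarray, template: RasterGrid) -> dict[int, float]:
    ids, counts = np.unique(zone_raster[zone_raster >= 0], return_counts=True)
    return {int(z): float(n) * template.cell_area_km2 for z, n in zip(ids, counts)}


def write_geojson(path, polygons: dict[int, shapely.Geometry]) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"subdistrict_id": int(zid)},
            "geometry": mapping(polygons[zid]),
        }
        for zid in sorted(polygons)
    ]
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_geojson(path) -> dict[int, shapely.Geometry]:
    with open(path) as fh:
        doc = json.load(fh)
    return {
        int(f["properties"]["subdistrict_id"]): shape(f["geometry"])
        for f in doc["features"]
    }
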