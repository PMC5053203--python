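"""Predictor-layer engineering and zonal aggregation.

Builds the six-predictor stack used by the distribution models — travel
time to the capital, travel time to provincial capitals, rain-fed and
irrigated cropland proportions, elevation and human population density —
and averages it, together with the observed response densities from the
census, to sub-district units.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .raster import RasterGrid

log = logging.getLogger(__name__)

#: canonical layer names, in model column order
PREDICTOR_NAMES = (
    "travel_capital",
    "travel_province",
    "rainfed_crop",
    "irrigated_crop",
    "elevation",
    "human_density",
)

#: layers receiving the log10(x + 1) transform (the +1 offset keeps the
#: zero travel time at a point of interest, and zero density, finite)
LOG_TRANSFORMED = ("travel_capital", "travel_province", "elevation", "human_density")

RESPONSE_NAMES = (
    "native_pigs",
    "breeding_pigs",
    "fattening_pigs",
    "smallholders",
    "largescale_farms",
)

#: farm-count responses may be expressed per 10 km^2 instead of per km^2
FARM_RESPONSES = ("smallholders", "largescale_farms")


def focal_mean(r: RasterGrid, window_km: float) -> RasterGrid:
    """Moving-window mean over a square window of side ``window_km``.

    A cell's smoothed value is the mean of all valid cells whose centers
    fall within the window centered on it; cells whose window holds no
    valid neighbour keep the nodata sentinel.
    """
    if window_km < r.cell_size_km:
        raise ValueError("focal window must be at least one cell wide")
    radius = int(np.floor(window_km / (2.0 * r.cell_size_km) + 1e-9))
    valid = r.mask()
    vals = np.where(valid, r.values, 0.0)
    size = 2 * radius + 1
    sums = ndimage.uniform_filter(vals, size=size, mode="constant", cval=0.0) * size**2
    counts = ndimage.uniform_filter(valid.astype(float), size=size, mode="constant", cval=0.0) * size**2
    counts = np.rint(counts)
    out = np.full(r.shape, r.nodata, dtype=float)
    ok = counts > 0
    out[ok] = sums[ok] / counts[ok]
    return r.with_values(out)


def _snap_targets(r: RasterGrid, targets: np.ndarray) -> np.ndarray:
    """(x, y) points -> flat cell indices of the nearest cell center."""
    pts = np.atleast_2d(np.asarray(targets, dtype=float))
    rows, cols = r.shape
    x0, y0 = r.origin
    cc = np.rint((pts[:, 0] - x0) / r.cell_size_km).astype(int)
    rr = np.rint((pts[:, 1] - y0) / r.cell_size_km).astype(int)
    if ((rr < 0) | (rr >= rows) | (cc < 0) | (cc >= cols)).any():
        raise ValueError("target point falls outside the grid")
    return rr * cols + cc


def cost_distance(friction: RasterGrid, targets: np.ndarray) -> RasterGrid:
    """Accumulated least-cost travel time from every cell to its nearest target.

    The friction raster gives the time to traverse one km of a cell.
    Moves connect 8-neighbours; a step between adjacent cells costs the
    center-to-center distance (cell_size or cell_size * sqrt(2)) times the
    mean friction of the two cells.  Target cells are at cost zero.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.size == 0:
        raise ValueError("cost_distance needs at least one target point")
    valid = friction.mask()
    if (friction.values[valid] <= 0).any():
        raise ValueError("friction values must be strictly positive")
    rows, cols = friction.shape
    n = rows * cols
    cs = friction.cell_size_km
    fvals = friction.values

    src_list, dst_list, w_list = [], [], []
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    idx = np.arange(n).reshape(rows, cols)
    for dr, dc in offsets:
        r0, r1 = max(0, dr), rows + min(0, dr)
        c0, c1 = max(0, dc), cols + min(0, dc)
        a = idx[r0:r1, c0:c1]
        b = idx[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        ok = valid[r0:r1, c0:c1] & valid[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        dist = cs * np.hypot(dr, dc)
        w = dist * 0.5 * (fvals[r0:r1, c0:c1] + fvals[r0 - dr : r1 - dr, c0 - dc : c1 - dc])
        src_list.append(a[ok])
        dst_list.append(b[ok])
        w_list.append(w[ok])
    graph = sparse.csr_matrix(
        (np.concatenate(w_list), (np.concatenate(src_list), np.concatenate(dst_list))),
        shape=(n, n),
    )
    sources = _snap_targets(friction, targets)
    dists = dijkstra(graph, directed=False, indices=sources, min_only=True)
    out = np.full(n, friction.nodata, dtype=float)
    reachable = np.isfinite(dists)
    out[reachable] = dists[reachable]
    out[~valid.ravel()] = friction.nodata
    return friction.with_values(out.reshape(rows, cols))


def prepare_predictors(layers: dict[str, RasterGrid]) -> dict[str, RasterGrid]:
    """Apply the model-scale transforms to the six named layers.

    Travel times, elevation and human density become log10(x + 1);
    cropland proportions pass through unchanged.
    """
    missing = [name for name in PREDICTOR_NAMES if name not in layers]
    if missing:
        raise KeyError(f"missing predictor layer(s): {missing}")
    out: dict[str, RasterGrid] = {}
    for name in PREDICTOR_NAMES:
        r = layers[name]
        if name in LOG_TRANSFORMED:
            vals = np.array(r.values, dtype=float)
            m = r.mask()
            if (vals[m] < 0).any():
                raise ValueError(f"layer {name} has negative values; cannot log-transform")
            vals[m] = np.log10(vals[m] + 1.0)
            out[name] = r.with_values(vals)
        else:
            out[name] = r.with_values(r.values.copy())
    return out


def _scale_total(h: pd.Series) -> int:
    return int(h["boars"] + h["sows"] + h["piglets"] + h["fattening"] + h["native"])


def zonal_aggregate(
    stack: dict[str, RasterGrid],
    zone_raster: np.ndarray,
    census: pd.DataFrame,
    farms_per_10km2: bool = True,
) -> pd.DataFrame:
    """Aggregate predictors (means) and census responses (densities) per zone.

    Returns one row per sub-district with the six predictor means, the
    zone area, and the five observed response densities: head/km^2 for the
    pig types and farms/km^2 (or farms/10 km^2) for the two farm scales.
    Zones whose cells are all nodata for some predictor are dropped with a
    warning; zones with no census holders keep structural-zero densities.
    """
    missing = [name for name in PREDICTOR_NAMES if name not in stack]
    if missing:
        raise KeyError(f"missing predictor layer(s): {missing}")
    template = stack[PREDICTOR_NAMES[0]]
    zone_ids = np.unique(zone_raster[zone_raster >= 0])
    areas = {}
    for zid in zone_ids:
        ncells = int((zone_raster == zid).sum())
        if ncells == 0:
            raise ValueError(f"zone {zid} has zero area")
        areas[int(zid)] = ncells * template.cell_area_km2

    census_zones = set(census["subdistrict_id"].unique())
    unknown = census_zones - {int(z) for z in zone_ids}
    if unknown:
        raise ValueError(f"census references unknown sub-district ids: {sorted(unknown)}")

    rows = []
    dropped = []
    total = census["boars"] + census["sows"] + census["piglets"] + census["fattening"] + census["native"]
    heads = pd.DataFrame(
        {
            "subdistrict_id": census["subdistrict_id"],
            "native_pigs": census["native"],
            "breeding_pigs": census["boars"] + census["sows"] + census["piglets"],
            "fattening_pigs": census["fattening"],
            "smallholders": (total < 50).astype(int),
            "largescale_farms": (total >= 50).astype(int),
        }
    )
    sums = heads.groupby("subdistrict_id").sum()
    farm_factor = 10.0 if farms_per_10km2 else 1.0
    for zid in zone_ids:
        zid = int(zid)
        in_zone = zone_raster == zid
        row: dict[str, float] = {"zone_id": zid, "area_km2": areas[zid]}
        ok = True
        for name in PREDICTOR_NAMES:
            r = stack[name]
            cells = in_zone & r.mask()
            if not cells.any():
                ok = False
                break
            row[name] = float(r.values[cells].mean())
        if not ok:
            dropped.append(zid)
            continue
        zsum = sums.loc[zid] if zid in sums.index else None
        for resp in RESPONSE_NAMES:
            count = float(zsum[resp]) if zsum is not None else 0.0
            dens = count / areas[zid]
            if resp in FARM_RESPONSES:
                dens *= farm_factor
            row[resp] = dens
        rows.append(row)
    if dropped:
        log.warning("dropped %d zone(s) with no valid predictor cells: %s", len(dropped), dropped)
    return pd.DataFrame(rows).set_index("zone_id")
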