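"""Focal statistics, cost-distance accessibility and zonal aggregation,
checked against brute-force and graph-library oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pigscape.covariates import (
    PREDICTOR_NAMES,
    cost_distance,
    focal_mean,
    prepare_predictors,
    zonal_aggregate,
)
from pigscape.raster import RasterGrid

# ---------------------------------------------------------------------------
# focal mean


def brute_force_focal(values, radius):
    rows, cols = values.shape
    out = np.empty_like(values, dtype=float)
    for i in range(rows):
        for j in range(cols):
            acc = []
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if 0 <= i + di < rows and 0 <= j + dj < cols:
                        acc.append(values[i + di, j + dj])
            out[i, j] = np.mean(acc)
    return out


def test_focal_mean_of_constant_is_constant():
    r = RasterGrid(np.full((6, 7), 3.5))
    out = focal_mean(r, 3.0)
    assert np.allclose(out.values, 3.5)


def test_focal_mean_single_cell_window_is_identity(rng):
    r = RasterGrid(rng.normal(size=(5, 5)))
    out = focal_mean(r, r.cell_size_km)
    assert np.allclose(out.values, r.values)


def test_focal_mean_matches_nested_loop_oracle(rng):
    vals = rng.normal(size=(5, 5))
    out = focal_mean(RasterGrid(vals), 3.0)
    assert np.allclose(out.values, brute_force_focal(vals, 1))


def test_focal_mean_commutes_with_constant_shift(rng):
    vals = rng.normal(size=(8, 8))
    a = focal_mean(RasterGrid(vals + 2.5), 3.0).values
    b = focal_mean(RasterGrid(vals), 3.0).values + 2.5
    assert np.allclose(a, b)


def test_focal_mean_ignores_nodata_cells(rng):
    vals = rng.normal(size=(5, 5))
    vals[2, 2] = -9999.0
    out = focal_mean(RasterGrid(vals, nodata=-9999.0), 3.0)
    # neighbour of the hole: average over its valid neighbours only
    block = vals[0:3, 0:3].ravel().tolist()
    block.remove(-9999.0)
    assert out.values[1, 1] == pytest.approx(np.mean(block))


def test_focal_window_smaller_than_cell_rejected():
    with pytest.raises(ValueError):
        focal_mean(RasterGrid(np.ones((3, 3))), 0.5)


# ---------------------------------------------------------------------------
# cost distance


def graph_oracle(friction: RasterGrid, targets):
    """Textbook shortest path on the explicit 8-connected grid graph."""
    rows, cols = friction.shape
    cs = friction.cell_size_km
    g = nx.Graph()
    for i in range(rows):
        for j in range(cols):
            for di, dj in [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]:
                a, b = i + di, j + dj
                if 0 <= a < rows and 0 <= b < cols:
                    dist = cs * np.hypot(di, dj)
                    w = dist * 0.5 * (friction.values[i, j] + friction.values[a, b])
                    g.add_edge((i, j), (a, b), weight=w)
    out = np.full((rows, cols), np.inf)
    for t in targets:
        lengths = nx.single_source_dijkstra_path_length(g, t, weight="weight")
        for (i, j), d in lengths.items():
            out[i, j] = min(out[i, j], d)
    return out


def test_cost_distance_straight_line_on_uniform_friction():
    f = 2.5
    r = RasterGrid(np.full((5, 9), f))
    out = cost_distance(r, np.array([r.cell_center(2, 0)]))
    for k in range(9):
        assert out.values[2, k] == pytest.approx(k * r.cell_size_km * f)


def test_cost_distance_zero_at_targets(rng):
    r = RasterGrid(rng.uniform(0.5, 3.0, size=(6, 6)))
    targets = np.array([r.cell_center(1, 2), r.cell_center(4, 5)])
    out = cost_distance(r, targets)
    assert out.values[1, 2] == 0.0
    assert out.values[4, 5] == 0.0


def test_cost_distance_matches_graph_oracle(rng):
    r = RasterGrid(rng.uniform(0.2, 4.0, size=(6, 6)))
    cells = [(0, 0), (3, 4)]
    out = cost_distance(r, np.array([r.cell_center(*c) for c in cells]))
    assert np.allclose(out.values, graph_oracle(r, cells), atol=1e-9)


def test_cost_distance_extra_target_never_increases(rng):
    r = RasterGrid(rng.uniform(0.2, 4.0, size=(7, 7)))
    one = cost_distance(r, np.array([r.cell_center(0, 0)]))
    two = cost_distance(r, np.array([r.cell_center(0, 0), r.cell_center(6, 6)]))
    assert (two.values <= one.values + 1e-12).all()


def test_cost_distance_input_validation(rng):
    r = RasterGrid(rng.uniform(0.2, 4.0, size=(4, 4)))
    with pytest.raises(ValueError):
        cost_distance(r, np.empty((0, 2)))
    bad = RasterGrid(np.zeros((4, 4)))
    with pytest.raises(ValueError):
        cost_distance(bad, np.array([bad.cell_center(0, 0)]))
    with pytest.raises(ValueError):
        cost_distance(r, np.array([[99.0, 99.0]]))


# ---------------------------------------------------------------------------
# predictor transforms


def _named_stack(rng, shape=(6, 6)):
    layers = {}
    for name in PREDICTOR_NAMES:
        if name.endswith("_crop"):
            layers[name] = RasterGrid(rng.uniform(0, 1, size=shape))
        else:
            layers[name] = RasterGrid(rng.uniform(0, 500, size=shape))
    return layers


def test_prepare_predictors_log_transform_and_passthrough(rng):
    layers = _named_stack(rng)
    layers["travel_capital"].values[0, 0] = 0.0
    layers["rainfed_crop"].values[1, 1] = 0.37
    stack = prepare_predictors(layers)
    assert stack["travel_capital"].values[0, 0] == pytest.approx(0.0)  # log10(0+1)
    assert stack["rainfed_crop"].values[1, 1] == pytest.approx(0.37)
    assert np.allclose(stack["elevation"].values, np.log10(layers["elevation"].values + 1))


def test_prepare_predictors_preserves_rank_order(rng):
    layers = _named_stack(rng)
    stack = prepare_predictors(layers)
    for name in ("travel_capital", "elevation", "human_density"):
        before = layers[name].values.ravel().argsort()
        after = stack[name].values.ravel().argsort()
        assert (before == after).all()


def test_prepare_predictors_missing_layer(rng):
    layers = _named_stack(rng)
    del layers["elevation"]
    with pytest.raises(KeyError):
        prepare_predictors(layers)


# ---------------------------------------------------------------------------
# zonal aggregation


def _tiny_census():
    return pd.DataFrame(
        [
            {"holder_id": 0, "subdistrict_id": 0, "boars": 1, "sows": 2, "piglets": 5,
             "fattening": 0, "native": 0},
            {"holder_id": 1, "subdistrict_id": 0, "boars": 0, "sows": 0, "piglets": 0,
             "fattening": 60, "native": 0},
            {"holder_id": 2, "subdistrict_id": 1, "boars": 0, "sows": 0, "piglets": 0,
             "fattening": 0, "native": 3},
        ]
    )


def test_single_zone_mean_is_global_mean(rng):
    stack = _named_stack(rng, shape=(4, 4))
    zones = np.zeros((4, 4), dtype=int)
    census = _tiny_census()
    census["subdistrict_id"] = 0
    frame = zonal_aggregate(stack, zones, census)
    for name in PREDICTOR_NAMES:
        assert frame.loc[0, name] == pytest.approx(stack[name].values.mean())


def test_zonal_means_match_nested_loop_oracle(landscape, predictor_stack, census):
    frame = zonal_aggregate(predictor_stack, landscape.zone_raster, census.holders)
    zr = landscape.zone_raster
    for zid in [0, 5, 11, 15]:
        sel = zr == zid
        for name in PREDICTOR_NAMES:
            expected = np.mean([predictor_stack[name].values[i, j]
                                for i, j in zip(*np.nonzero(sel))])
            assert frame.loc[zid, name] == pytest.approx(expected)


def test_zone_with_no_pigs_has_structural_zero_density(rng):
    stack = _named_stack(rng, shape=(4, 4))
    zones = np.repeat(np.arange(2), 8).reshape(4, 4)
    census = _tiny_census()
    census["subdistrict_id"] = 0  # zone 1 has no holders
    frame = zonal_aggregate(stack, zones, census)
    assert frame.loc[1, "native_pigs"] == 0.0
    assert frame.loc[1, "smallholders"] == 0.0
    assert not frame.loc[1].isna().any()


def test_aggregation_conserves_census_totals(landscape, predictor_stack, census):
    frame = zonal_aggregate(predictor_stack, landscape.zone_raster, census.holders,
                            farms_per_10km2=False)
    h = census.holders
    total_native = (frame["native_pigs"] * frame["area_km2"]).sum()
    assert total_native == pytest.approx(h["native"].sum())
    total_breeding = (frame["breeding_pigs"] * frame["area_km2"]).sum()
    assert total_breeding == pytest.approx((h["boars"] + h["sows"] + h["piglets"]).sum())
    total_farms = ((frame["smallholders"] + frame["largescale_farms"]) * frame["area_km2"]).sum()
    assert total_farms == pytest.approx(len(h))


def test_farm_densities_use_per_10km2_units(landscape, predictor_stack, census):
    per1 = zonal_aggregate(predictor_stack, landscape.zone_raster, census.holders,
                           farms_per_10km2=False)
    per10 = zonal_aggregate(predictor_stack, landscape.zone_raster, census.holders,
                            farms_per_10km2=True)
    assert np.allclose(per10["smallholders"], 10 * per1["smallholders"])
    assert np.allclose(per10["native_pigs"], per1["native_pigs"])  # head densities unchanged


def test_census_with_unknown_zone_rejected(rng):
    stack = _named_stack(rng, shape=(4, 4))
    zones = np.zeros((4, 4), dtype=int)
    census = _tiny_census()  # references zone 1, absent from the raster
    with pytest.raises(ValueError):
        zonal_aggregate(stack, zones, census)
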