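"""Zero-altered (hurdle) two-part random-forest distribution model.

Each response — a density of pigs (head/km^2) or farms (farms/10 km^2)
per sub-district — is modelled in two parts: a classification forest for
presence (zero vs non-zero zones) fit on all zones, and a regression
forest for abundance fit on log10(density + 1) over the non-zero zones
only.  The combined prediction is the hurdle expectation

    density = P(non-zero) * (10**abundance - 1)

floored at zero (a hard presence threshold is available as an alternative
combination rule).  Predictions are produced at two scales: per
sub-district, from zone-aggregated predictors, and per 1 km pixel, from
the raster predictors, with pixel surfaces summarizable back to zones for
like-for-like evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import forest as rf
from .covariates import PREDICTOR_NAMES, RESPONSE_NAMES
from .raster import RasterGrid

MIN_POSITIVE_ZONES = 10


@dataclass
class HurdleRFModel:
    presence_model: rf.ForestModel
    abundance_model: rf.ForestModel
    response_name: str
    combination: str = "product"
    presence_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.combination not in ("product", "threshold"):
            raise ValueError("combination must be 'product' or 'threshold'")
        if not 0.0 <= self.presence_threshold <= 1.0:
            raise ValueError("presence_threshold must lie in [0, 1]")


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def fit_hurdle(
    zonal: pd.DataFrame,
    response_name: str,
    n_trees: int = 500,
    m_try: int = 4,
    min_node_size: int | None = None,
    seed: int = 0,
    combination: str = "product",
    presence_threshold: float = 0.5,
) -> HurdleRFModel:
    """Fit the two-part model for one response on the zonal frame."""
    if response_name not in zonal.columns:
        raise KeyError(f"zonal frame has no response column '{response_name}'")
    missing = [n for n in PREDICTOR_NAMES if n not in zonal.columns]
    if missing:
        raise KeyError(f"zonal frame lacks predictor column(s): {missing}")
    X = zonal[list(PREDICTOR_NAMES)]
    y = zonal[response_name].to_numpy(dtype=float)
    positive = y > 0
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValueError(f"response '{response_name}' is zero in every zone; nothing to model")
    if n_pos < MIN_POSITIVE_ZONES:
        raise ValueError(
            f"response '{response_name}' has only {n_pos} non-zero zones "
            f"(need >= {MIN_POSITIVE_ZONES}) — too few to fit the abundance part"
        )
    s_pres, s_abund = _subseeds(seed, 2)
    presence = rf.fit_forest(
        X, positive.astype(float), task="classification",
        n_trees=n_trees, m_try=m_try, seed=s_pres,
    )
    abundance = rf.fit_forest(
        X[positive], np.log10(y[positive] + 1.0), task="regression",
        n_trees=n_trees, m_try=m_try, min_node_size=min_node_size, seed=s_abund,
    )
    return HurdleRFModel(
        presence_model=presence,
        abundance_model=abundance,
        response_name=response_name,
        combination=combination,
        presence_threshold=presence_threshold,
    )


def combine_parts(model: HurdleRFModel, p_presence: np.ndarray, abundance_log10: np.ndarray) -> np.ndarray:
    dens = np.maximum(10.0 ** abundance_log10 - 1.0, 0.0)
    if model.combination == "product":
        return p_presence * dens
    return np.where(p_presence >= model.presence_threshold, dens, 0.0)


def predict_density(model: HurdleRFModel, predictors, scale: str = "zonal"):
    """Combined hurdle prediction per unit.

    ``scale='zonal'`` takes a zonal frame (or any table with the predictor
    columns) and returns a Series of densities indexed like it;
    ``scale='pixel'`` takes a dict of predictor rasters (already on the
    model/log scale, as produced by ``prepare_predictors``) and returns a
    density raster.
    """
    if scale == "zonal":
        if not isinstance(predictors, pd.DataFrame):
            raise TypeError("zonal-scale prediction expects a DataFrame")
        X = predictors[list(PREDICTOR_NAMES)]
        p = rf.predict(model.presence_model, X)
        a = rf.predict(model.abundance_model, X)
        return pd.Series(combine_parts(model, p, a), index=predictors.index, name=model.response_name)
    if scale == "pixel":
        if not isinstance(predictors, dict):
            raise TypeError("pixel-scale prediction expects a dict of rasters")
        missing = [n for n in PREDICTOR_NAMES if n not in predictors]
        if missing:
            raise KeyError(f"missing predictor layer(s): {missing}")
        template = predictors[PREDICTOR_NAMES[0]]
        valid = np.ones(template.shape, dtype=bool)
        for n in PREDICTOR_NAMES:
            if not predictors[n].same_grid(template):
                raise ValueError("predictor rasters are not aligned")
            valid &= predictors[n].mask()
        X = pd.DataFrame(
            {n: predictors[n].values[valid] for n in PREDICTOR_NAMES}
        )
        p = rf.predict(model.presence_model, X)
        a = rf.predict(model.abundance_model, X)
        out = np.full(template.shape, template.nodata, dtype=float)
        out[valid] = combine_parts(model, p, a)
        return template.with_values(out)
    raise ValueError("scale must be 'zonal' or 'pixel'")


def summarize_pixels_to_zones(
    surface: RasterGrid,
    zone_raster: np.ndarray,
    farms_per_10km2_factor: float = 1.0,
) -> pd.DataFrame:
    """Sum a pixel density surface within zones.

    Zone count = sum of (cell density x cell area); zone density = count
    divided by zone area — i.e. the area-weighted mean of cell densities,
    conserving a constant field.  ``farms_per_10km2_factor`` carries the
    per-10 km^2 unit through the area arithmetic when densities are in
    farms/10 km^2 (factor 10).
    """
    if surface.shape != zone_raster.shape:
        raise ValueError("density surface and zone raster are not aligned")
    valid = surface.mask()
    cell_area = surface.cell_area_km2
    rows = []
    for zid in np.unique(zone_raster[zone_raster >= 0]):
        sel = (zone_raster == zid) & valid
        area = (zone_raster == zid).sum() * cell_area
        count = float(surface.values[sel].sum()) * cell_area / farms_per_10km2_factor
        rows.append(
            {
                "zone_id": int(zid),
                "area_km2": area,
                "count": count,
                "density": count / area * farms_per_10km2_factor,
            }
        )
    return pd.DataFrame(rows).set_index("zone_id")


def fit_single_part(
    zonal: pd.DataFrame,
    response_name: str,
    n_trees: int = 500,
    m_try: int = 4,
    seed: int = 0,
) -> rf.ForestModel:
    """Reference single-part model: one regression forest on all zones
    with the same log10(density + 1) transform (no presence part)."""
    X = zonal[list(PREDICTOR_NAMES)]
    y = np.log10(zonal[response_name].to_numpy(dtype=float) + 1.0)
    s_pres, s_abund = _subseeds(seed, 2)
    return rf.fit_forest(X, y, task="regression", n_trees=n_trees, m_try=m_try, seed=s_abund)


def predict_single_part(model: rf.ForestModel, zonal: pd.DataFrame) -> pd.Series:
    a = rf.predict(model, zonal[list(PREDICTOR_NAMES)])
    return pd.Series(np.maximum(10.0 ** a - 1.0, 0.0), index=zonal.index)


# ---------------------------------------------------------------------------
# serialization


def hurdle_to_dict(model: HurdleRFModel) -> dict:
    return {
        "response_name": model.response_name,
        "combination": model.combination,
        "presence_threshold": model.presence_threshold,
        "presence_model": rf.forest_to_dict(model.presence_model),
        "abundance_model": rf.forest_to_dict(model.abundance_model),
    }


def hurdle_from_dict(d: dict) -> HurdleRFModel:
    return HurdleRFModel(
        presence_model=rf.forest_from_dict(d["presence_model"]),
        abundance_model=rf.forest_from_dict(d["abundance_model"]),
        response_name=d["response_name"],
        combination=d["combination"],
        presence_threshold=d["presence_threshold"],
    )


def save_hurdle(model: HurdleRFModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(hurdle_to_dict(model), fh)


def load_hurdle(path) -> HurdleRFModel:
    with open(path) as fh:
        return hurdle_from_dict(json.load(fh))
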