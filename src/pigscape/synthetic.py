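"""Synthetic landscape and holder-census generator with known ground truth.

The generator emulates the statistical structure of a national pig census
joined to gridded spatial covariates, so that the whole downstream
pipeline — typology, covariate engineering, the two-part distribution
model and its evaluation — can be exercised end-to-end with recoverable
ground truth:

* six spatially autocorrelated covariate rasters (white noise smoothed by
  a Gaussian kernel; travel times derived from a generated friction
  surface and points of interest by the cost-distance operation);
* an irregular partition of the grid into sub-districts (discrete Voronoi
  cells of random seed points);
* a holder population exhibiting zero inflation (whole zones empty for a
  category) and over-dispersed abundances (log-normal counts), with
  opposite-sign covariate associations for smallholder-type and
  large-scale categories.

Census holders are the union of five primary-category subpopulations
(native, breeding and fattening pig keepers, plus smallholder and
large-scale commercial farms).  Each candidate holder draws presence from
a logit-linear model and, upon presence, a conditional count
round(10**(linear predictor + Normal(0, sd)) - 1) truncated at one pig,
all evaluated on standardized zone-mean predictors.  The drawn count maps
onto the census pig-type columns according to the category: breeding
counts are split into boars/sows/piglets, large-scale farm counts are
kept at or above the 50-head threshold, smallholder farm counts below it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from . import zones as zones_mod
from .covariates import PREDICTOR_NAMES, cost_distance, prepare_predictors
from .raster import RasterGrid, read_raster, write_raster

CATEGORIES = ("native", "breeding", "fattening", "smallholder_farms", "largescale_farms")

#: share of candidate holders assigned to each primary category
CATEGORY_MIX = {
    "native": 0.35,
    "breeding": 0.15,
    "fattening": 0.20,
    "smallholder_farms": 0.25,
    "largescale_farms": 0.05,
}

#: split of a breeding-category count into boars / sows / piglets
BREEDING_SPLIT = (0.05, 0.35, 0.60)

LN10 = np.log(10.0)


@dataclass(frozen=True)
class LandscapeConfig:
    grid_rows: int = 40
    grid_cols: int = 40
    cell_size_km: float = 1.0
    n_subdistricts: int = 16
    n_poi: int = 5
    random_seed: int = 0
    spatial_smoothing_scale: float = 6.0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if not 1 <= self.n_subdistricts <= self.grid_rows * self.grid_cols:
            raise ValueError("need 1 <= n_subdistricts <= number of grid cells")
        if self.n_poi < 1:
            raise ValueError("n_poi must be positive")
        if self.spatial_smoothing_scale <= 0:
            raise ValueError("spatial_smoothing_scale must be positive")


@dataclass(frozen=True)
class CategoryParams:
    """Generative presence/abundance model for one response category.

    Coefficients apply to the six standardized zone-mean predictors in
    :data:`pigscape.covariates.PREDICTOR_NAMES` order; presence is on the
    logit scale, abundance on the log10 count scale.
    """

    presence_intercept: float
    presence_coefs: tuple[float, ...]
    abundance_intercept: float
    abundance_coefs: tuple[float, ...]
    abundance_sd: float

    def __post_init__(self) -> None:
        if len(self.presence_coefs) != 6 or len(self.abundance_coefs) != 6:
            raise ValueError("expected six coefficients per linear predictor")
        if self.abundance_sd < 0:
            raise ValueError("abundance_sd must be non-negative")


@dataclass(frozen=True)
class GenerativeParams:
    categories: dict[str, CategoryParams]

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.categories]
        if missing:
            raise ValueError(f"missing category params: {missing}")

    def sign_pattern(self) -> dict[str, dict[str, list[int]]]:
        """Recorded ground-truth coefficient signs per category."""
        out = {}
        for cat, p in self.categories.items():
            out[cat] = {
                "presence": [int(np.sign(c)) for c in p.presence_coefs],
                "abundance": [int(np.sign(c)) for c in p.abundance_coefs],
            }
        return out


def default_generative_params() -> GenerativeParams:
    """Defaults encoding the contrasted association pattern of the study
    system.

    Abundance (log10 count scale): commercial categories (breeding,
    fattening, large-scale farms) decline with travel time to cities and
    with elevation, smallholder categories (native pigs, smallholder
    farms) increase with them, and every category responds positively to
    human density and croplands, with human density the strongest
    predictor followed by travel time to the capital.

    Presence (logit scale) carries the same signs but a different shape,
    reflecting that occurrence and abundance are distinct processes:
    smallholder-type categories have a steep absence cliff toward the
    urban core (they all but vanish where land is densest), while the
    commercial categories thin out gradually toward remote zones, where
    low per-holder presence rates in sparsely settled sub-districts
    produce stochastic zone-level zeros that the covariates only weakly
    predict — the census analogue of false zeros.
    """
    #                 tcap   tprov  racrop ircrop elev   huden
    c = {
        "native": CategoryParams(
            presence_intercept=-1.0,
            presence_coefs=(3.0, 1.8, 0.8, 0.3, 2.4, 0.3),
            abundance_intercept=0.55,
            abundance_coefs=(0.20, 0.10, 0.10, 0.05, 0.15, 0.25),
            abundance_sd=0.25,
        ),
        "breeding": CategoryParams(
            presence_intercept=-2.0,
            presence_coefs=(-1.2, -0.8, 0.5, 0.4, -1.0, 0.6),
            abundance_intercept=2.20,
            abundance_coefs=(-0.35, -0.15, 0.10, 0.10, -0.15, 0.40),
            abundance_sd=0.25,
        ),
        "fattening": CategoryParams(
            presence_intercept=-2.0,
            presence_coefs=(-1.3, -0.8, 0.5, 0.4, -1.1, 0.6),
            abundance_intercept=2.25,
            abundance_coefs=(-0.40, -0.15, 0.10, 0.10, -0.20, 0.40),
            abundance_sd=0.25,
        ),
        "smallholder_farms": CategoryParams(
            presence_intercept=-0.8,
            presence_coefs=(2.6, 1.8, 0.8, 0.4, 2.0, 0.3),
            abundance_intercept=0.90,
            abundance_coefs=(0.25, 0.10, 0.10, 0.05, 0.10, 0.30),
            abundance_sd=0.25,
        ),
        "largescale_farms": CategoryParams(
            presence_intercept=-2.2,
            presence_coefs=(-1.3, -1.0, 0.5, 0.4, -1.1, 0.7),
            abundance_intercept=2.35,
            abundance_coefs=(-0.40, -0.20, 0.10, 0.10, -0.20, 0.45),
            abundance_sd=0.25,
        ),
    }
    return GenerativeParams(categories=c)


@dataclass
class Landscape:
    config: LandscapeConfig
    layers: dict[str, RasterGrid]
    friction: RasterGrid
    capital_xy: tuple[float, float]
    poi_xy: np.ndarray
    zone_raster: np.ndarray
    polygons: dict


def _smooth_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Standardized Gaussian random field: smoothed white noise, z-scored."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=scale, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate the six covariate layers, sub-districts and points of interest."""
    rows, cols = config.grid_rows, config.grid_cols
    streams = np.random.SeedSequence(config.random_seed).spawn(8)
    rngs = [np.random.default_rng(s) for s in streams]
    template = RasterGrid(np.zeros((rows, cols)), cell_size_km=config.cell_size_km)
    s = config.spatial_smoothing_scale

    g_elev = _smooth_field(rngs[0], (rows, cols), s)
    g_rain = _smooth_field(rngs[1], (rows, cols), s)
    g_irr = _smooth_field(rngs[2], (rows, cols), s)
    g_fric = _smooth_field(rngs[3], (rows, cols), s)
    g_hum = _smooth_field(rngs[4], (rows, cols), s)

    elevation = np.exp(4.0 + 1.0 * g_elev)  # metres, strictly positive
    rainfed = expit(1.2 * g_rain)
    irrigated = expit(1.2 * g_irr - 0.5)
    # rougher terrain is slower to cross; time (hours) per km of cell
    friction_vals = np.exp(0.2 + 0.35 * g_fric + 0.002 * (elevation - elevation.mean()) / elevation.std())
    friction = template.with_values(friction_vals)

    rng_pts = rngs[5]
    capital_cell = (int(rng_pts.integers(rows)), int(rng_pts.integers(cols)))
    capital_xy = template.cell_center(*capital_cell)
    poi_cells = rng_pts.choice(rows * cols, size=config.n_poi, replace=False)
    poi_xy = np.array([template.cell_center(c // cols, c % cols) for c in poi_cells])

    travel_capital = cost_distance(friction, np.array([capital_xy]))
    travel_province = cost_distance(friction, poi_xy)

    # settlement follows accessibility: density decays with travel time to
    # the capital, with independent smooth noise so the two remain separable
    t = travel_capital.values
    t_norm = (t - t.min()) / max(t.max() - t.min(), 1e-12)
    human_density = 10.0 ** (1.8 - 0.8 * t_norm + 0.4 * g_hum)

    layers = {
        "travel_capital": travel_capital,
        "travel_province": travel_province,
        "rainfed_crop": template.with_values(rainfed),
        "irrigated_crop": template.with_values(irrigated),
        "elevation": template.with_values(elevation),
        "human_density": template.with_values(human_density),
    }

    rng_zones = rngs[6]
    seed_cells = rng_zones.choice(rows * cols, size=config.n_subdistricts, replace=False)
    seed_pts = np.array([template.cell_center(c // cols, c % cols) for c in seed_cells])
    zone_raster = zones_mod.voronoi_zone_raster(template, seed_pts)
    polygons = zones_mod.zone_polygons(zone_raster, template)

    return Landscape(
        config=config,
        layers=layers,
        friction=friction,
        capital_xy=capital_xy,
        poi_xy=poi_xy,
        zone_raster=zone_raster,
        polygons=polygons,
    )


@dataclass
class GeneratedCensus:
    """A generated holder census plus the ground truth that produced it."""

    holders: pd.DataFrame
    zone_truth: pd.DataFrame
    standardization: dict[str, dict[str, float]]
    category_stats: pd.DataFrame


def standardized_zone_predictors(landscape: Landscape) -> tuple[pd.DataFrame, dict]:
    """Zone means of the transformed predictors, z-scored across zones."""
    stack = prepare_predictors(landscape.layers)
    zr = landscape.zone_raster
    zone_ids = np.unique(zr[zr >= 0])
    rows = []
    for zid in zone_ids:
        sel = zr == zid
        rows.append({"zone_id": int(zid), **{n: float(stack[n].values[sel].mean()) for n in PREDICTOR_NAMES}})
    df = pd.DataFrame(rows).set_index("zone_id")
    standardization = {}
    for n in PREDICTOR_NAMES:
        mu, sd = float(df[n].mean()), float(df[n].std(ddof=0))
        sd = sd if sd > 1e-12 else 1.0
        standardization[n] = {"mean": mu, "sd": sd}
        df[n] = (df[n] - mu) / sd
    return df, standardization


def _split_breeding(count: int) -> tuple[int, int, int]:
    """Deterministically split a breeding count into boars/sows/piglets,
    each at least one head when the count allows (>= 3)."""
    if count <= 2:
        return (0, count, 0) if count == 1 else (0, 1, 1)
    boars = max(1, int(round(BREEDING_SPLIT[0] * count)))
    sows = max(1, int(round(BREEDING_SPLIT[1] * count)))
    piglets = count - boars - sows
    if piglets < 1:
        sows = max(1, sows - (1 - piglets))
        piglets = count - boars - sows
    return boars, sows, piglets


def generate_holders(
    landscape: Landscape,
    params: GenerativeParams,
    n_holders: int,
    seed: int,
) -> GeneratedCensus:
    """Draw a holder census from the generative hurdle structure.

    ``n_holders`` candidate holders are placed in zones proportionally to
    zone human-density mass, assigned a primary category, and realized
    (or not) by the category's presence model; present holders draw a
    log-normal conditional count.  Returns the census table together with
    the per-zone, per-category ground truth (presence probability, log10
    abundance linear predictor, analytic expected density) for recovery
    tests.
    """
    if n_holders <= 0:
        raise ValueError("n_holders must be positive")
    zcov, standardization = standardized_zone_predictors(landscape)
    zone_ids = zcov.index.to_numpy()
    zr = landscape.zone_raster
    hd = landscape.layers["human_density"].values
    template = landscape.layers["human_density"]
    areas = {int(z): float((zr == z).sum()) * template.cell_area_km2 for z in zone_ids}

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # zone allocation proportional to settlement mass
    zone_mass = np.array([hd[zr == z].sum() for z in zone_ids], dtype=float)
    zone_prob = zone_mass / zone_mass.sum()
    holder_zone = rng.choice(len(zone_ids), size=n_holders, p=zone_prob)

    # primary category by fixed census mix
    cat_names = list(CATEGORIES)
    cat_prob = np.array([CATEGORY_MIX[c] for c in cat_names])
    holder_cat = rng.choice(len(cat_names), size=n_holders, p=cat_prob / cat_prob.sum())

    # cell within zone, weighted by human density
    zone_cells = {}
    for zi, z in enumerate(zone_ids):
        rr, cc = np.nonzero(zr == z)
        w = hd[rr, cc]
        zone_cells[zi] = (rr, cc, w / w.sum())

    Z = zcov.to_numpy()  # (n_zones, 6)
    lp_pres = np.empty((len(zone_ids), len(cat_names)))
    lp_abund = np.empty_like(lp_pres)
    for ci, cat in enumerate(cat_names):
        p = params.categories[cat]
        lp_pres[:, ci] = p.presence_intercept + Z @ np.asarray(p.presence_coefs)
        lp_abund[:, ci] = p.abundance_intercept + Z @ np.asarray(p.abundance_coefs)
    prob_pres = expit(lp_pres)

    # all stochastic inputs are pre-drawn as fixed-size arrays (common random
    # numbers), so one category's parameters never perturb another's draws
    u_pres = rng.random(n_holders)
    eps_raw = rng.standard_normal(n_holders)
    u_cell = rng.random(n_holders)

    p_h = prob_pres[holder_zone, holder_cat]
    sd_h = np.array([params.categories[c].abundance_sd for c in cat_names])[holder_cat]
    present = u_pres < p_h
    lp_h = lp_abund[holder_zone, holder_cat] + sd_h * eps_raw
    count_h = np.maximum(1, np.rint(10.0 ** lp_h - 1.0).astype(np.int64))

    n_candidates = np.zeros((len(zone_ids), len(cat_names)), dtype=int)
    n_present = np.zeros_like(n_candidates)
    np.add.at(n_candidates, (holder_zone, holder_cat), 1)
    np.add.at(n_present, (holder_zone[present], holder_cat[present]), 1)

    cum_w = {zi: np.cumsum(w) for zi, (_, _, w) in zone_cells.items()}
    records = []
    holder_id = 0
    for i in np.nonzero(present)[0]:
        zi = int(holder_zone[i])
        cat = cat_names[int(holder_cat[i])]
        count = int(count_h[i])
        rr, cc, _ = zone_cells[zi]
        k = int(np.searchsorted(cum_w[zi], u_cell[i], side="right").clip(0, rr.size - 1))
        rec = {
            "holder_id": holder_id,
            "subdistrict_id": int(zone_ids[zi]),
            "row": int(rr[k]),
            "col": int(cc[k]),
            "boars": 0,
            "sows": 0,
            "piglets": 0,
            "fattening": 0,
            "native": 0,
            "category": cat,
            "drawn_count": count,
        }
        if cat == "native":
            rec["native"] = count
        elif cat == "breeding":
            b, s, p_ = _split_breeding(count)
            rec["boars"], rec["sows"], rec["piglets"] = b, s, p_
        elif cat == "fattening":
            rec["fattening"] = count
        elif cat == "smallholder_farms":
            rec["native"] = min(count, 49)
        else:  # largescale_farms
            rec["fattening"] = max(count, 50)
        records.append(rec)
        holder_id += 1

    holders = pd.DataFrame(
        records,
        columns=["holder_id", "subdistrict_id", "row", "col", "boars", "sows", "piglets",
                 "fattening", "native", "category", "drawn_count"],
    )

    # ground truth: analytic expectation under the untruncated log-normal model
    truth_rows = []
    for zi, z in enumerate(zone_ids):
        for ci, cat in enumerate(cat_names):
            sd = params.categories[cat].abundance_sd
            mean_count = 10.0 ** lp_abund[zi, ci] * np.exp((sd * LN10) ** 2 / 2.0) - 1.0
            expected_density = (
                n_holders * CATEGORY_MIX[cat] * zone_prob[zi] * prob_pres[zi, ci] * max(mean_count, 0.0) / areas[int(z)]
            )
            truth_rows.append(
                {
                    "zone_id": int(z),
                    "category": cat,
                    "presence_prob": float(prob_pres[zi, ci]),
                    "presence_lp": float(lp_pres[zi, ci]),
                    "abundance_log10": float(lp_abund[zi, ci]),
                    "expected_density": float(expected_density),
                    "n_candidates": int(n_candidates[zi, ci]),
                    "n_present": int(n_present[zi, ci]),
                    **{f"z_{n}": float(zcov.loc[z, n]) for n in PREDICTOR_NAMES},
                }
            )
    zone_truth = pd.DataFrame(truth_rows)

    cat_stats = (
        zone_truth.groupby("category")[["n_candidates", "n_present"]].sum().loc[list(CATEGORIES)]
    )
    cat_stats["presence_fraction"] = cat_stats["n_present"] / cat_stats["n_candidates"].clip(lower=1)

    return GeneratedCensus(
        holders=holders,
        zone_truth=zone_truth,
        standardization=standardization,
        category_stats=cat_stats,
    )


# ---------------------------------------------------------------------------
# fixture bundles on disk


def _params_to_dict(params: GenerativeParams) -> dict:
    return {
        cat: {
            "presence_intercept": p.presence_intercept,
            "presence_coefs": list(p.presence_coefs),
            "abundance_intercept": p.abundance_intercept,
            "abundance_coefs": list(p.abundance_coefs),
            "abundance_sd": p.abundance_sd,
        }
        for cat, p in params.categories.items()
    }


def params_from_dict(d: dict) -> GenerativeParams:
    return GenerativeParams(
        categories={
            cat: CategoryParams(
                presence_intercept=v["presence_intercept"],
                presence_coefs=tuple(v["presence_coefs"]),
                abundance_intercept=v["abundance_intercept"],
                abundance_coefs=tuple(v["abundance_coefs"]),
                abundance_sd=v["abundance_sd"],
            )
            for cat, v in d.items()
        }
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_bundle(
    config: LandscapeConfig,
    params: GenerativeParams,
    out_dir,
    n_holders: int = 5000,
) -> dict:
    """Write a complete, re-readable fixture: census CSV, covariate and
    friction rasters, sub-district GeoJSON and a manifest of the true
    generative parameters.  The census seed is derived from the landscape
    seed so one config regenerates one bit-identical bundle."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"fixture directory {out} is not writable: {exc}") from exc

    landscape = generate_landscape(config)
    # the census stream (root sequence) is independent of the landscape
    # streams (spawned children of the same sequence)
    census_seed = config.random_seed
    census = generate_holders(landscape, params, n_holders=n_holders, seed=census_seed)

    files = {}
    for name, layer in landscape.layers.items():
        path = out / f"{name}.tif"
        write_raster(path, layer)
        files[f"{name}.tif"] = _sha256(path)
    write_raster(out / "friction.tif", landscape.friction)
    files["friction.tif"] = _sha256(out / "friction.tif")

    zones_mod.write_geojson(out / "subdistricts.geojson", landscape.polygons)
    files["subdistricts.geojson"] = _sha256(out / "subdistricts.geojson")

    census_cols = ["holder_id", "subdistrict_id", "row", "col", "boars", "sows", "piglets", "fattening", "native"]
    census.holders[census_cols].to_csv(out / "census.csv", index=False)
    files["census.csv"] = _sha256(out / "census.csv")
    census.zone_truth.to_csv(out / "zone_truth.csv", index=False)
    files["zone_truth.csv"] = _sha256(out / "zone_truth.csv")

    manifest = {
        "config": {
            "grid_rows": config.grid_rows,
            "grid_cols": config.grid_cols,
            "cell_size_km": config.cell_size_km,
            "n_subdistricts": config.n_subdistricts,
            "n_poi": config.n_poi,
            "random_seed": config.random_seed,
            "spatial_smoothing_scale": config.spatial_smoothing_scale,
        },
        "n_holders": n_holders,
        "census_seed": census_seed,
        "params": _params_to_dict(params),
        "sign_pattern": params.sign_pattern(),
        "capital_xy": list(landscape.capital_xy),
        "poi_xy": [list(p) for p in landscape.poi_xy],
        "standardization": census.standardization,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_fixture_bundle(bundle_dir):
    """Re-read a bundle written by :func:`make_fixture_bundle`.

    Returns (layers, polygons, census, manifest).
    """
    d = Path(bundle_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    layers = {name: read_raster(d / f"{name}.tif") for name in PREDICTOR_NAMES}
    polygons = zones_mod.read_geojson(d / "subdistricts.geojson")
    census = pd.read_csv(d / "census.csv")
    return layers, polygons, census, manifest
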