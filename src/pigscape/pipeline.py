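"""End-to-end orchestration: simulate -> classify -> covariates -> fit ->
predict -> evaluate, with a reproducibility manifest.

One global seed deterministically derives a sub-seed for every stochastic
stage (by hashing the stage name with the seed), so each stage is
reproducible on its own and the whole run is bit-stable: two runs with
the same configuration and seed write byte-identical outputs and hence
identical manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import hurdle as hd
from . import synthetic as syn
from . import zones as zones_mod
from .covariates import (
    FARM_RESPONSES,
    PREDICTOR_NAMES,
    RESPONSE_NAMES,
    prepare_predictors,
    zonal_aggregate,
)
from .raster import read_raster, write_raster
from .typology import census_summary

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pigscape_run"
    # exactly one of the two input modes
    simulate: dict | None = None  # LandscapeConfig fields + n_holders
    data: dict | None = None  # census / rasters / zones paths
    n_trees: int = 500
    m_try: int = 4
    min_node_size: int | None = None
    combination: str = "product"
    presence_threshold: float = 0.5
    responses: tuple[str, ...] = RESPONSE_NAMES
    farms_per_10km2: bool = True

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.data is None):
            raise ValueError("config must set exactly one of 'simulate' or 'data'")
        bad = [r for r in self.responses if r not in RESPONSE_NAMES]
        if bad:
            raise ValueError(f"unknown response(s): {bad}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: PipelineConfig, out: Path) -> tuple[dict, np.ndarray, pd.DataFrame]:
    """Stage 1: simulate a fixture bundle or read real-data paths.

    Returns (raw layers, zone raster, census).
    """
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        n_holders = int(sim.pop("n_holders", 5000))
        sim.setdefault("random_seed", stage_seed(cfg.seed, "simulate"))
        lcfg = syn.LandscapeConfig(**sim)
        params = syn.default_generative_params()
        bundle_dir = out / "fixture"
        syn.make_fixture_bundle(lcfg, params, bundle_dir, n_holders=n_holders)
        layers, polygons, census, _ = syn.read_fixture_bundle(bundle_dir)
        template = layers[PREDICTOR_NAMES[0]]
        zone_raster = zones_mod.rasterize_zones(polygons, template)
        return layers, zone_raster, census
    paths = cfg.data
    census = pd.read_csv(paths["census"])
    rasters = Path(paths["rasters"])
    layers = {name: read_raster(rasters / f"{name}.tif") for name in PREDICTOR_NAMES}
    polygons = zones_mod.read_geojson(paths["zones"])
    template = layers[PREDICTOR_NAMES[0]]
    zone_raster = zones_mod.rasterize_zones(polygons, template)
    return layers, zone_raster, census


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written as
    ``report.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}, "checksums": {}}

    log.info("stage simulate/load: preparing inputs")
    layers, zone_raster, census = _load_inputs(cfg, out)
    report["stages"]["inputs"] = {"n_holders": int(len(census)), "n_zones": int(len(np.unique(zone_raster[zone_raster >= 0])))}

    log.info("stage classify: census summary")
    summary = census_summary(census[["holder_id", "subdistrict_id", "boars", "sows", "piglets", "fattening", "native"]])
    summary["crosstab"].to_csv(out / "census_crosstab.csv", index=False)
    with open(out / "census_stats.json", "w") as fh:
        json.dump(summary["stats"], fh, indent=2, sort_keys=True)
    report["stages"]["classify"] = {"total_heads": summary["stats"]["total_heads"]}

    log.info("stage covariates: predictor stack and zonal frame")
    stack = prepare_predictors(layers)
    frame = zonal_aggregate(stack, zone_raster, census, farms_per_10km2=cfg.farms_per_10km2)
    frame.to_csv(out / "zonal_frame.csv")
    report["stages"]["covariates"] = {"n_zones": int(len(frame))}

    models: dict[str, hd.HurdleRFModel] = {}
    metrics: dict[str, dict[str, ev.FitMetrics]] = {}
    fitted, skipped = [], {}
    for resp in cfg.responses:
        rseed = stage_seed(cfg.seed, f"fit:{resp}")
        log.info("stage fit: %s (seed %d)", resp, rseed)
        try:
            model = hd.fit_hurdle(
                frame,
                resp,
                n_trees=cfg.n_trees,
                m_try=cfg.m_try,
                min_node_size=cfg.min_node_size,
                seed=rseed,
                combination=cfg.combination,
                presence_threshold=cfg.presence_threshold,
            )
        except ValueError as exc:
            log.warning("stage fit: skipping %s: %s", resp, exc)
            skipped[resp] = str(exc)
            continue
        models[resp] = model
        hd.save_hurdle(model, out / f"model_{resp}.json")
        fitted.append(resp)

        zonal_pred = hd.predict_density(model, frame, scale="zonal")
        zonal_pred.to_frame("predicted").to_csv(out / f"pred_zonal_{resp}.csv")
        pixel_pred = hd.predict_density(model, stack, scale="pixel")
        write_raster(out / f"pred_pixel_{resp}.tif", pixel_pred)
        factor = 10.0 if (cfg.farms_per_10km2 and resp in FARM_RESPONSES) else 1.0
        pix2zone = hd.summarize_pixels_to_zones(pixel_pred, zone_raster, farms_per_10km2_factor=factor)
        pix2zone.to_csv(out / f"pred_pixel_zonal_{resp}.csv")

        obs = frame[resp].to_numpy()
        metrics[resp] = {
            "zonal": ev.fit_metrics(resp, "zonal", obs, zonal_pred.to_numpy()),
            "pixel": ev.fit_metrics(resp, "pixel", obs, pix2zone.loc[frame.index, "density"].to_numpy()),
        }
    report["stages"]["fit"] = {"fitted": fitted, "skipped": skipped}

    log.info("stage evaluate: metrics, importance, partial dependence")
    metric_rows = [
        {"response": r, "scale": s, "cor": m.cor, "rmse": m.rmse, "n": m.n}
        for r in fitted
        for s, m in metrics[r].items()
    ]
    pd.DataFrame(metric_rows).to_csv(out / "fit_metrics.csv", index=False)
    report["metrics"] = {
        r: {s: {"cor": m.cor, "rmse": m.rmse, "n": m.n} for s, m in metrics[r].items()} for r in fitted
    }

    if set(fitted) == set(RESPONSE_NAMES):
        table = ev.importance_table(models, frame=frame, metrics=metrics)
        table.to_csv(out / "importance_table.csv")
        report["stages"]["importance"] = {"rows": int(len(table))}

    profiles = []
    for resp in fitted:
        for var in PREDICTOR_NAMES:
            prof = ev.partial_dependence(models[resp], frame, var)
            for g, v in zip(prof.grid, prof.profile):
                profiles.append({"response": resp, "variable": var, "grid": g, "profile": v})
    pd.DataFrame(profiles).to_csv(out / "partial_dependence.csv", index=False)

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "report.json":
            report["checksums"][str(path.relative_to(out))] = _sha256(path)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
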