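"""End-to-end orchestration of the impact assessment on synthetic inputs.

Mirrors the study workflow:

1. build (or load) baseline climatology, DEM, growing-area atlas,
   communities and per-GCM anomaly fields;
2. aggregate the baseline to the coarser working resolution and downscale
   the GCM-ensemble-mean anomaly onto it (delta method);
3. simulate the 8-treatment factorial for baseline and future with the
   ensemble-mean climate, average treatments, and classify high-impact
   spots on the standardized yield change;
4. select site pixels around communities inside hot/adaptation spots
   (15 km radius, atlas overlap, 100 m elevation band) at the fine
   resolution;
5. rerun all GCMs individually at the site pixels for ensemble
   uncertainty metrics, compare alternative planting seasons, and
   quantify the fertilizer response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crop, spots
from .downscale import ScenarioClimate, downscale, ensemble_mean_climate
from .ensemble import (EnsembleMetrics, ensemble_metrics,
                       fertilizer_response, season_summary)
from .raster import AreaMask, GridRaster, MonthlyClimate, aggregate_mean
from .synthetic import (SyntheticConfig, make_atlas_and_communities,
                        make_baseline_climate, make_gcm_anomalies)

log = logging.getLogger("beanclim")


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    period: str = "2050s"
    n_years: int = 99
    agg_factor: int = 2          # spot-finding runs at this coarser grid
    season: str = "primera"
    compare_seasons: tuple[str, ...] = ("primera", "postrera", "apante")
    method: str = "robust_z"
    band_km: float = 15.0
    loss_threshold_pct: float = 10.0
    max_site_pixels: int = 120   # cap on fine pixels rerun per GCM
    zone_blocks: int = 4         # synthetic "municipality" zoning, NxN


@dataclass
class PipelineResult:
    config: PipelineConfig
    dem: GridRaster
    atlas: AreaMask
    communities: pd.DataFrame
    change: spots.YieldChangeField
    classification: spots.SpotClassification
    site_pixels: dict[str, list[tuple[int, int]]]
    metrics: EnsembleMetrics | None
    seasons: pd.DataFrame
    fert_ratio: GridRaster | None


def _aggregate_climate(mc: MonthlyClimate, factor: int) -> MonthlyClimate:
    if factor == 1:
        return mc.copy()
    def agg(stack):
        return np.stack([aggregate_mean(
            GridRaster(stack[m], mc.origin, mc.cell_size, mc.nodata),
            factor).values for m in range(12)])
    first = aggregate_mean(mc.layer("prec", 0), factor)
    return MonthlyClimate(agg(mc.prec), agg(mc.tmin), agg(mc.tmax),
                          mc.origin, first.cell_size, mc.nodata)


def _aggregate_mask(atlas: AreaMask, factor: int) -> AreaMask:
    if factor == 1:
        return atlas
    coarse = aggregate_mean(atlas.mask, factor)
    vals = np.where(coarse.valid, (coarse.values >= 0.5).astype(float),
                    coarse.nodata)
    return AreaMask(coarse.with_values(vals))


def _zone_raster(geom: GridRaster, blocks: int) -> GridRaster:
    rows, cols = geom.shape
    rsz = max(1, rows // blocks)
    csz = max(1, cols // blocks)
    rr = np.minimum(np.arange(rows) // rsz, blocks - 1)
    cc = np.minimum(np.arange(cols) // csz, blocks - 1)
    return geom.with_values(rr[:, None] * blocks + cc[None, :])


def _pixel_mask(geom: GridRaster, pixels: list[tuple[int, int]]) -> AreaMask:
    m = np.zeros(geom.shape)
    for r, c in pixels:
        m[r, c] = 1.0
    return AreaMask(GridRaster(m, geom.origin, geom.cell_size, geom.nodata))


def run_pipeline(cfg: PipelineConfig,
                 with_site_stage: bool = True) -> PipelineResult:
    scfg = cfg.synthetic
    seed = scfg.seed
    log.info("generating synthetic inputs (seed %d)", seed)
    baseline, dem = make_baseline_climate(scfg)
    atlas, communities = make_atlas_and_communities(scfg, dem)
    anomalies = make_gcm_anomalies(scfg, cfg.period)

    # --- step 1: coarse-grid factorial with the ensemble-mean climate ----
    base_coarse = _aggregate_climate(baseline, cfg.agg_factor)
    atlas_coarse = _aggregate_mask(atlas, cfg.agg_factor)
    base_scn = ScenarioClimate(base_coarse, "baseline")
    gcm_scns = [downscale(base_coarse, a, label=f"gcm{i:02d}")
                for i, a in enumerate(anomalies)]
    ens_scn = ensemble_mean_climate(gcm_scns, label=f"ens_{cfg.period}")

    treatments = crop.treatment_factorial()
    season = crop.SEASONS[cfg.season]
    log.info("simulating baseline grid (%s, %d treatments, %d years)",
             cfg.season, len(treatments), cfg.n_years)
    y_base = crop.run_grid(base_scn, season, treatments, cfg.n_years,
                           seed, mask=atlas_coarse)
    log.info("simulating future grid (%s ensemble mean)", cfg.period)
    y_fut = crop.run_grid(ens_scn, season, treatments, cfg.n_years,
                          seed, mask=atlas_coarse)

    change = spots.yield_change(y_fut, y_base)
    classification = spots.classify_yield_change(
        change, atlas_coarse, method=cfg.method, d_km=cfg.band_km)
    n_hot = int(classification.category_mask("hotspot").sum())
    log.info("classified %d hotspot pixels", n_hot)

    # --- zonal season comparison on the coarse grid ----------------------
    zones = _zone_raster(base_coarse.geometry_raster(), cfg.zone_blocks)
    rel_by_season: dict[str, GridRaster] = {cfg.season: change.relative}
    base_mean = spots.mean_surface(y_base)
    for sname in cfg.compare_seasons:
        if sname == cfg.season:
            continue
        sw = crop.SEASONS[sname]
        yb = crop.run_grid(base_scn, sw, treatments, cfg.n_years, seed,
                           mask=atlas_coarse)
        yf = crop.run_grid(ens_scn, sw, treatments, cfg.n_years, seed,
                           mask=atlas_coarse)
        rel_by_season[sname] = spots.yield_change(yf, yb).relative
    seasons_tbl = season_summary(rel_by_season, zones, base_mean,
                                 cfg.loss_threshold_pct)

    # --- step 4: per-GCM uncertainty at the fine site pixels -------------
    site_pixels: dict[str, list[tuple[int, int]]] = {}
    metrics = None
    fert_ratio = None
    if with_site_stage:
        cls_cat = classification.category
        for _, com in communities.iterrows():
            pix = spots.select_site_pixels(com.to_dict(), None, atlas, dem,
                                           radius_km=cfg.band_km)
            kept = []
            for r, c in pix:
                lon, lat = dem.cell_center(r, c)
                try:
                    cr, cc = cls_cat.index_of(lon, lat)
                except IndexError:
                    continue
                if cls_cat.values[cr, cc] in (
                        spots.CATEGORY_CODES["hotspot"],
                        spots.CATEGORY_CODES["adaptation"]):
                    kept.append((r, c))
            if kept:
                site_pixels[com["name"]] = kept
        all_pix = sorted({p for pix in site_pixels.values() for p in pix})
        if len(all_pix) > cfg.max_site_pixels:
            idx = np.linspace(0, len(all_pix) - 1,
                              cfg.max_site_pixels).astype(int)
            all_pix = [all_pix[i] for i in idx]
        log.info("site stage: %d communities, %d pixels",
                 len(site_pixels), len(all_pix))
        if len(all_pix) >= 2:
            site_mask = _pixel_mask(dem, all_pix)
            base_fine_scn = ScenarioClimate(baseline, "baseline")
            fert_levels = ("none", "F1", "F2")
            trt_all = crop.treatment_factorial(fertilizers=fert_levels)
            yb_site = crop.run_grid(base_fine_scn, season, trt_all,
                                    cfg.n_years, seed, mask=site_mask)
            gcm_changes = []
            trt8 = [t for t in trt_all if t.fertilizer in ("F1", "F2")]
            yb8 = {t.label: yb_site[t.label] for t in trt8}
            for i, anom in enumerate(anomalies):
                scn = downscale(baseline, anom, label=f"gcm{i:02d}")
                yf_site = crop.run_grid(scn, season, trt8, cfg.n_years,
                                        seed, mask=site_mask)
                gcm_changes.append(
                    spots.yield_change(yf_site, yb8).delta)
            metrics = ensemble_metrics(gcm_changes)
            f2 = spots.mean_surface(
                [yb_site[t.label] for t in trt_all
                 if t.fertilizer == "F2"])
            f0 = spots.mean_surface(
                [yb_site[t.label] for t in trt_all
                 if t.fertilizer == "none"])
            fert_ratio = fertilizer_response(f0, f2)

    return PipelineResult(
        config=cfg, dem=dem, atlas=atlas, communities=communities,
        change=change, classification=classification,
        site_pixels=site_pixels, metrics=metrics, seasons=seasons_tbl,
        fert_ratio=fert_ratio)
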