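"""Synthetic study-region generator.

Emulates the external inputs of a Central American drybean impact study:
a WorldClim-like fine-resolution monthly climatology with a bimodal wet
season (May-Oct, split by the July-August canicula dry spell), a smooth
DEM, temperature lapse with elevation, a patchy mid-elevation growing-area
mask, a community table, and an ensemble of coarse pseudo-GCM monthly
anomaly fields for two future periods.

Everything is deterministic given the config seed; all rasters share one
geometry.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import (AreaMask, GridRaster, MonthlyClimate, haversine_km,
                     write_monthly_climate, write_raster, write_stack)

#: relative monthly rainfall weights: dry Nov-Apr, wet May-Oct.  June is
#: deliberately heavier than July+August combined once the canicula factor
#: is applied, reproducing the characteristic mid-summer dip.
_MONTH_WEIGHTS = np.array(
    [8.0, 5.0, 10.0, 35.0, 190.0, 250.0, 210.0, 210.0, 240.0, 200.0,
     60.0, 15.0])
_CANICULA_MONTHS = (6, 7)  # July, August (0-based)

#: seasonal cycle of sea-level temperature (degC offsets from annual mean);
#: warmest in April-May before the rains, as in the Central American dry
#: corridor.
_TSEASON = np.array([-1.0, -0.3, 1.0, 2.0, 1.8, 0.6, 0.2, 0.4, 0.2, -0.2,
                     -0.8, -1.2])

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study region.

    The defaults describe a 40x40 grid at 2.5 arc-min resolution with a
    ~1400 mm bimodal rainfall regime, a 50 % canicula, and a 0.55 degC /
    100 m lapse rate, with 19 pseudo-GCMs.
    """

    grid_shape: tuple[int, int] = (40, 40)
    cell_size: float = 1.0 / 24.0  # 2.5 arc-minutes
    origin: tuple[float, float] = (-87.0, 14.5)
    n_gcms: int = 19
    seed: int = 0
    annual_total_mm: float = 1400.0
    canicula_depth: float = 0.5
    lapse_rate_per_100m: float = 0.55
    #: sea-level annual-mean tmax / tmin (degC); chosen so warming of ~2 degC
    #: lifts growing-season tmax past the crop's 35 degC ceiling at the low
    #: end of the growing-area elevation band
    tmax_sealevel: float = 34.0
    tmin_sealevel: float = 22.0
    dem_max_m: float = 2200.0
    #: elevation band of the growing-area mask (m)
    atlas_band_m: tuple[float, float] = (300.0, 1600.0)
    n_communities: int = 15
    #: inter-GCM spread of the temperature anomaly (degC, 1 SD)
    gcm_temp_spread: float = 0.4
    #: SD of GCM precipitation anomalies (mm/month, mixed sign)
    gcm_prec_spread: float = 12.0
    anomaly_coarsen: int = 5
    #: amplitude of the smooth spatial temperature noise (degC)
    temp_noise_amp: float = 1.0

    def __post_init__(self) -> None:
        if self.n_gcms < 2:
            raise ValueError("n_gcms must be >= 2")
        if self.annual_total_mm <= 0:
            raise ValueError("annual total must be positive")
        if not 0.0 <= self.canicula_depth <= 1.0:
            raise ValueError("canicula depth must be in [0, 1]")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to [0, 1]."""
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    lo, hi = sm.min(), sm.max()
    return (sm - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def make_dem(cfg: SyntheticConfig) -> GridRaster:
    """Spatially smooth elevation surface, 0 .. dem_max_m.

    A west-east tilt is added so elevation correlates with longitude,
    giving contiguous lowland and highland sectors rather than isolated
    bumps.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    rows, cols = cfg.grid_shape
    rough = _smooth_field(rng, cfg.grid_shape, sigma=min(rows, cols) / 8)
    tilt = np.tile(np.linspace(0.0, 1.0, cols), (rows, 1))
    relief = 0.55 * rough + 0.45 * tilt
    relief = (relief - relief.min()) / (relief.max() - relief.min())
    dem = relief * cfg.dem_max_m
    return GridRaster(dem, cfg.origin, cfg.cell_size)


def make_baseline_climate(
        cfg: SyntheticConfig) -> tuple[MonthlyClimate, GridRaster]:
    """Baseline monthly climatology plus the DEM it is draped over.

    Temperatures fall with elevation at the configured lapse rate and follow
    a mild seasonal cycle peaking before the rains.  Rainfall follows the
    bimodal weights with the July-August canicula scaled down by
    ``canicula_depth``, modulated by a smooth per-pixel wetness multiplier
    shared by all months (so monthly ratios are spatially uniform).
    """
    dem = make_dem(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    rows, cols = cfg.grid_shape

    weights = _MONTH_WEIGHTS.copy()
    for m in _CANICULA_MONTHS:
        weights[m] *= (1.0 - cfg.canicula_depth)
    monthly_mm = weights / _MONTH_WEIGHTS.sum() * cfg.annual_total_mm

    wetness = 0.7 + 0.6 * _smooth_field(rng, (rows, cols),
                                        sigma=min(rows, cols) / 10)
    prec = monthly_mm[:, None, None] * wetness[None, :, :]

    lapse = cfg.lapse_rate_per_100m * dem.values / 100.0
    tnoise = cfg.temp_noise_amp * (_smooth_field(rng, (rows, cols),
                                                 sigma=min(rows, cols) / 10)
                                   - 0.5)
    tmax = (cfg.tmax_sealevel + _TSEASON[:, None, None]
            - lapse[None, :, :] + tnoise[None, :, :])
    tmin = (cfg.tmin_sealevel + 0.6 * _TSEASON[:, None, None]
            - lapse[None, :, :] + tnoise[None, :, :])

    mc = MonthlyClimate(prec, tmin, tmax, cfg.origin, cfg.cell_size)
    mc.check_invariants()
    return mc, dem


def make_gcm_anomalies(cfg: SyntheticConfig,
                       period: str) -> list[MonthlyClimate]:
    """Coarse monthly anomaly stacks for ``cfg.n_gcms`` pseudo-GCMs.

    period '2020s' centres the warming at +1.0 degC, '2050s' at +2.0 degC,
    with inter-model spread ``gcm_temp_spread``; precipitation anomalies are
    mixed-sign smooth fields of SD ``gcm_prec_spread`` mm/month.  Fields are
    generated at a grid ``anomaly_coarsen`` times coarser than the baseline.
    """
    centres = {"2020s": 1.0, "2050s": 2.0}
    if period not in centres:
        raise ValueError("period must be '2020s' or '2050s'")
    warm_centre = centres[period]
    rows, cols = cfg.grid_shape
    k = cfg.anomaly_coarsen
    crows = max(2, int(np.ceil(rows / k)))
    ccols = max(2, int(np.ceil(cols / k)))
    ccell = cfg.cell_size * k
    out: list[MonthlyClimate] = []
    base_ss = np.random.SeedSequence(
        [cfg.seed, 37, {"2020s": 0, "2050s": 1}[period]])
    # within-field spatial/seasonal variation scales with the spread
    # parameters, so zero spread yields identical, spatially flat anomalies
    for child in base_ss.spawn(cfg.n_gcms):
        rng = np.random.default_rng(child)
        warm = warm_centre + cfg.gcm_temp_spread * rng.standard_normal()
        dwarm = warm + 0.75 * cfg.gcm_temp_spread * (
            _smooth_field(rng, (crows, ccols), sigma=2.0) - 0.5)
        season = 0.5 * cfg.gcm_temp_spread * rng.standard_normal(12)
        dtmax = dwarm[None, :, :] + season[:, None, None]
        dtmin = dwarm[None, :, :] + 0.8 * season[:, None, None]
        dprec = cfg.gcm_prec_spread * 2.0 * (
            _smooth_field(rng, (crows, ccols), sigma=2.0) - 0.5)
        dprec = dprec[None, :, :] + 0.15 * cfg.gcm_prec_spread * (
            rng.standard_normal(12)[:, None, None])
        out.append(MonthlyClimate(dprec, dtmin, dtmax, cfg.origin, ccell))
    return out


def make_atlas_and_communities(
        cfg: SyntheticConfig,
        dem: GridRaster) -> tuple[AreaMask, pd.DataFrame]:
    """Growing-area mask in the mid-elevation band plus a community table.

    The mask is the elevation band intersected with a smooth patchiness
    field (so it is spatially fragmented like a real crop atlas).
    Communities are sampled at mask cells; their elevations are read off
    the DEM.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 51]))
    lo, hi = cfg.atlas_band_m
    band = (dem.values >= lo) & (dem.values <= hi)
    patch = _smooth_field(rng, dem.shape,
                          sigma=min(dem.shape) / 10) > 0.35
    mask_arr = (band & patch)
    if not mask_arr.any():
        raise RuntimeError("empty growing-area mask: adjust atlas band")
    atlas = AreaMask(GridRaster(mask_arr.astype(float), dem.origin,
                                dem.cell_size, dem.nodata))

    cand = np.argwhere(mask_arr)
    n = min(cfg.n_communities, len(cand))
    picks = cand[rng.choice(len(cand), size=n, replace=False)]
    recs = []
    for i, (r, c) in enumerate(picks):
        lon, lat = dem.cell_center(int(r), int(c))
        recs.append({"name": f"community_{i + 1:02d}", "lon": lon,
                     "lat": lat, "elevation_m": float(dem.values[r, c])})
    communities = pd.DataFrame(recs)
    return atlas, communities


def write_fixture_set(cfg: SyntheticConfig, outdir: str) -> dict[str, str]:
    """Generate and write the complete synthetic input set to a directory."""
    os.makedirs(outdir, exist_ok=True)
    baseline, dem = make_baseline_climate(cfg)
    atlas, communities = make_atlas_and_communities(cfg, dem)
    paths = {
        "baseline": os.path.join(outdir, "baseline_climate.nc"),
        "dem": os.path.join(outdir, "dem.asc"),
        "atlas": os.path.join(outdir, "atlas_mask.asc"),
        "communities": os.path.join(outdir, "communities.csv"),
    }
    write_monthly_climate(baseline, paths["baseline"])
    write_raster(dem, paths["dem"])
    write_raster(atlas.mask, paths["atlas"])
    communities.to_csv(paths["communities"], index=False)
    for period in ("2020s", "2050s"):
        anoms = make_gcm_anomalies(cfg, period)
        for g, anom in enumerate(anoms):
            p = os.path.join(outdir, f"anomaly_{period}_gcm{g:02d}.nc")
            write_monthly_climate(anom, p)
            paths[f"anomaly_{period}_gcm{g:02d}"] = p
    return paths
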