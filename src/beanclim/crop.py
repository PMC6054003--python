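"""Water- and temperature-limited drybean yield emulator.

A deliberately simple seasonal model standing in for a full process crop
model, but honouring the regional management protocol: a sowing window with
a 50 % available-soil-water trigger, soil water initialised at the -1.5 MPa
lower limit 60 days before the window, a 2 cultivars x 2 soils x 2
fertilizer factorial (8 treatments), and replicate-year averaging.

Yield is

    Y = Y_pot * f_fert * mean_t(water stress factor) * mean_t(temperature
        suitability)

over the cultivar's growing duration from the sowing day.  Water stress is
the daily transpiration fraction of a single-layer soil water bucket;
temperature suitability is a trapezoid on cardinal temperatures applied to
the daily mean, with an extra penalty on days whose maximum exceeds the
crop's ceiling temperature.  Any yield model honouring ``run_grid``'s
interface is interchangeable with this one downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .raster import AreaMask, GridRaster
from .downscale import ScenarioClimate
from . import weather as wg


@dataclass(frozen=True)
class SoilProfile:
    """Single-layer bucket soil: 300 mm top layer drives the sowing trigger."""

    name: str
    depth_mm: float = 300.0
    ll: float = 0.10           # volumetric water at -1.5 MPa
    dul: float = 0.24          # drained upper limit
    runoff_frac: float = 0.12  # fraction of daily rain lost to runoff

    def __post_init__(self) -> None:
        if not 0.0 < self.ll < self.dul < 1.0:
            raise ValueError("need 0 < ll < dul < 1")

    @property
    def water_min(self) -> float:
        return self.ll * self.depth_mm

    @property
    def water_max(self) -> float:
        return self.dul * self.depth_mm

    @property
    def capacity(self) -> float:
        return (self.dul - self.ll) * self.depth_mm


MEDIUM_SILTY_LOAM = SoilProfile("medium_silty_loam", ll=0.11, dul=0.26,
                                runoff_frac=0.10)
MEDIUM_SANDY_LOAM = SoilProfile("medium_sandy_loam", ll=0.07, dul=0.19,
                                runoff_frac=0.15)

#: fertilizer yield multipliers; the unfertilized multiplier reflects
#: rain-fed Central American bean yields reaching about a third of the
#: fully fertilized (128 kg/ha 18-46-00) level
FERT_MULTIPLIER = {"none": 0.34, "F1": 0.70, "F2": 1.00}


@dataclass(frozen=True)
class CultivarParams:
    """Cardinal temperatures and potential yield of a cultivar."""

    name: str
    duration_days: int = 75
    t_base: float = 8.0
    t_opt_lo: float = 20.0
    t_opt_hi: float = 28.0
    t_max: float = 35.0
    potential_yield: float = 2800.0  # kg/ha
    heat_sens: float = 0.15          # suitability lost per degC above t_max

    def __post_init__(self) -> None:
        if not (self.t_base < self.t_opt_lo <= self.t_opt_hi < self.t_max):
            raise ValueError("cardinal temperatures out of order")
        if self.potential_yield <= 0:
            raise ValueError("potential yield must be positive")


ICTA_OSTUA = CultivarParams("ICTA_OSTUA", duration_days=75,
                            potential_yield=2800.0)
BAT1289 = CultivarParams("BAT1289", duration_days=70,
                         potential_yield=2600.0)


@dataclass(frozen=True)
class Treatment:
    cultivar: CultivarParams
    soil: SoilProfile
    fertilizer: str = "F2"      # one of FERT_MULTIPLIER keys
    sidedress_n: float = 30.0   # kg N/ha at 22 days after sowing (F1/F2)

    def __post_init__(self) -> None:
        if self.fertilizer not in FERT_MULTIPLIER:
            raise ValueError(f"unknown fertilizer level {self.fertilizer}")

    @property
    def label(self) -> str:
        return f"{self.cultivar.name}|{self.soil.name}|{self.fertilizer}"


def treatment_factorial(
        cultivars=(ICTA_OSTUA, BAT1289),
        soils=(MEDIUM_SILTY_LOAM, MEDIUM_SANDY_LOAM),
        fertilizers=("F1", "F2")) -> list[Treatment]:
    """The full 2 x 2 x 2 management design (8 treatments by default)."""
    return [Treatment(c, s, f) for c, s, f
            in itertools.product(cultivars, soils, fertilizers)]


@dataclass(frozen=True)
class SeasonWindow:
    """A sowing window, inclusive day-of-year bounds (365-day calendar)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= 365 and 1 <= self.end <= 365
                and self.start <= self.end):
            raise ValueError("invalid season window")


PRIMERA = SeasonWindow("primera", 105, 181)    # 15 Apr - 30 Jun
POSTRERA = SeasonWindow("postrera", 232, 273)  # 20 Aug - 30 Sep
APANTE = SeasonWindow("apante", 298, 339)      # 25 Oct - 5 Dec
SEASONS = {"primera": PRIMERA, "postrera": POSTRERA, "apante": APANTE}


# ---------------------------------------------------------------------------
# soil water bucket
# ---------------------------------------------------------------------------

def water_balance_step(state: float | np.ndarray, rain, et_demand,
                       soil: SoilProfile):
    """One daily step of the single-layer bucket.

    Adds rain net of runoff (capped at the drained upper limit; excess
    drains), then removes actual ET = demand * min(1, ASW / (0.5 *
    capacity)).  Returns (new state, transpiration fraction actual/demand).
    Vectorises over years when given arrays.
    """
    rain = np.asarray(rain, dtype=float)
    if np.any(rain < 0):
        raise ValueError("negative rain")
    state = np.asarray(state, dtype=float)
    et_demand = np.asarray(et_demand, dtype=float)
    water = np.minimum(state + rain * (1.0 - soil.runoff_frac),
                       soil.water_max)
    asw = water - soil.water_min
    supply_frac = np.minimum(1.0, asw / (0.5 * soil.capacity))
    et = et_demand * supply_frac
    new = np.maximum(water - et, soil.water_min)
    frac = np.where(et_demand > 0, supply_frac, 1.0)
    if state.ndim == 0:
        return float(new), float(frac)
    return new, frac


def asw_fraction(state, soil: SoilProfile):
    """Available soil water as a fraction of capacity, in [0, 1]."""
    return np.clip((np.asarray(state, dtype=float) - soil.water_min)
                   / soil.capacity, 0.0, 1.0)


def reference_et(tmax, tmin, srad):
    """Hargreaves-type reference ET (mm/day) from temperature and radiation."""
    tmean = (np.asarray(tmax) + np.asarray(tmin)) / 2.0
    return np.maximum(0.0135 * (tmean + 17.8) * np.asarray(srad) / 2.45, 0.0)


def crop_coefficient(days_after_sowing: np.ndarray,
                     duration: int) -> np.ndarray:
    """Stage-dependent Kc: 0.4 establishment, 1.05 mid, 0.7 late."""
    das = np.asarray(days_after_sowing, dtype=float)
    frac = das / duration
    return np.where(frac < 0.25, 0.4, np.where(frac < 0.75, 1.05, 0.7))


# ---------------------------------------------------------------------------
# sowing and yield
# ---------------------------------------------------------------------------

SPINUP_DAYS = 60
BARE_SOIL_ET_FRAC = 0.5  # evaporative demand before canopy, x reference ET


def _circ(doys: np.ndarray) -> np.ndarray:
    """Map day-of-year offsets onto 0..364 circularly (same replicate year)."""
    return np.mod(doys - 1, 365)


def find_sowing_day(year: "wg.DailyWeatherSeries", window: SeasonWindow,
                    soil: SoilProfile) -> int | None:
    """First window day whose available soil water reaches 50 %.

    The bucket starts at the lower limit 60 days before the window opens
    (wrapping circularly within the same replicate year) and is driven by
    bare-soil evaporative demand.  Returns a day-of-year, or None.
    """
    sow = find_sowing_days(year, window, soil)
    d = int(sow[0])
    return d if d > 0 else None


def find_sowing_days(series: "wg.DailyWeatherSeries", window: SeasonWindow,
                     soil: SoilProfile) -> np.ndarray:
    """Vectorised sowing search over replicate years; 0 marks no sowing."""
    n = series.n_years
    state = np.full(n, soil.water_min)
    days = _circ(np.arange(window.start - SPINUP_DAYS, window.end + 1))
    sow = np.zeros(n, dtype=int)
    for i, d in enumerate(days):
        demand = BARE_SOIL_ET_FRAC * reference_et(
            series.tmax[:, d], series.tmin[:, d], series.srad[:, d])
        state, _ = water_balance_step(state, series.rain[:, d], demand, soil)
        doy = d + 1
        if i >= SPINUP_DAYS:  # inside the window
            ready = (asw_fraction(state, soil) >= 0.5) & (sow == 0)
            sow[ready] = doy
    return sow


def temperature_suitability(tmean, tmax_day, cv: CultivarParams):
    """Trapezoid on daily mean T, with a heat penalty above the ceiling."""
    t = np.asarray(tmean, dtype=float)
    up = np.clip((t - cv.t_base) / (cv.t_opt_lo - cv.t_base), 0.0, 1.0)
    down = np.clip((cv.t_max - t) / (cv.t_max - cv.t_opt_hi), 0.0, 1.0)
    trap = np.minimum(up, down)
    heat = np.clip(1.0 - cv.heat_sens
                   * np.maximum(0.0, np.asarray(tmax_day) - cv.t_max),
                   0.0, 1.0)
    return trap * heat


def simulate_yield(year: "wg.DailyWeatherSeries", sow_day: int | None,
                   treatment: Treatment) -> float:
    """Seasonal yield (kg/ha) for a single replicate year; 0 if no sowing."""
    ylds = simulate_yields(year, np.array([sow_day or 0]), treatment)
    return float(ylds[0])


def simulate_yields(series: "wg.DailyWeatherSeries", sow_days: np.ndarray,
                    treatment: Treatment) -> np.ndarray:
    """Vectorised over replicate years; sow_days of 0 yield 0."""
    cv = treatment.cultivar
    soil = treatment.soil
    n = series.n_years
    sow = np.asarray(sow_days, dtype=int)
    active = sow > 0
    ylds = np.zeros(n)
    if not active.any():
        return ylds
    state = np.full(n, soil.water_min)
    # bring soil to sowing-day state: spin from 60 d before each year's
    # sowing; approximate with a common spin from the earliest sowing day
    start = int(sow[active].min())
    spin = _circ(np.arange(start - SPINUP_DAYS, start))
    for d in spin:
        demand = BARE_SOIL_ET_FRAC * reference_et(
            series.tmax[:, d], series.tmin[:, d], series.srad[:, d])
        state, _ = water_balance_step(state, series.rain[:, d], demand, soil)

    wsum = np.zeros(n)
    tsum = np.zeros(n)
    cnt = np.zeros(n)
    horizon = int(sow[active].max()) - start + cv.duration_days
    for i in range(horizon):
        d = _circ(np.array([start + i]))[0]
        doy = d + 1
        das = (start + i) - sow + 1          # days after sowing, per year
        growing = active & (das >= 1) & (das <= cv.duration_days)
        kc = np.where(growing,
                      crop_coefficient(np.maximum(das, 1), cv.duration_days),
                      BARE_SOIL_ET_FRAC)
        demand = kc * reference_et(series.tmax[:, d], series.tmin[:, d],
                                   series.srad[:, d])
        state, frac = water_balance_step(state, series.rain[:, d],
                                         demand, soil)
        tmean = (series.tmax[:, d] + series.tmin[:, d]) / 2.0
        tsuit = temperature_suitability(tmean, series.tmax[:, d], cv)
        wsum += np.where(growing, frac, 0.0)
        tsum += np.where(growing, tsuit, 0.0)
        cnt += growing
    ok = cnt > 0
    wmean = np.where(ok, wsum / np.maximum(cnt, 1), 0.0)
    tmean_f = np.where(ok, tsum / np.maximum(cnt, 1), 0.0)
    ylds = (cv.potential_yield * FERT_MULTIPLIER[treatment.fertilizer]
            * wmean * tmean_f)
    return np.where(active, ylds, 0.0)


# ---------------------------------------------------------------------------
# gridded runs
# ---------------------------------------------------------------------------

def run_pixel(prec: np.ndarray, tmin: np.ndarray, tmax: np.ndarray,
              latitude: float, season: SeasonWindow,
              treatments: list[Treatment], n_years: int,
              seed) -> dict[str, float]:
    """Mean yield over replicate years for each treatment at one pixel."""
    params = wg.calibrate(prec, tmin, tmax, latitude=latitude)
    series = wg.generate(params, n_years=n_years, seed=seed)
    out: dict[str, float] = {}
    sow_by_soil: dict[str, np.ndarray] = {}
    # fertilizer is a pure multiplier, so the stress simulation only needs
    # to run once per (cultivar, soil) pair
    base_yield: dict[tuple[str, str], float] = {}
    for t in treatments:
        if t.soil.name not in sow_by_soil:
            sow_by_soil[t.soil.name] = find_sowing_days(series, season,
                                                        t.soil)
        key = (t.cultivar.name, t.soil.name)
        if key not in base_yield:
            ref = replace(t, fertilizer="F2")
            ylds = simulate_yields(series, sow_by_soil[t.soil.name], ref)
            base_yield[key] = float(ylds.mean()) / FERT_MULTIPLIER["F2"]
        out[t.label] = base_yield[key] * FERT_MULTIPLIER[t.fertilizer]
    return out


def run_grid(scenario: ScenarioClimate, season: SeasonWindow,
             treatments: list[Treatment], n_years: int, seed: int,
             mask: AreaMask | None = None) -> dict[str, GridRaster]:
    """Per-treatment mean-yield surfaces over all (masked) pixels.

    Weather is generated independently per pixel with a seed derived from
    ``seed`` and the pixel index, so results are deterministic and
    insensitive to evaluation order.
    """
    if not treatments:
        raise ValueError("treatments must be non-empty")
    mc = scenario.climate
    geom = mc.geometry_raster()
    if mask is not None and not mask.mask.same_geometry(geom):
        raise ValueError("mask geometry differs from climate geometry")
    valid = mc.valid if mask is None else (mc.valid & mask.boolean)
    surfaces = {t.label: np.full(mc.shape, mc.nodata) for t in treatments}
    for r, c in np.argwhere(valid):
        _, lat = geom.cell_center(int(r), int(c))
        prec, tmn, tmx = mc.pixel(int(r), int(c))
        ss = np.random.SeedSequence([int(seed), int(r), int(c)])
        ylds = run_pixel(prec, tmn, tmx, lat, season, treatments,
                         n_years, ss)
        for label, y in ylds.items():
            surfaces[label][r, c] = y
    return {label: GridRaster(vals, mc.origin, mc.cell_size, mc.nodata)
            for label, vals in surfaces.items()}
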