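"""Stochastic daily weather generation from monthly climate normals.

Rainfall occurrence follows an order-k (k = 1..3, default 3) wet/dry Markov
chain whose transition probability is linear in the recent wet/dry history:

    p(wet | history) = p_wet + r * (wbar(history) - p_wet)

where ``p_wet`` is the month's unconditional wet-day probability, ``r`` the
persistence, and ``wbar`` a geometrically weighted mean of the previous k
wet/dry indicators (most recent heaviest).  Because the dependence on the
history indicators is linear, the stationary wet-day frequency equals
``p_wet`` exactly for any order and persistence, so monthly rainfall totals
are preserved in expectation by construction.

Wet-day amounts are gamma distributed per month; expected wet days per
month are tied to the monthly total P by an empirical power law
``W = a * P^b`` (a = 0.7, b = 0.55, capped at the days in the month), and
the gamma scale is set so the expected monthly sum matches P.

Daily temperatures are monthly normals interpolated to days plus Gaussian
deviates; solar radiation is the extraterrestrial envelope for the latitude
and day of year times a dry/wet-day transmissivity.  Years have 365 days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_OF_DOY = np.repeat(np.arange(12), DAYS_IN_MONTH)  # 365 entries
MID_DOY = np.cumsum(DAYS_IN_MONTH) - DAYS_IN_MONTH / 2.0

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1


@dataclass
class WeatherGenParams:
    """Calibrated per-pixel generator parameters."""

    p_wet: np.ndarray                 # [12] unconditional wet-day prob
    rain_shape: np.ndarray            # [12] gamma shape
    rain_scale: np.ndarray            # [12] gamma scale, mm
    tmax_month: np.ndarray            # [12] monthly mean daily max, degC
    tmin_month: np.ndarray            # [12] monthly mean daily min, degC
    markov_order: int = 3
    persistence: float = 0.25
    temp_sd: float = 1.2
    tau_dry: float = 0.70             # clear-sky transmissivity, dry days
    tau_wet: float = 0.45             # wet days
    latitude: float = 13.0

    def transition_prob(self, month: int, history: tuple[int, ...]) -> float:
        """p(wet | last-k wet/dry indicators), most recent last."""
        k = self.markov_order
        h = history[-k:]
        w = _history_weights(k)[-len(h):]
        wbar = float(np.dot(w, h) / w.sum())
        p = self.p_wet[month]
        return float(p + self.persistence * (wbar - p))


def _history_weights(k: int) -> np.ndarray:
    """Geometric weights over the last k days, most recent heaviest."""
    return 0.5 ** np.arange(k - 1, -1, -1, dtype=float)


@dataclass
class DailyWeatherSeries:
    """Replicate years of daily weather, each array shaped (n_years, 365)."""

    rain: np.ndarray
    tmax: np.ndarray
    tmin: np.ndarray
    srad: np.ndarray

    @property
    def n_years(self) -> int:
        return self.rain.shape[0]

    def year(self, i: int) -> "DailyWeatherSeries":
        return DailyWeatherSeries(self.rain[i:i + 1], self.tmax[i:i + 1],
                                  self.tmin[i:i + 1], self.srad[i:i + 1])


def expected_wet_days(monthly_total: np.ndarray, a: float = 0.7,
                      b: float = 0.55) -> np.ndarray:
    """Empirical wet-day count from monthly rainfall total, capped."""
    P = np.asarray(monthly_total, dtype=float)
    return np.minimum(np.where(P > 0, a * P ** b, 0.0),
                      DAYS_IN_MONTH.astype(float))


def calibrate(prec: np.ndarray, tmin: np.ndarray, tmax: np.ndarray,
              order: int = 3, rain_shape: float = 0.8,
              persistence: float = 0.25, temp_sd: float = 1.2,
              latitude: float = 13.0) -> WeatherGenParams:
    """Fit generator parameters to 12 monthly normals (deterministic).

    The gamma scale is solved so the expected monthly rainfall
    ``days * p_wet * shape * scale`` equals the input total exactly.
    """
    prec = np.asarray(prec, dtype=float)
    if prec.shape != (12,):
        raise ValueError("need 12 monthly precipitation values")
    if np.any(prec < 0):
        raise ValueError("negative monthly rainfall")
    if order not in (1, 2, 3):
        raise ValueError("markov order must be 1, 2 or 3")
    W = expected_wet_days(prec)
    p_wet = W / DAYS_IN_MONTH
    shape = np.full(12, rain_shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(W > 0, prec / (W * rain_shape), 1.0)
    return WeatherGenParams(
        p_wet=p_wet, rain_shape=shape, rain_scale=scale,
        tmax_month=np.asarray(tmax, dtype=float),
        tmin_month=np.asarray(tmin, dtype=float),
        markov_order=order, persistence=persistence, temp_sd=temp_sd,
        latitude=latitude)


def _daily_from_monthly(monthly: np.ndarray) -> np.ndarray:
    """Linear interpolation of 12 mid-month values to 365 days (periodic)."""
    x = np.concatenate([[MID_DOY[-1] - 365.0], MID_DOY, [MID_DOY[0] + 365.0]])
    y = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
    return np.interp(np.arange(1, 366, dtype=float), x, y)


def extraterrestrial_radiation(latitude: float,
                               doy: np.ndarray) -> np.ndarray:
    """Daily top-of-atmosphere solar radiation Ra, MJ/m2/day (FAO-56)."""
    phi = math.radians(latitude)
    doy = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (24 * 60 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta)
        + np.cos(phi) * np.cos(delta) * np.sin(ws))
    return np.maximum(ra, 0.1)


def generate(params: WeatherGenParams, n_years: int = 99,
             seed: int | np.random.SeedSequence = 0) -> DailyWeatherSeries:
    """Generate replicate years of daily weather (reproducible by seed)."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    k = params.markov_order
    r = params.persistence
    weights = _history_weights(k)
    wsum = weights.sum()

    month = MONTH_OF_DOY
    p_wet_day = params.p_wet[month]            # [365]

    # occurrence: loop over days, vectorized over years
    wet = np.zeros((n_years, 365), dtype=bool)
    hist = rng.random((n_years, k)) < params.p_wet[0]
    for d in range(365):
        wbar = (hist * weights).sum(axis=1) / wsum
        p = p_wet_day[d] + r * (wbar - p_wet_day[d])
        wet[:, d] = rng.random(n_years) < p
        hist = np.roll(hist, -1, axis=1)
        hist[:, -1] = wet[:, d]

    shape_day = params.rain_shape[month]
    scale_day = params.rain_scale[month]
    amounts = rng.gamma(np.broadcast_to(shape_day, wet.shape),
                        np.broadcast_to(scale_day, wet.shape))
    rain = np.where(wet, amounts, 0.0)

    tmax_base = _daily_from_monthly(params.tmax_month)
    tmin_base = _daily_from_monthly(params.tmin_month)
    common = params.temp_sd * rng.standard_normal(wet.shape)
    spread = 0.5 * params.temp_sd * rng.standard_normal(wet.shape)
    tmax = tmax_base + common + spread
    tmin = tmin_base + common - spread
    tmin = np.minimum(tmin, tmax - 0.1)

    doy = np.arange(1, 366)
    ra = extraterrestrial_radiation(params.latitude, doy)
    tau = np.where(wet, params.tau_wet, params.tau_dry)
    tau = tau * (1.0 + 0.05 * rng.standard_normal(wet.shape))
    srad = np.maximum(ra * np.clip(tau, 0.05, 0.85), 0.1)

    return DailyWeatherSeries(rain=rain, tmax=tmax, tmin=tmin, srad=srad)


# ---------------------------------------------------------------------------
# DSSAT weather files
# ---------------------------------------------------------------------------

def write_wth(series: DailyWeatherSeries, path: str, insi: str = "SYNT",
              lat: float = 13.0, lon: float = -86.0,
              elev: float = 0.0) -> None:
    """Write a DSSAT .WTH fixed-width weather file (365-day years).

    TAV is the mean of (tmax+tmin)/2 over the whole series; AMP the
    amplitude (max - min) of the monthly means of daily mean temperature.
    """
    tmean = (series.tmax + series.tmin) / 2.0
    tav = float(tmean.mean())
    monthly_means = [tmean[:, MONTH_OF_DOY == m].mean() for m in range(12)]
    amp = float(max(monthly_means) - min(monthly_means))
    with open(path, "w") as fh:
        fh.write(f"*WEATHER DATA : {insi}\n")
        fh.write("@ INSI      LAT     LONG  ELEV   TAV   AMP REFHT WNDHT\n")
        fh.write(f"  {insi:<4s} {lat:8.3f} {lon:8.3f} {elev:5.0f} "
                 f"{tav:5.1f} {amp:5.1f}  2.00  2.00\n")
        fh.write("@DATE  SRAD  TMAX  TMIN  RAIN\n")
        for y in range(series.n_years):
            yy = (y + 1) % 100
            for d in range(365):
                date = yy * 1000 + d + 1
                fh.write(f"{date:05d} {series.srad[y, d]:5.1f} "
                         f"{series.tmax[y, d]:5.1f} "
                         f"{series.tmin[y, d]:5.1f} "
                         f"{series.rain[y, d]:5.1f}\n")


def read_wth(path: str) -> tuple[DailyWeatherSeries, dict]:
    """Parse a .WTH file written by :func:`write_wth` (round-trip tested)."""
    meta: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("@ INSI"):
            parts = lines[i + 1].split()
            meta = {"insi": parts[0], "lat": float(parts[1]),
                    "lon": float(parts[2]), "elev": float(parts[3]),
                    "tav": float(parts[4]), "amp": float(parts[5])}
        elif line.startswith("@DATE"):
            for rec in lines[i + 1:]:
                p = rec.split()
                if len(p) == 5:
                    rows.append([float(v) for v in p[1:]])
            break
    arr = np.array(rows)
    n_years = arr.shape[0] // 365
    shp = (n_years, 365)
    return DailyWeatherSeries(
        srad=arr[:, 0].reshape(shp), tmax=arr[:, 1].reshape(shp),
        tmin=arr[:, 2].reshape(shp), rain=arr[:, 3].reshape(shp)), meta
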