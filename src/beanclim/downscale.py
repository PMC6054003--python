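"""Delta-method downscaling of coarse monthly anomalies.

Coarse GCM anomalies are bilinearly interpolated (between coarse cell
centres, with edge replication outside them) to the fine baseline geometry
and added to the baseline climatology: temperatures additively in degC,
precipitation additively in mm with a floor at zero (or multiplicatively,
as a fractional change, if requested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .raster import GridRaster, MonthlyClimate


@dataclass
class ScenarioClimate:
    """A monthly climate labelled with its scenario (baseline or GCM x period)."""

    climate: MonthlyClimate
    label: str = "baseline"


def interpolate_to(coarse: GridRaster, target: GridRaster) -> np.ndarray:
    """Bilinear interpolation of a coarse layer onto a target geometry.

    Interpolates between coarse cell centres; beyond the outermost centres
    the edge value is replicated.
    """
    crows, ccols = coarse.shape
    clat = coarse.origin[1] - (np.arange(crows) + 0.5) * coarse.cell_size
    clon = coarse.origin[0] + (np.arange(ccols) + 0.5) * coarse.cell_size
    # lat decreases with row; flip to ascending for the interpolator
    interp = RegularGridInterpolator(
        (clat[::-1], clon), coarse.values[::-1, :],
        method="linear", bounds_error=False, fill_value=None)
    lon_t, lat_t = target.cell_centers()
    lat_q = np.clip(lat_t, clat[-1], clat[0])
    lon_q = np.clip(lon_t, clon[0], clon[-1])
    pts = np.column_stack([lat_q.ravel(), lon_q.ravel()])
    return interp(pts).reshape(target.shape)


def _check_extent(anomaly: MonthlyClimate, baseline: MonthlyClimate) -> None:
    a_lon0, a_lat0 = anomaly.origin
    b_lon0, b_lat0 = baseline.origin
    a_rows, a_cols = anomaly.shape
    b_rows, b_cols = baseline.shape
    a_lon1 = a_lon0 + a_cols * anomaly.cell_size
    a_lat1 = a_lat0 - a_rows * anomaly.cell_size
    b_lon1 = b_lon0 + b_cols * baseline.cell_size
    b_lat1 = b_lat0 - b_rows * baseline.cell_size
    # half-cell slack: interpolation extrapolates only by edge replication
    slack = anomaly.cell_size
    if (a_lon0 > b_lon0 + slack or a_lon1 < b_lon1 - slack
            or a_lat0 < b_lat0 - slack or a_lat1 > b_lat1 + slack):
        raise ValueError("anomaly grid does not cover baseline extent")


def downscale(baseline: MonthlyClimate, anomaly: MonthlyClimate,
              label: str = "scenario",
              mult_precip: bool = False) -> ScenarioClimate:
    """Add interpolated monthly anomalies to the baseline climatology.

    Parameters
    ----------
    baseline : MonthlyClimate
        Fine-resolution climatology.
    anomaly : MonthlyClimate
        Coarse anomaly stack (temperature in degC; precipitation in mm, or
        as a fractional change if ``mult_precip``).
    mult_precip : bool
        If True, precipitation anomalies are applied multiplicatively as
        ``prec * (1 + delta)``; default is additive with a floor at 0 mm.
    """
    _check_extent(anomaly, baseline)
    geom = baseline.geometry_raster()
    prec = np.empty_like(baseline.prec)
    tmin = np.empty_like(baseline.tmin)
    tmax = np.empty_like(baseline.tmax)
    for m in range(12):
        dp = interpolate_to(anomaly.layer("prec", m), geom)
        dn = interpolate_to(anomaly.layer("tmin", m), geom)
        dx = interpolate_to(anomaly.layer("tmax", m), geom)
        if mult_precip:
            prec[m] = baseline.prec[m] * np.maximum(0.0, 1.0 + dp)
        else:
            prec[m] = np.maximum(0.0, baseline.prec[m] + dp)
        tmin[m] = baseline.tmin[m] + dn
        tmax[m] = baseline.tmax[m] + dx
    climate = MonthlyClimate(prec, tmin, tmax, baseline.origin,
                             baseline.cell_size, baseline.nodata)
    return ScenarioClimate(climate, label)


def ensemble_mean_climate(
        scenarios: list[ScenarioClimate],
        label: str = "ensemble_mean") -> ScenarioClimate:
    """Per-layer, per-cell arithmetic mean of scenario climates."""
    if not scenarios:
        raise ValueError("need at least one scenario")
    first = scenarios[0].climate
    for s in scenarios[1:]:
        if s.climate.shape != first.shape or \
                abs(s.climate.cell_size - first.cell_size) > 1e-9:
            raise ValueError("scenario geometries differ")
    prec = np.mean([s.climate.prec for s in scenarios], axis=0)
    tmin = np.mean([s.climate.tmin for s in scenarios], axis=0)
    tmax = np.mean([s.climate.tmax for s in scenarios], axis=0)
    return ScenarioClimate(
        MonthlyClimate(prec, tmin, tmax, first.origin, first.cell_size,
                       first.nodata), label)
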