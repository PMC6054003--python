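"""Climate-model ensemble uncertainty and seasonal/zonal summaries.

Per-pixel metrics over the GCM ensemble of yield-change fields: ensemble
mean change, sample standard deviation, and directional agreement (the
percentage of models predicting change in the majority direction, with
zero counted as non-negative, so agreement is always in [50, 100]).
Zonal summaries mirror country/municipality tables: mean percent change
per zone and season, and the fraction of zones with losses beyond a
threshold, both over all zones and over the top-production zones that
together hold half of total baseline production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import GridRaster


@dataclass
class EnsembleMetrics:
    mean_change: GridRaster
    sd_change: GridRaster
    agreement: GridRaster  # % in [50, 100]


def ensemble_metrics(changes: list[GridRaster]) -> EnsembleMetrics:
    """Per-pixel mean, sample SD (n-1) and % directional agreement."""
    if len(changes) < 2:
        raise ValueError("need at least 2 ensemble members")
    first = changes[0]
    for c in changes[1:]:
        if not c.same_geometry(first):
            raise ValueError("ensemble member geometries differ")
    stack = np.stack([c.masked() for c in changes])
    ok = np.all(np.isfinite(stack), axis=0)
    n = len(changes)
    filled = np.where(np.isfinite(stack), stack, 0.0)
    mean = np.where(ok, filled.mean(axis=0), first.nodata)
    sd = np.where(ok, filled.std(axis=0, ddof=1), first.nodata)
    neg = np.sum(stack < 0, axis=0)
    agree = 100.0 * np.maximum(neg, n - neg) / n
    agree = np.where(ok, agree, first.nodata)
    return EnsembleMetrics(first.with_values(mean), first.with_values(sd),
                           first.with_values(agree))


def fertilizer_response(no_fert: GridRaster,
                        full_fert: GridRaster) -> GridRaster:
    """Per-pixel ratio of unfertilized to fully fertilized (F2) yield."""
    if not no_fert.same_geometry(full_fert):
        raise ValueError("geometries differ")
    a, b = no_fert.masked(), full_fert.masked()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b > 0, np.clip(a / b, 0.0, 1.0), np.nan)
    return no_fert.with_values(
        np.where(np.isfinite(ratio), ratio, no_fert.nodata))


def top_production_zones(production: dict[int, float],
                         fraction: float = 0.5) -> set[int]:
    """Greedy prefix of zones, by descending production, reaching the
    requested fraction of the total."""
    total = sum(production.values())
    if total <= 0:
        return set(production)
    chosen: set[int] = set()
    acc = 0.0
    for zone in sorted(production, key=production.get, reverse=True):
        chosen.add(zone)
        acc += production[zone]
        if acc >= fraction * total:
            break
    return chosen


def season_summary(rel_changes: dict[str, GridRaster],
                   zones: GridRaster,
                   baseline_yield: GridRaster,
                   loss_threshold_pct: float = 10.0) -> pd.DataFrame:
    """Zonal mean % change per season, plus loss-exceedance fractions.

    Parameters
    ----------
    rel_changes : mapping season name -> relative (%) change raster.
    zones : integer zone-id raster aligned with the change fields.
    baseline_yield : raster used as the production proxy for the
        "zones holding 50 % of production" subset.
    loss_threshold_pct : loss (positive number, %) defining exceedance.

    Returns a table with one row per season: per-zone mean changes, the %
    of zones whose mean loss exceeds the threshold, and the same % within
    the top-production subset.
    """
    some = next(iter(rel_changes.values()))
    if not zones.same_geometry(some):
        raise ValueError("zones raster misaligned with change fields")
    zvals = zones.values
    zone_ids = sorted(int(z) for z in np.unique(zvals[zones.valid]))
    base = baseline_yield.masked()
    production = {}
    for zid in zone_ids:
        cells = (zvals == zid) & zones.valid
        prod = np.nansum(np.where(cells, base, 0.0))
        if np.isfinite(prod):
            production[zid] = float(prod)
    top = top_production_zones(production)

    records = []
    for season, rel in rel_changes.items():
        relv = rel.masked()
        zone_means = {}
        for zid in zone_ids:
            cells = (zvals == zid) & zones.valid & np.isfinite(relv)
            if not cells.any():
                continue  # empty zone: omitted
            zone_means[zid] = float(np.mean(relv[cells]))
        if not zone_means:
            continue
        losses = {z: -m for z, m in zone_means.items()}
        n_all = len(zone_means)
        n_exc = sum(1 for v in losses.values() if v > loss_threshold_pct)
        top_zones = [z for z in zone_means if z in top]
        n_exc_top = sum(1 for z in top_zones
                        if losses[z] > loss_threshold_pct)
        records.append({
            "season": season,
            "mean_change_pct": float(np.mean(list(zone_means.values()))),
            "pct_zones_loss_gt_threshold": 100.0 * n_exc / n_all,
            "pct_top_production_zones_loss_gt_threshold":
                100.0 * n_exc_top / max(len(top_zones), 1),
            "n_zones": n_all,
        })
    return pd.DataFrame.from_records(records)
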