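"""High-impact-spot (HIS) classification of yield-change surfaces.

The yield change (future minus baseline, mean of the management
treatments) is standardised either by a robust root-mean-square scaling of
the pixel population (default) or by the Getis-Ord local Gi* statistic of
spatial association, and classified:

* **hotspot** — z <= -2 (beyond the 95 % band on the loss side); reported
  within the current growing areas;
* **adaptation spot** — -2 < z <= -1 (beyond the 68 % band); within
  growing areas;
* **pressure spot** — z >= +1 on the gain side; reported everywhere, since
  such pixels mostly lie outside the present growing zone.

Also provides the kernel-density growing-area overlay and the study-site
pixel selection (distance / atlas / elevation triple filter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import AreaMask, GridRaster, haversine_km

CATEGORY_CODES = {"none": 0, "adaptation": 1, "hotspot": 2, "pressure": 3}


@dataclass
class YieldChangeField:
    """Per-pixel yield change, future - baseline (kg/ha and % of baseline)."""

    delta: GridRaster
    relative: GridRaster


@dataclass
class SpotClassification:
    z: GridRaster
    category: GridRaster          # integer codes per CATEGORY_CODES
    method: str

    def category_mask(self, name: str) -> np.ndarray:
        return (self.category.valid
                & (self.category.values == CATEGORY_CODES[name]))


def mean_surface(surfaces: dict[str, GridRaster] | list[GridRaster]
                 ) -> GridRaster:
    """Per-pixel mean over treatment surfaces (nodata where any is missing)."""
    items = list(surfaces.values()) if isinstance(surfaces, dict) \
        else list(surfaces)
    first = items[0]
    stack = np.stack([s.masked() for s in items])
    ok = np.all(np.isfinite(stack), axis=0)
    mean = stack.mean(axis=0)  # NaN wherever any layer is missing
    return first.with_values(np.where(ok, mean, first.nodata))


def yield_change(future: dict[str, GridRaster],
                 baseline: dict[str, GridRaster]) -> YieldChangeField:
    """Treatment-mean change field from matching treatment surface sets."""
    if set(future) != set(baseline):
        raise ValueError("treatment sets differ between scenarios")
    fmean = mean_surface(future)
    bmean = mean_surface(baseline)
    if not fmean.same_geometry(bmean):
        raise ValueError("scenario geometries differ")
    f, b = fmean.masked(), bmean.masked()
    delta = f - b
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(b != 0, 100.0 * delta / b, np.nan)
    nod = fmean.nodata
    return YieldChangeField(
        delta=fmean.with_values(np.where(np.isfinite(delta), delta, nod)),
        relative=fmean.with_values(np.where(np.isfinite(rel), rel, nod)))


# ---------------------------------------------------------------------------
# scaling statistics
# ---------------------------------------------------------------------------

def robust_rms_scale(x: np.ndarray, k: float = 3.0,
                     max_iter: int = 20) -> tuple[np.ndarray, float, float]:
    """Robustly standardise values by iterative RMS outlier exclusion.

    Repeats: centre on the mean of the included set, compute the RMS of
    the included deviations, exclude points beyond ``k`` RMS, until the
    included set is stable (at most ``max_iter`` iterations).  Returns
    (z for ALL inputs, final mean, final scale).
    """
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    vals = x[finite]
    if vals.size < 3:
        raise ValueError("need at least 3 valid values")
    if np.allclose(vals, vals[0]):
        raise ValueError("degenerate input: all values equal")
    incl = np.ones(vals.size, dtype=bool)
    m = s = 0.0
    for _ in range(max_iter):
        m = vals[incl].mean()
        d = vals - m
        s = float(np.sqrt(np.mean(d[incl] ** 2)))
        if s == 0.0:
            raise ValueError("degenerate input: zero scale")
        new_incl = np.abs(d) <= k * s
        if np.array_equal(new_incl, incl):
            break
        incl = new_incl
    z = np.full(x.shape, np.nan)
    z[finite] = (vals - m) / s
    return z, float(m), float(s)


def robust_z_raster(r: GridRaster) -> GridRaster:
    """Robust z of a raster's valid cells; nodata preserved."""
    vals = r.masked()
    z, _, _ = robust_rms_scale(vals.ravel())
    z = z.reshape(r.shape)
    return r.with_values(np.where(np.isfinite(z), z, r.nodata))


def getis_ord_local(x: GridRaster, d_km: float = 15.0) -> GridRaster:
    """Standardised Getis-Ord Gi* with binary weights within a distance band.

    Gi* = [sum_j w_ij x_j - xbar sum_j w_ij]
          / ( S * sqrt( (n sum_j w_ij^2 - (sum_j w_ij)^2) / (n - 1) ) )

    with w_ij = 1 for cells whose centres lie within ``d_km`` km of cell i
    (self included), S the global population SD.  Pixels whose band holds
    no other cell, or a zero denominator (e.g. a spatially constant field),
    yield nodata.
    """
    valid = x.valid
    vals = x.values[valid]
    n = vals.size
    if n < 2:
        raise ValueError("need at least 2 valid pixels")
    lon, lat = x.cell_centers()
    lons, lats = lon[valid], lat[valid]
    xbar = vals.mean()
    S = float(np.sqrt(np.mean(vals ** 2) - xbar ** 2))
    out = np.full(x.shape, x.nodata)
    rows, cols = np.nonzero(valid)
    for i in range(n):
        d = haversine_km((lons[i], lats[i]), (lons, lats))
        w = (d <= d_km).astype(float)   # includes self (d=0)
        sw = w.sum()
        denom_inner = (n * np.sum(w ** 2) - sw ** 2) / (n - 1)
        denom = S * np.sqrt(max(denom_inner, 0.0))
        if sw < 2 or denom <= 0:
            continue
        gi = (np.dot(w, vals) - xbar * sw) / denom
        out[rows[i], cols[i]] = gi
    return x.with_values(out)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_spots(z: GridRaster, atlas: AreaMask | None = None,
                   method: str = "robust_z") -> SpotClassification:
    """Three-way HIS classification of a standardised field.

    Hotspots (z <= -2) and adaptation spots (-2 < z <= -1) are reported
    only inside the growing-area mask when one is given; pressure spots
    (z >= +1) are reported everywhere.
    """
    valid = z.valid
    zv = z.values
    inside = valid if atlas is None else (valid & atlas.boolean)
    cat = np.full(z.shape, float(CATEGORY_CODES["none"]))
    cat[inside & (zv <= -1.0)] = CATEGORY_CODES["adaptation"]
    cat[inside & (zv <= -2.0)] = CATEGORY_CODES["hotspot"]
    cat[valid & (zv >= 1.0)] = CATEGORY_CODES["pressure"]
    cat[~valid] = z.nodata
    return SpotClassification(z=z.copy(),
                              category=z.with_values(cat), method=method)


def classify_yield_change(change: YieldChangeField,
                          atlas: AreaMask | None = None,
                          method: str = "robust_z",
                          d_km: float = 15.0) -> SpotClassification:
    """Standardise a change field (robust_z or getis_ord) and classify it."""
    if method == "robust_z":
        z = robust_z_raster(change.delta)
    elif method == "getis_ord":
        z = getis_ord_local(change.delta, d_km=d_km)
    else:
        raise ValueError("method must be 'robust_z' or 'getis_ord'")
    return classify_spots(z, atlas, method=method)


# ---------------------------------------------------------------------------
# kernel density overlay and site selection
# ---------------------------------------------------------------------------

def silverman_bandwidth_km(lons: np.ndarray, lats: np.ndarray) -> float:
    """Rule-of-thumb bandwidth from point dispersion, in km."""
    mlat = float(np.mean(lats))
    x_km = np.asarray(lons) * 111.19 * np.cos(np.radians(mlat))
    y_km = np.asarray(lats) * 111.19
    sigma = float(np.sqrt((np.var(x_km) + np.var(y_km)) / 2.0))
    n = len(np.asarray(lons))
    return max(1.06 * sigma * n ** (-1 / 5), 1e-3) if sigma > 0 else 5.0


def kernel_density_mask(points, geom: GridRaster,
                        bandwidth_km: float | None = None,
                        threshold: float = 0.1) -> AreaMask:
    """Gaussian kernel density of presence points, thresholded to a mask.

    ``points`` is a sequence of (lon, lat).  The mask holds cells whose
    density reaches ``threshold`` times the maximum density.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("need at least one point")
    if bandwidth_km is None:
        bandwidth_km = silverman_bandwidth_km(pts[:, 0], pts[:, 1])
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    lon, lat = geom.cell_centers()
    dens = np.zeros(geom.shape)
    for plon, plat in pts:
        d = haversine_km((plon, plat), (lon, lat))
        dens += np.exp(-0.5 * (d / bandwidth_km) ** 2)
    mask = (dens >= threshold * dens.max()).astype(float)
    return AreaMask(GridRaster(mask, geom.origin, geom.cell_size,
                               geom.nodata))


def select_site_pixels(community: dict, classification: SpotClassification
                       | None, atlas: AreaMask, dem: GridRaster,
                       radius_km: float = 15.0,
                       elev_tol_m: float = 100.0) -> list[tuple[int, int]]:
    """Pixels usable for a study site around a community.

    A pixel qualifies when its centre lies within ``radius_km`` of the
    community, it falls in the growing-area mask, and its elevation is
    within ``elev_tol_m`` of the community's (all bounds inclusive).  If a
    classification is given, the pixel must additionally be a hotspot or
    adaptation spot.  Returns (row, col) pairs; empty when nothing
    qualifies.
    """
    lon, lat = dem.cell_centers()
    d = haversine_km((community["lon"], community["lat"]), (lon, lat))
    ok = (d <= radius_km) & atlas.boolean & dem.valid
    ok &= np.abs(dem.values - community["elevation_m"]) <= elev_tol_m
    if classification is not None:
        ok &= (classification.category_mask("hotspot")
               | classification.category_mask("adaptation"))
    return [(int(r), int(c)) for r, c in np.argwhere(ok)]
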