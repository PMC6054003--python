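# Methods

## Spatial data model

All gridded data live on geographic (WGS84) lon/lat grids with square
cells, rows north→south. The origin is the north-west grid corner;
point-in-cell queries use cell-centre registration, matching the
convention of interpolated climatology products. One nodata sentinel per
raster (default −9999). Block aggregation to coarser resolutions averages
the valid cells of each block; trailing partial blocks are averaged over
the cells that exist rather than padded, so no values are invented.
Distances are great-circle with R = 6371 km. Reprojection and non-
geographic CRS are out of scope. On-disk formats are ESRI ASCII grid
(single layers) and classic NetCDF (multi-layer stacks); both are plain,
dependency-light formats that round-trip exactly at the precision written.

## Synthetic study region

The generator emulates the statistical features the analysis depends on,
not the geography of any real place:

- **DEM**: Gaussian-filtered noise plus a west–east tilt, scaled to
  0–2200 m, so lowland and highland sectors are contiguous.
- **Temperature**: sea-level annual means (tmax 34 °C, tmin 22 °C) with a
  mild seasonal cycle peaking before the rains, lapsed at 0.55 °C/100 m.
  These values place growing-season daily maxima a degree or two below the
  crop's 35 °C ceiling at the lower edge of the growing-area band, so a
  ~+2 °C ensemble exceeds the ceiling exactly where a heat-driven impact
  gradient should emerge — the configuration the classification stage is
  designed to detect.
- **Rainfall**: a bimodal May–October wet season; July and August are
  scaled by (1 − canícula depth), default 0.5, which keeps July+August
  below June everywhere. A smooth per-pixel wetness multiplier (0.7–1.3)
  is shared by all months, so monthly ratios are spatially uniform and the
  canícula property is preserved pixel-wise. Default annual total
  1400 mm.
- **GCM anomalies**: 19 pseudo-models, generated at a 5× coarser grid.
  Warming centres +1.0 °C (2020s) / +2.0 °C (2050s) — fixture choices,
  not estimates of any scenario — with inter-model SD 0.4 °C, smooth
  spatial structure, and mixed-sign precipitation anomalies
  (SD 12 mm/month). All within-field variation scales with the spread
  parameters, so zero spread yields identical flat anomalies.
- **Growing-area mask**: the 300–1600 m elevation band intersected with a
  smooth patchiness field; 15 communities are sampled on the mask with
  elevations read off the DEM.

What the generator does **not** emulate: orographic rain shadows,
coastlines, spatially varying diurnal range, real GCM covariance
structure, or observational error. Passing tests therefore demonstrate
that the pipeline's logic behaves correctly under controlled, physically
plausible conditions — not that its outputs would be accurate for any real
region.

## Delta downscaling

Anomalies are interpolated bilinearly between coarse cell centres (edge
values replicated beyond the outermost centres) and added to the baseline.
Precipitation is treated additively with a floor at 0 mm, because the
method is defined as a sum of interpolated anomalies; a multiplicative
mode (fractional changes) is available as a flag for users who prefer
ratio scaling in dry climates. Bilinear weights are non-negative, so the
fine field is monotone in every coarse cell — a property the tests
exercise.

## Weather generator

Occurrence: an order-k (k = 1, 2, 3; default 3) wet/dry chain with

    p(wet | history) = p_wet + r · (w̄(history) − p_wet)

where w̄ is the geometrically weighted mean (most recent day weight 1,
decaying by ½) of the previous k wet indicators and r ∈ [0, 1) the
persistence (default 0.25). Linearity in the indicators makes the
stationary wet-day frequency exactly p_wet for every k and r, with no
probability clipping needed — so monthly totals are preserved in
expectation by construction, and the recovery tests check the realised
totals against 3-standard-error bands.

Calibration ties expected wet days to the monthly total P through
W = min(0.7 · P^0.55, days-in-month), an empirical power law of tropical
station climatologies; p_wet = W/days. Wet-day amounts are gamma with
shape 0.8 and scale solved from P = W · shape · scale. Daily temperatures
are monthly normals interpolated linearly between mid-month points plus
Gaussian deviates (SD 1.2 °C common + 0.6 °C anti-symmetric), with
tmin clamped ≤ tmax − 0.1. Solar radiation is the FAO-56 extraterrestrial
envelope for the latitude and day of year times a transmissivity of 0.70
(dry) / 0.45 (wet) with 5 % noise. Years have 365 days (no leap days),
which the DSSAT `.WTH` writer also assumes.

## Yield emulator

The emulator is deliberately minimal — a transparent stand-in for a full
process crop model that preserves the management protocol and the sign
structure of water and heat stress. It does not model phenology, nitrogen
or phosphorus dynamics, or CO₂ response, and none of its absolute yields
should be read as predictions.

- **Soil**: single-layer bucket, 300 mm deep (the layer the sowing
  trigger senses). Generic silty loam (LL 0.11, DUL 0.26, runoff 10 %)
  and sandy loam (LL 0.07, DUL 0.19, runoff 15 %). Daily: rain net of
  runoff, capped at DUL (excess drains), actual ET = demand ×
  min(1, ASW/(0.5 · capacity)).
- **Demand**: stage crop coefficient (0.4 establishment, 1.05 mid, 0.7
  late) × a Hargreaves-type reference ET computed from temperature and
  radiation; bare-soil demand before sowing is 0.5 × reference ET (a
  choice the sources leave open; it only shifts the sowing date slightly).
- **Sowing**: the bucket starts at the lower limit 60 days before the
  window opens (wrapping circularly within the same replicate year, which
  keeps years independent) and the first window day with ASW ≥ 50 % of
  capacity sows the crop; years that never reach the trigger yield 0.
- **Yield**: potential (2800 kg/ha ICTA OSTUA / 2600 kg/ha BAT1289) ×
  fertilizer multiplier × mean daily transpiration fraction × mean daily
  temperature suitability over the cultivar duration (75 / 70 days).
  Temperature suitability is a trapezoid on cardinal temperatures
  8 / 20 / 28 / 35 °C applied to the daily mean, times a heat penalty of
  0.15 per °C of daily maximum above 35 °C. Fertilizer multipliers:
  none 0.34, F1 0.70, F2 1.00 — the unfertilized level reflects rain-fed
  yields reaching about a third of the fully fertilized level. Because
  fertilizer is purely multiplicative, grid runs simulate each
  (cultivar, soil) pair once and scale.
- Season windows (day-of-year): primera 105–181, postrera 232–273,
  apante 298–339.

## Spot classification

The robust RMS scaling iterates: centre on the included-set mean, scale by
the included-set RMS deviation, exclude points beyond 3×, repeat to
stability (≤ 20 iterations); all pixels are then standardised by the final
centre and scale. Note an algebraic consequence of the k = 3 multiplier:
a sample of n values can only trigger an exclusion if some deviation
exceeds 3 RMS, and the largest achievable ratio is √(n−1), so n must
exceed 10 before any single outlier can be shed. Cutoffs are inclusive:
hotspot z ≤ −2, adaptation −2 < z ≤ −1, pressure z ≥ +1, which on
Gaussian fields reproduces the 68 % / 95 % confidence-band coverages the
categories are named for (the acceptance suite verifies this on 10⁶
draws). Hot/adaptation spots are reported within the growing-area mask;
pressure spots everywhere, since they mostly fall outside current
production.

Whether the standardised field should be the robust-scaled change itself
or a spatial-association statistic is genuinely open in the method's
lineage; the package computes robust z by default and offers the
Getis–Ord local G\* (binary weights within a 15 km band, self included,
standardised per the Ord–Getis formula) as `method="getis_ord"`. The two
agree on smooth elevation-driven signals but G\* additionally rewards
spatial clustering.

Kernel-density overlay: Gaussian kernels on great-circle distance, with
Silverman's rule-of-thumb bandwidth (1.06 σ n^(−1/5), σ in km from point
dispersion) unless overridden; mask = density ≥ threshold × max.

Site selection is the inclusive triple filter: ≤ 15 km from the
community, on the growing-area mask, elevation within 100 m.

## Ensemble uncertainty

Per-pixel over the GCM change fields: mean, sample SD (n − 1), and
agreement = 100 · max(#negative, #non-negative)/n, counting zero as
non-negative, so the floor is 50 % by construction. The zonal summary
reports per-zone mean percent change by season, the percentage of zones
with mean loss beyond 10 %, and the same percentage within the
top-production zones holding half of total baseline production (greedy
prefix by descending production; zone counts, not area weights). The
ensemble-mean-of-changes and the change-under-ensemble-mean-climate are
both computed but never equated — they differ whenever the yield response
is nonlinear in climate.

## Pipeline problem sizes

The end-to-end configuration runs the spot-finding factorial on the grid
aggregated 2× (mirroring the coarse-then-fine, screen-then-zoom staging
of this kind of assessment), then reruns all GCMs at the fine site pixels
only (capped at 120). The reference configuration is a 40×40 fine grid,
19 pseudo-GCMs and 20 replicate years — replicate count chosen so the
whole analysis completes in minutes while leaving Monte-Carlo error well
below the warming signal; the generator default remains 99 years for
single-pixel use.

## Known limitations

- The emulator's absolute yields and the synthetic region's geography are
  illustrative; only signs, orderings and calibrated statistics are
  meaningful test targets.
- G\* significance is read directly from the z-value; no permutation
  testing.
- Zonal summaries are zone-count based; production weighting within zones
  is limited to the 50 %-of-production subset rule.
- Precipitation anomalies are additive by default; strongly negative
  coarse anomalies over dry pixels clamp at 0 mm and are not redistributed.
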