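"""Delta-downscale a pseudo-GCM anomaly and generate daily weather.

The coarse monthly anomaly is bilinearly interpolated to the fine grid and
added to the baseline; the combined monthly climate then drives the
Markov-chain weather generator at one pixel, and the replicate years are
written as a DSSAT .WTH file.
"""

import numpy as np

from beanclim.downscale import downscale
from beanclim.synthetic import SyntheticConfig, make_baseline_climate, \
    make_gcm_anomalies
from beanclim.weather import calibrate, generate, write_wth

cfg = SyntheticConfig(grid_shape=(40, 40), seed=0)
baseline, dem = make_baseline_climate(cfg)
anomaly = make_gcm_anomalies(cfg, "2050s")[0]

scenario = downscale(baseline, anomaly, label="gcm00_2050s")
dt = (scenario.climate.tmax - baseline.tmax).mean()
print(f"downscaled warming, grid mean: +{dt:.2f} degC")

r, c = 20, 20
prec, tmin, tmax = scenario.climate.pixel(r, c)
lon, lat = baseline.geometry_raster().cell_center(r, c)
params = calibrate(prec, tmin, tmax, latitude=lat)
series = generate(params, n_years=99, seed=1)
annual = series.rain.sum(axis=1)
print(f"pixel ({r},{c}): monthly target {prec.sum():.0f} mm, "
      f"generated {annual.mean():.0f} +/- {annual.std():.0f} mm over "
      f"{series.n_years} replicate years")
write_wth(series, "scratch_example.WTH", lat=lat, lon=lon,
          elev=dem.values[r, c])
print("wrote scratch_example.WTH (99 x 365 daily records)")
# The generated mean matches the monthly calibration target by
# construction; the spread is the interannual variability the crop model
# integrates over.
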