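"""Build a synthetic Central-American study region and describe it.

The generator produces a WorldClim-like monthly climatology draped over a
smooth DEM, a patchy mid-elevation bean-growing mask, and a community
table — everything the assessment needs, with no downloads.
"""

import numpy as np

from beanclim.synthetic import (SyntheticConfig, make_atlas_and_communities,
                                make_baseline_climate)

cfg = SyntheticConfig(grid_shape=(40, 40), seed=0)
climate, dem = make_baseline_climate(cfg)
atlas, communities = make_atlas_and_communities(cfg, dem)

annual = climate.prec.sum(axis=0)
print(f"grid: {cfg.grid_shape} cells of {cfg.cell_size * 60:.1f} arc-min")
print(f"elevation: {dem.values.min():.0f}-{dem.values.max():.0f} m")
print(f"annual rainfall: {annual.min():.0f}-{annual.max():.0f} mm")
jun, jul, aug = climate.prec[5].mean(), climate.prec[6].mean(), \
    climate.prec[7].mean()
print(f"canicula dip: Jun {jun:.0f} mm vs Jul {jul:.0f} / Aug {aug:.0f} mm")
print(f"growing-area mask: {int(atlas.boolean.sum())} cells "
      f"({100 * atlas.boolean.mean():.0f} % of grid)")
print(f"communities: {len(communities)}, elevations "
      f"{communities.elevation_m.min():.0f}-"
      f"{communities.elevation_m.max():.0f} m")
# The mid-summer dip splits the wet season in two, which is why the region
# has distinct primera and postrera planting seasons.
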