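"""Build the latitudinal and Holdridge regionalizations of a study grid.

Monthly temperatures follow a known latitudinal gradient (t = 28 − 0.5·|lat|),
so biotemperature belt boundaries sit at analytically known latitudes: the
tropical belt (biotemperature ≥ 24 °C) must end at |lat| = (28 − 24)/0.5 = 8°.
"""

import numpy as np

from climoccur import (GridDefinition, biotemperature, build_holdridge_raster,
                       build_latitudinal_raster, gen_monthly_climate)

grid = GridDefinition(xmin=-10.0, ymin=-90.0, cellsize=1.0, ncols=20, nrows=180)

latzone = build_latitudinal_raster(grid)
print("latitudinal zones at sample latitudes:")
for lat in (0.5, 30.5, 50.5, 70.5):
    print(f"  lat {lat:+6.1f} -> {latzone.sample([0.5], [lat])[0]}"
          f"   (lat {-lat:+6.1f} -> {latzone.sample([0.5], [-lat])[0]})")

monthly = gen_monthly_climate(grid, gradient=0.5, seasonality=5.0,
                              intercept=28.0, noise_sd=0.0)
biot = biotemperature(monthly)
print(f"\nbiotemperature range: {np.nanmin(biot.values):.2f} to "
      f"{np.nanmax(biot.values):.2f} °C (always within 0-30)")

holdridge = build_holdridge_raster(monthly)
print("\nHoldridge belts along the gradient (one cell per 10° of latitude):")
for lat in range(5, 90, 10):
    zone = holdridge.sample([0.5], [lat - 0.5])[0]
    print(f"  lat {lat - 0.5:5.1f} -> {zone}")
print("\ntropical/subtropical boundary predicted at |lat| = 8°:")
print("  lat 7.5 ->", holdridge.sample([0.5], [7.5])[0],
      "| lat 8.5 ->", holdridge.sample([0.5], [8.5])[0])
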