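"""Terrain uplift proxies: ruggedness (TRI) and distance to ridge lines.

TRI is the mean absolute elevation difference to adjacent cells; ridges are
the cells whose standardized topographic position index (TPI) exceeds +1 SD,
and every cell gets the Euclidean distance to the nearest ridge cell.
"""

import numpy as np

from flyscape import SimulationConfig, compute_terrain_layers, generate_dem

config = SimulationConfig(seed=1, extent_m=60_000, cell_m=100, n_ridges=4)
dem = generate_dem(config)
layers = compute_terrain_layers(dem, inner_radius_m=10, outer_radius_m=200,
                                ridge_sd_threshold=1.0, target_cell_m=100)

ridge_cells = int(np.nansum(layers.ridge_mask.values))
print(f"TRI: mean {np.nanmean(layers.tri.values):.1f} m, "
      f"max {np.nanmax(layers.tri.values):.1f} m")
print(f"ridge cells: {ridge_cells} "
      f"({100 * ridge_cells / layers.ridge_mask.values.size:.1f}% of the map)")
print(f"distance to ridge: median {np.nanmedian(layers.dist_ridge.values):.0f} m, "
      f"max {np.nanmax(layers.dist_ridge.values):.0f} m")
# High TRI and small ridge distance mark terrain where deflected winds
# produce predictable orographic uplift -- cheap flight for a soaring bird.
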