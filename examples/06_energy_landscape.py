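"""Weekly flyability maps: the realized energy landscape through ontogeny.

The fitted model predicts, for every 100 m cell and week since emigration,
the inverse-logit probability that the cell supports energy-efficient
commuting flight.  Cells above 0.7 count as flyable.
"""

import numpy as np

from flyscape import SimulationConfig, fit_conditional_logit, simulate_population
from flyscape.landscape import compute_landscape_series, hotspot_density
from flyscape.validation import analyze_world

config = SimulationConfig(seed=1)  # the default study conditions: 20 birds, 156 weeks
world = simulate_population(config)
design, transform, steps, _ = analyze_world(world)
fit = fit_conditional_logit(design, transform)

series = compute_landscape_series(fit, world.terrain, steps,
                                  weeks=range(1, 157), threshold=0.7, keep_maps=(156,))
a = series.flyable_area_km2
print(f"flyable area week 1:   {a[0]:,.0f} km^2")
print(f"flyable area week 156: {a[-1]:,.0f} km^2  "
      f"({a[-1] / a[0]:.1f}-fold the first week)")
g = series.growth
if g.fitted and not g.flags:
    print(f"logistic growth fit: asymptote {g.asymptote:,.0f} km^2, "
          f"rate {g.rate:.3f}/week, midpoint week {g.midpoint:.0f}")
else:
    for flag in g.flags:
        print(f"growth fit note: {flag}")

dens = hotspot_density(series.maps[156], threshold=0.7)
r, c = np.unravel_index(np.nanargmax(dens.values), dens.values.shape)
x, y = series.maps[156].cell_center(r, c)
print(f"strongest flyability hotspot at ({x / 1000:.1f}, {y / 1000:.1f}) km")
# As the agents age, the week interactions flatten the terrain dependence:
# more of the landscape clears the 0.7 threshold and the map opens up.
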