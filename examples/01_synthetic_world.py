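"""Build a small synthetic world: ridged terrain and GPS-like eagle tracks.

The generator plants Gaussian-profile ridges in a planar landscape and
releases agents that wander near their nest, emigrate, and then commute by
step selection with known preference coefficients.
"""

from flyscape import SimulationConfig, simulate_population

config = SimulationConfig(
    seed=1, n_individuals=3, post_emigration_weeks=12,
    extent_m=120_000, n_ridges=5, noncommuting_mean_bout_h=20.0,
)
world = simulate_population(config)

dem = world.dem
print(f"DEM: {dem.n_rows} x {dem.n_cols} cells at {dem.cell_size:.0f} m, "
      f"elevation {dem.values.min():.0f}-{dem.values.max():.0f} m")
print(f"tracks: {len(world.tracks)} fixes from {config.n_individuals} individuals "
      f"(one per {config.fix_interval_min} min)")
print(f"commuting decisions with known selection coefficients: {len(world.true_steps)}")
print(f"mean commuting step length: {world.true_steps.step_length.mean():.0f} m "
      f"(kernel mean {config.gamma_shape * config.gamma_scale_m:.0f} m)")
# The step lengths are drawn from the configured gamma kernel and then
# preference-weighted; downstream stages must recover the coefficients.
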