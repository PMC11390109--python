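"""Segment tracks into behaviors and extract commuting bouts.

Ground speed comes from consecutive fixes; flight altitude is height above
ellipsoid minus geoid undulation minus ground elevation.  Two-component EM
mixtures on each variable give low/high labels, and runs of >= 2 hourly
high-speed/high-altitude (HH) fixes are nonstop commuting bouts.
"""

from flyscape import (
    SimulationConfig, simulate_population,
    compute_flight_altitude, compute_ground_speed,
    extract_commuting_bouts, fit_behavior_model, label_behavior, subsample_hourly,
)

config = SimulationConfig(seed=2, n_individuals=3, post_emigration_weeks=12,
                          extent_m=120_000, noncommuting_mean_bout_h=20.0)
world = simulate_population(config)

tracks = compute_ground_speed(world.tracks)
tracks = compute_flight_altitude(tracks, world.dem, config.geoid_offset_m)
model = fit_behavior_model(tracks)
tracks = label_behavior(tracks, model)
hourly, bouts = extract_commuting_bouts(subsample_hourly(tracks))

print(f"speed classes:    low {model.speed_means[0]:.1f} m/s, high {model.speed_means[1]:.1f} m/s")
print(f"altitude classes: low {model.alt_means[0]:.0f} m,   high {model.alt_means[1]:.0f} m")
acc = ((tracks.behavior_class == "HH") == (tracks.true_behavior == "commuting")).mean()
print(f"label accuracy vs simulation truth: {100 * acc:.2f}%")
print(f"commuting bouts (>= 1 h nonstop): {len(bouts)}, "
      f"mean duration {sum(b.duration_h for b in bouts) / len(bouts):.1f} h")
# The high/high corner is the commuting behavior the energy-landscape
# analysis is built on; everything else is ignored downstream.
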