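"""Closed-loop validation: recover the generator's known selection
coefficients by running the full analysis on simulated tracks.

The experiment is the package's core correctness check: simulate a
population under the default study conditions, push the tracks through
segmentation, dispersal detection, and stratum sampling, fit the
conditional-logistic model, and compare the estimates to the generating
coefficients.

Two controls keep the comparison on a defined scale: alternatives are drawn
from the generator's known movement kernels, and covariates are z-scored
with the generator's frozen world constants.  (Re-fitting a tentative gamma
kernel to the observed -- selection-tilted -- step lengths absorbs the mean
step-length preference into the availability distribution, which shifts the
step-length main effect toward zero; that is a property of uncorrected
empirical availability kernels, not of the estimator, so the controlled
experiment supplies the true kernels.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dispersal import detect_population
from .sampling import MovementKernels, TransformParams, annotate_and_transform, generate_strata, steps_from_bouts
from .ssf import SSFModelFit, build_design, fit_conditional_logit
from .synthetic import SimulationConfig, SyntheticWorld, simulate_population
from .tracks import (
    compute_flight_altitude,
    compute_ground_speed,
    extract_commuting_bouts,
    fit_behavior_model,
    label_behavior,
    subsample_hourly,
)

log = logging.getLogger(__name__)


@dataclass
class RecoveryResult:
    seed: int
    fit: SSFModelFit
    table: pd.DataFrame  # term, truth, estimate, se, within_2se, sign_correct
    n_strata: int
    label_accuracy: float
    steps: pd.DataFrame | None = None

    @property
    def all_within_2se(self) -> bool:
        return bool(self.table["within_2se"].all())

    @property
    def all_signs_correct(self) -> bool:
        return bool(self.table["sign_correct"].all())


def analyze_world(world: SyntheticWorld, n_alternatives: int = 50, use_true_kernels: bool = True,
                  rng=None):
    """Run segmentation -> dispersal -> sampling -> design on a simulated
    world; returns (design, transform, steps, label_accuracy)."""
    config = world.config
    tracks = compute_ground_speed(world.tracks)
    tracks = compute_flight_altitude(tracks, world.dem, config.geoid_offset_m)
    model = fit_behavior_model(tracks)
    tracks = label_behavior(tracks, model)
    truth = tracks["true_behavior"] == "commuting"
    pred_hh = tracks["behavior_class"] == "HH"
    label_accuracy = float((truth == pred_hh).mean())
    hourly = subsample_hourly(tracks)
    hourly, _ = extract_commuting_bouts(hourly)
    hourly, _ = detect_population(hourly, world.nests)
    steps = steps_from_bouts(hourly)
    steps = steps[(steps["week"] >= 1) & (steps["week"] <= 156)]
    if use_true_kernels:
        kernels = MovementKernels(
            config.gamma_shape, config.gamma_scale_m, 0.0, config.vm_kappa, len(steps)
        )
    else:
        from .sampling import fit_movement_kernels

        kernels = fit_movement_kernels(steps)
    if rng is None:
        rng = np.random.default_rng([int(config.seed), 77])
    strata = generate_strata(steps, kernels, world.terrain, n_alternatives, rng)
    params = TransformParams.from_pairs(config.zscore)
    strata, transform = annotate_and_transform(strata, world.terrain, params)
    design = build_design(strata)
    return design, transform, steps, label_accuracy


def run_recovery(seed: int, config: SimulationConfig | None = None,
                 n_alternatives: int = 50, dem=None, terrain=None) -> RecoveryResult:
    """One recovery replicate under the default study conditions.

    ``dem``/``terrain`` may be passed to hold the landscape fixed across
    replicate seeds (the study region is one fixed landscape; the seed then
    varies the agents and the availability sampling).
    """
    if config is None:
        config = SimulationConfig(seed=int(seed))
    else:
        config.seed = int(seed)
    world = simulate_population(config, dem, terrain)
    design, transform, steps, acc = analyze_world(world, n_alternatives)
    fit = fit_conditional_logit(design, transform)
    truth = np.array([config.true_beta.get(t, 0.0) for t in fit.terms])
    err = np.abs(fit.beta - truth)
    table = pd.DataFrame(
        {
            "term": list(fit.terms),
            "truth": truth,
            "estimate": fit.beta,
            "se": fit.se,
            "within_2se": err < 2 * fit.se,
            "sign_correct": np.sign(fit.beta) == np.sign(truth),
        }
    )
    log.info("seed %d: %d strata, label accuracy %.4f", seed, design.n_strata, acc)
    return RecoveryResult(int(seed), fit, table, design.n_strata, acc, steps)
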