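"""Movement kernels, stratum construction, and the z-transform."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flyscape.raster import RasterGrid
from flyscape.sampling import (
    MovementKernels,
    TransformParams,
    annotate_and_transform,
    correlation_screen,
    fit_movement_kernels,
    generate_strata,
    steps_from_bouts,
)
from flyscape.terrain import TerrainLayers


def _steps_frame(lengths, angles):
    n = len(lengths)
    return pd.DataFrame(
        {
            "individual_id": "a", "bout_id": 0.0,
            "x0": 0.0, "y0": 0.0, "x1": lengths, "y1": 0.0,
            "step_length": lengths, "bearing": 0.0,
            "turning_angle": angles, "week": 1.0,
        }
    )


def _flat_layers(n=200, cell=100.0, tri_sd=10.0, rng=None):
    """Synthetic 100 m terrain layers with independent random covariates."""
    rng = rng or np.random.default_rng(0)
    extent = n * cell
    tri = RasterGrid(0, extent, cell, np.abs(rng.normal(15, tri_sd, (n, n))))
    dist = RasterGrid(0, extent, cell, np.abs(rng.normal(3000, 1500, (n, n))))
    zeros = RasterGrid(0, extent, cell, np.zeros((n, n)))
    return TerrainLayers(tri, zeros, zeros, dist, tri, dist)


# --- kernel fitting ------------------------------------------------------

def test_gamma_kernel_recovery(rng):
    lengths = rng.gamma(2.0, 500.0, 10_000)
    angles = rng.vonmises(0.0, 1.5, 10_000)
    k = fit_movement_kernels(_steps_frame(lengths, angles))
    assert 1.9 <= k.gamma_shape <= 2.1
    assert 475 <= k.gamma_scale <= 525


def test_uniform_angles_give_tiny_kappa(rng):
    lengths = rng.gamma(2.0, 500.0, 10_000)
    angles = rng.uniform(-np.pi, np.pi, 10_000)
    k = fit_movement_kernels(_steps_frame(lengths, angles))
    assert k.vm_kappa < 0.05


def test_concentrated_angle_recovery(rng):
    k = fit_movement_kernels(
        _steps_frame(rng.gamma(2.0, 500.0, 10_000), rng.vonmises(0.0, 5.0, 10_000))
    )
    assert k.vm_kappa == pytest.approx(5.0, rel=0.05)
    assert k.vm_mu == pytest.approx(0.0, abs=0.05)


def test_degenerate_angles_capped_with_warning(caplog, rng):
    with caplog.at_level(logging.WARNING):
        k = fit_movement_kernels(_steps_frame(rng.gamma(2.0, 500.0, 200), np.zeros(200)))
    assert k.vm_kappa == 500.0
    assert "capped" in caplog.text


def test_stationary_data_rejected(rng):
    lengths = np.r_[np.zeros(120), rng.gamma(2.0, 500.0, 80)]
    with pytest.raises(ValueError, match="stationary"):
        fit_movement_kernels(_steps_frame(lengths, rng.vonmises(0, 1, 200)))


def test_too_few_turning_angles_rejected(rng):
    angles = np.full(100, np.nan)
    angles[:10] = 0.1
    with pytest.raises(ValueError, match="turning angles"):
        fit_movement_kernels(_steps_frame(rng.gamma(2.0, 500.0, 100), angles))


# --- stratum generation --------------------------------------------------

@pytest.fixture(scope="module")
def layers():
    return _flat_layers()


def _observed_steps(n, layers, rng, week_max=50):
    lo = 0.3 * layers.tri_100.x_max
    hi = 0.7 * layers.tri_100.x_max
    x0 = rng.uniform(lo, hi, n)
    y0 = rng.uniform(lo, hi, n)
    lengths = rng.gamma(2.0, 500.0, n)
    bearing = rng.uniform(-np.pi, np.pi, n)
    return pd.DataFrame(
        {
            "individual_id": rng.choice(["a", "b", "c"], n),
            "bout_id": 0.0,
            "x0": x0,
            "y0": y0,
            "x1": x0 + lengths * np.cos(bearing),
            "y1": y0 + lengths * np.sin(bearing),
            "step_length": lengths,
            "bearing": bearing,
            "turning_angle": np.where(rng.uniform(size=n) < 0.8, rng.vonmises(0, 1, n), np.nan),
            "week": rng.integers(1, week_max + 1, n).astype(float),
        }
    )


def test_stratum_size_is_51(layers, rng):
    steps = _observed_steps(40, layers, rng)
    kern = MovementKernels(2.0, 500.0, 0.0, 1.0, 40)
    strata = generate_strata(steps, kern, layers, 50, rng)
    sizes = strata.groupby("stratum_id").size()
    assert (sizes == 51).all()
    assert (strata.groupby("stratum_id")["used"].sum() == 1).all()


def test_strata_reproducible_given_seed(layers):
    steps = _observed_steps(10, layers, np.random.default_rng(4))
    kern = MovementKernels(2.0, 500.0, 0.0, 1.0, 10)
    a = generate_strata(steps, kern, layers, 50, np.random.default_rng(9))
    b = generate_strata(steps, kern, layers, 50, np.random.default_rng(9))
    pd.testing.assert_frame_equal(a, b)


def test_alternative_lengths_follow_fitted_gamma(layers):
    rng = np.random.default_rng(8)
    steps = _observed_steps(10_000, layers, rng)
    kern = MovementKernels(2.0, 500.0, 0.0, 1.0, 10_000)
    strata = generate_strata(steps, kern, layers, 50, rng)
    alt = strata.loc[strata["used"] == 0, "step_length"].to_numpy()
    res = stats.kstest(alt[:100_000], "gamma", args=(2.0, 0, 500.0))
    assert res.pvalue > 0.01


def test_high_kappa_alternatives_collinear(layers, rng):
    steps = _observed_steps(5, layers, rng)
    steps["turning_angle"] = 0.1  # previous bearing defined everywhere
    kern = MovementKernels(1e6, 0.001, 0.0, 500.0, 5)  # near-constant length
    strata = generate_strata(steps, kern, layers, 50, rng)
    alt = strata[strata["used"] == 0]
    assert alt["turning_angle"].abs().max() < 0.25  # tight around the previous bearing
    np.testing.assert_allclose(alt["step_length"], 1000.0, rtol=0.02)


def test_turning_angle_convention_ccw_from_previous_bearing():
    # east, east, north: the second step turns +pi/2 (counter-clockwise)
    ts = pd.date_range("2021-01-01 08:00", periods=4, freq="h")
    hourly = pd.DataFrame(
        {
            "individual_id": "a",
            "timestamp": ts,
            "x": [0.0, 1000.0, 2000.0, 2000.0],
            "y": [0.0, 0.0, 0.0, 1000.0],
            "bout_id": [0.0, 0.0, 0.0, 0.0],
            "week_since_emigration": 1.0,
        }
    )
    steps = steps_from_bouts(hourly)
    assert steps["turning_angle"].iloc[1] == pytest.approx(0.0)
    assert steps["turning_angle"].iloc[2] == pytest.approx(np.pi / 2)


def test_bout_entry_supplies_first_step_bearing():
    # a non-bout fix precedes the bout; the first in-bout step measures its
    # turn against the entry displacement (here: entry east, step north)
    ts = pd.date_range("2021-01-01 08:00", periods=3, freq="h")
    hourly = pd.DataFrame(
        {
            "individual_id": "a",
            "timestamp": ts,
            "x": [0.0, 1000.0, 1000.0],
            "y": [0.0, 0.0, 1000.0],
            "bout_id": [np.nan, 1.0, 1.0],
            "week_since_emigration": 1.0,
        }
    )
    steps = steps_from_bouts(hourly)
    assert len(steps) == 1
    assert steps["turning_angle"].iloc[0] == pytest.approx(np.pi / 2)


# --- annotation and z-transform -----------------------------------------

def test_z_transform_matches_hand_computation(layers, rng):
    steps = _observed_steps(3, layers, rng)
    kern = MovementKernels(2.0, 500.0, 0.0, 1.0, 3)
    strata = generate_strata(steps, kern, layers, 50, rng)
    out, params = annotate_and_transform(strata, layers)
    for c in ("tri", "dist_ridge", "step_length", "week"):
        x = out[c].to_numpy(dtype=float)
        np.testing.assert_allclose(out[f"{c}_z"], (x - x.mean()) / x.std(), atol=1e-10)
        assert params.means[c] == pytest.approx(x.mean())
    assert out.loc[out["tri"].idxmax(), "tri_z"] == pytest.approx(out["tri_z"].max())


def test_external_transform_params_reused(layers, rng):
    steps = _observed_steps(4, layers, rng)
    kern = MovementKernels(2.0, 500.0, 0.0, 1.0, 4)
    strata = generate_strata(steps, kern, layers, 50, rng)
    fixed = TransformParams.from_pairs(
        {"tri": (10.0, 5.0), "dist_ridge": (2000.0, 800.0),
         "step_length": (1000.0, 700.0), "week": (25.0, 14.0)}
    )
    out, params = annotate_and_transform(strata, layers, fixed)
    assert params is fixed
    np.testing.assert_allclose(out["tri_z"], (out["tri"] - 10.0) / 5.0, atol=1e-12)


def test_constant_covariate_rejected(rng):
    n = 50
    extent = n * 100.0
    const = RasterGrid(0, extent, 100.0, np.full((n, n), 5.0))
    varied = RasterGrid(0, extent, 100.0, rng.uniform(0, 5000, (n, n)))
    layers = TerrainLayers(const, const, const, varied, const, varied)
    steps = _observed_steps(3, layers, rng)
    kern = MovementKernels(2.0, 500.0, 0.0, 1.0, 3)
    strata = generate_strata(steps, kern, layers, 50, rng)
    with pytest.raises(ValueError, match="constant"):
        annotate_and_transform(strata, layers)


# --- correlation screen --------------------------------------------------

def test_duplicated_covariate_flagged(rng):
    x = rng.normal(size=500)
    df = pd.DataFrame({"tri": x, "dist_ridge": x, "step_length": rng.normal(size=500),
                       "week": rng.normal(size=500)})
    rep = correlation_screen(df)
    assert ("tri", "dist_ridge", 1.0) in [(a, b, round(r)) for a, b, r in rep.flagged]


def test_anticorrelated_pair_flagged(rng):
    x = rng.normal(size=500)
    df = pd.DataFrame({"tri": x, "dist_ridge": -x})
    rep = correlation_screen(df, columns=("tri", "dist_ridge"))
    assert rep.flagged[0][2] == pytest.approx(-1.0)


def test_independent_covariates_unflagged(rng):
    df = pd.DataFrame({c: rng.normal(size=10_000)
                       for c in ("tri", "dist_ridge", "step_length", "week")})
    rep = correlation_screen(df)
    assert rep.flagged == []
    off_diag = rep.matrix.values[~np.eye(4, dtype=bool)]
    assert np.abs(off_diag).max() < 0.1
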