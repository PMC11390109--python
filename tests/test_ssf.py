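"""Conditional-logistic SSF: likelihood oracle, fitting, mixed model, nRMSE."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import logsumexp

from flyscape.sampling import TransformParams
from flyscape.ssf import (
    TERMS,
    SeparationError,
    SSFModelFit,
    build_design,
    fit_conditional_logit,
    fit_mixed_conditional_logit,
    nll_grad_hess,
    normalized_rmse,
    term_columns,
)


def brute_nll_grad(beta, X, y, stratum):
    """Direct softmax enumeration over strata (independent of the vectorized path)."""
    nll = 0.0
    grad = np.zeros(len(beta))
    for s in np.unique(stratum):
        rows = np.flatnonzero(stratum == s)
        eta = np.array([float(X[r] @ beta) for r in rows])
        lse = logsumexp(eta)
        used = rows[y[rows] == 1][0]
        nll += lse - float(X[used] @ beta)
        p = np.exp(eta - lse)
        for k, r in enumerate(rows):
            grad += p[k] * X[r]
        grad -= X[used]
    return nll, grad


def make_cl_dataset(rng, n_ind=20, strata_per_ind=50, n_alt=10, beta=None,
                    slope_sd=(0.0, 0.0)):
    """Draw matched-stratum choice data directly from the conditional-logit
    model (optionally with per-individual Gaussian slope deviations on the
    tri and dist_ridge columns)."""
    if beta is None:
        beta = np.zeros(len(TERMS))
    frames = []
    sid = 0
    for i in range(n_ind):
        u = rng.normal(0.0, slope_sd)
        for _ in range(strata_per_ind):
            m = n_alt + 1
            z = {
                "tri": rng.normal(size=m),
                "dist_ridge": rng.normal(size=m),
                "step_length": rng.normal(size=m),
                "week": np.full(m, rng.normal()),
            }
            X = term_columns(z)
            eta = X @ beta + u[0] * z["tri"] + u[1] * z["dist_ridge"]
            p = np.exp(eta - logsumexp(eta))
            used = np.zeros(m)
            used[rng.choice(m, p=p)] = 1
            frames.append(pd.DataFrame(
                {"stratum_id": sid, "individual_id": f"i{i:02d}", "used": used,
                 "tri_z": z["tri"], "dist_ridge_z": z["dist_ridge"],
                 "step_length_z": z["step_length"], "week_z": z["week"]}
            ))
            sid += 1
    return pd.concat(frames, ignore_index=True)


TRUE_BETA = np.array([0.6, -0.6, 0.5, 0.25, 0.06, -0.15, -0.06, -0.06, 0.15, 0.06])


# --- design --------------------------------------------------------------

def test_design_products_match_hand_computation():
    cols = term_columns({"tri": [2.0], "dist_ridge": [-1.0], "step_length": [1.0], "week": [3.0]})
    by = dict(zip(TERMS, cols[0]))
    assert by["tri:week"] == 6.0
    assert by["tri:step_length:week"] == 6.0
    assert by["dist_ridge:step_length"] == -1.0
    assert by["dist_ridge:step_length:week"] == -3.0
    zero = term_columns({"tri": [0.0], "dist_ridge": [0.0], "step_length": [0.0], "week": [5.0]})
    np.testing.assert_array_equal(zero, 0.0)


def test_build_design_validates_input(rng):
    df = make_cl_dataset(rng, n_ind=2, strata_per_ind=3)
    design = build_design(df)
    assert design.X.shape == (2 * 3 * 11, 10)
    assert design.n_strata == 6
    bad = df.drop(columns=["week_z"])
    with pytest.raises(ValueError, match="missing"):
        build_design(bad)
    two_used = df.copy()
    two_used.loc[1, "used"] = 1
    with pytest.raises(ValueError, match="exactly one used"):
        build_design(two_used)


# --- likelihood ----------------------------------------------------------

def test_nll_at_zero_is_s_log_51(rng):
    df = make_cl_dataset(rng, n_ind=2, strata_per_ind=10, n_alt=50)
    d = build_design(df)
    nll, _, _ = nll_grad_hess(np.zeros(10), d.X, d.y, d.starts, d.counts)
    assert nll == pytest.approx(20 * np.log(51.0), abs=1e-9)


def test_identical_covariate_stratum_contributes_log51(rng):
    z = {k: np.full(51, 0.7) for k in ("tri", "dist_ridge", "step_length", "week")}
    X = term_columns(z)
    y = np.zeros(51)
    y[13] = 1
    starts = np.array([0])
    counts = np.array([51])
    for beta in (np.zeros(10), rng.normal(size=10)):
        nll, grad, _ = nll_grad_hess(beta, X, y, starts, counts)
        assert nll == pytest.approx(np.log(51.0), abs=1e-10)
        np.testing.assert_allclose(grad, 0.0, atol=1e-10)


def test_nll_and_gradient_match_brute_force(rng):
    # 20 random strata of size <= 6
    frames = []
    for s in range(20):
        m = int(rng.integers(2, 7))
        z = {k: rng.normal(size=m) for k in ("tri", "dist_ridge", "step_length")}
        z["week"] = np.full(m, rng.normal())
        used = np.zeros(m)
        used[rng.integers(m)] = 1
        frames.append(pd.DataFrame(
            {"stratum_id": s, "individual_id": "a", "used": used,
             **{f"{k}_z": v for k, v in z.items()}}
        ))
    d = build_design(pd.concat(frames, ignore_index=True))
    for _ in range(5):
        beta = rng.normal(scale=0.8, size=10)
        nll, grad, _ = nll_grad_hess(beta, d.X, d.y, d.starts, d.counts)
        nll_b, grad_b = brute_nll_grad(beta, d.X, d.y, d.stratum)
        assert nll == pytest.approx(nll_b, abs=1e-10)
        np.testing.assert_allclose(grad, grad_b, atol=1e-10)


def test_fit_matches_naive_optimizer(rng):
    df = make_cl_dataset(rng, n_ind=3, strata_per_ind=40, n_alt=5, beta=TRUE_BETA)
    d = build_design(df)
    ours = fit_conditional_logit(d)

    def f(b):
        return brute_nll_grad(b, d.X, d.y, d.stratum)[0]

    naive = optimize.minimize(f, np.zeros(10), method="BFGS",
                              options={"gtol": 1e-9, "maxiter": 5000})
    np.testing.assert_allclose(ours.beta, naive.x, atol=1e-4)


def test_stratum_constant_shift_invariance(rng):
    df = make_cl_dataset(rng, n_ind=2, strata_per_ind=15, n_alt=6, beta=TRUE_BETA)
    d = build_design(df)
    fit0 = fit_conditional_logit(d)
    X2 = d.X.copy()
    for s in range(d.n_strata):
        rows = d.stratum == s
        X2[rows] += rng.normal(size=10)  # same constant vector added to every row
    nll1, g1, _ = nll_grad_hess(fit0.beta, d.X, d.y, d.starts, d.counts)
    nll2, g2, _ = nll_grad_hess(fit0.beta, X2, d.y, d.starts, d.counts)
    assert nll1 == pytest.approx(nll2, abs=1e-8)
    np.testing.assert_allclose(g1, g2, atol=1e-8)
    d.X = X2
    fit2 = fit_conditional_logit(d)
    np.testing.assert_allclose(fit0.beta, fit2.beta, atol=1e-6)


def test_separation_raises_named_error(rng):
    frames = []
    for s in range(30):
        z = {k: rng.normal(size=6) for k in ("dist_ridge", "step_length")}
        tri = rng.normal(size=6)
        used = np.zeros(6)
        used[np.argmax(tri)] = 1  # tri perfectly ranks the used row
        frames.append(pd.DataFrame(
            {"stratum_id": s, "individual_id": "a", "used": used, "tri_z": tri,
             "dist_ridge_z": z["dist_ridge"], "step_length_z": z["step_length"],
             "week_z": 0.0}
        ))
    d = build_design(pd.concat(frames, ignore_index=True))
    with pytest.raises(SeparationError, match="tri"):
        fit_conditional_logit(d)


def test_parameter_recovery_direct_dgp(rng):
    df = make_cl_dataset(rng, n_ind=5, strata_per_ind=300, n_alt=20, beta=TRUE_BETA)
    d = build_design(df)
    fit = fit_conditional_logit(d)
    assert np.all(np.abs(fit.beta - TRUE_BETA) < 3 * fit.se)
    assert np.all(np.sign(fit.beta) == np.sign(TRUE_BETA))


def test_against_r_clogit(rng, tmp_path):
    """Independent cross-check: survival::clogit on the same small dataset."""
    df = make_cl_dataset(rng, n_ind=2, strata_per_ind=60, n_alt=4, beta=TRUE_BETA)
    d = build_design(df)
    ours = fit_conditional_logit(d)
    tab = pd.DataFrame(d.X, columns=[f"x{i}" for i in range(10)])
    tab["y"] = d.y.astype(int)
    tab["s"] = d.stratum
    csv = tmp_path / "cl.csv"
    tab.to_csv(csv, index=False)
    out = tmp_path / "coef.csv"
    script = (
        "suppressMessages(library(survival));"
        f"d <- read.csv('{csv}');"
        "m <- clogit(y ~ x0+x1+x2+x3+x4+x5+x6+x7+x8+x9 + strata(s), data=d,"
        " method='exact');"
        f"write.csv(data.frame(beta=coef(m), se=sqrt(diag(vcov(m)))), '{out}')"
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    r = pd.read_csv(out)
    np.testing.assert_allclose(ours.beta, r["beta"].to_numpy(), atol=2e-4)
    np.testing.assert_allclose(ours.se, r["se"].to_numpy(), rtol=2e-3)


# --- mixed model ---------------------------------------------------------

def test_mixed_zero_variance_matches_fixed(rng):
    df = make_cl_dataset(rng, n_ind=10, strata_per_ind=40, n_alt=8, beta=TRUE_BETA)
    d = build_design(df)
    fixed = fit_conditional_logit(d)
    mixed = fit_mixed_conditional_logit(d, compute_se=False)
    assert mixed.random_slope_sd["tri"] ** 2 < 0.05
    assert mixed.random_slope_sd["dist_ridge"] ** 2 < 0.05
    assert np.all(np.abs(mixed.beta - fixed.beta) < 2 * fixed.se)


def test_mixed_recovers_slope_sd(rng):
    df = make_cl_dataset(rng, n_ind=20, strata_per_ind=40, n_alt=8, beta=TRUE_BETA,
                         slope_sd=(0.5, 0.0))
    d = build_design(df)
    mixed = fit_mixed_conditional_logit(d, compute_se=False)
    assert 0.3 <= mixed.random_slope_sd["tri"] <= 0.7
    assert mixed.random_modes is not None
    assert len(mixed.random_modes) == 20


def test_mixed_requires_multiple_individuals(rng):
    df = make_cl_dataset(rng, n_ind=1, strata_per_ind=30, n_alt=5)
    d = build_design(df)
    with pytest.raises(ValueError, match="individual"):
        fit_mixed_conditional_logit(d)


# --- nRMSE ---------------------------------------------------------------

def _fit_with_beta(beta, d):
    return SSFModelFit(terms=TERMS, beta=np.asarray(beta, dtype=float),
                       se=np.zeros(10), vcov=np.zeros((10, 10)), loglik=0.0,
                       n_strata=d.n_strata, n_rows=len(d.y), converged=True)


def test_nrmse_constant_half_prediction(rng):
    df = make_cl_dataset(rng, n_ind=2, strata_per_ind=10, n_alt=50)
    d = build_design(df)
    assert normalized_rmse(_fit_with_beta(np.zeros(10), d), d) == pytest.approx(0.5)


def test_nrmse_perfect_prediction_limit(rng):
    # tri = +1 on the used row and -1 elsewhere: a huge tri coefficient
    # drives predictions to the 0/1 indicator and nRMSE to 0
    z = {"tri": np.r_[1.0, -np.ones(10)], "dist_ridge": np.zeros(11),
         "step_length": np.zeros(11), "week": np.zeros(11)}
    df = pd.DataFrame({"stratum_id": 0, "individual_id": "a",
                       "used": np.r_[1.0, np.zeros(10)],
                       **{f"{k}_z": v for k, v in z.items()}})
    d = build_design(df)
    beta = np.zeros(10)
    beta[0] = 60.0
    assert normalized_rmse(_fit_with_beta(beta, d), d) < 1e-6


def test_nrmse_hand_computed_fixture(rng):
    df = make_cl_dataset(rng, n_ind=1, strata_per_ind=2, n_alt=3, beta=TRUE_BETA)
    d = build_design(df)
    beta = rng.normal(scale=0.3, size=10)
    p = 1.0 / (1.0 + np.exp(-(d.X @ beta)))
    expected = np.sqrt(np.mean((p - d.y) ** 2))
    assert normalized_rmse(_fit_with_beta(beta, d), d) == pytest.approx(expected, abs=1e-12)


def test_fit_json_round_trip(rng):
    df = make_cl_dataset(rng, n_ind=2, strata_per_ind=15, n_alt=6, beta=TRUE_BETA)
    d = build_design(df)
    tp = TransformParams({"tri": 1.0, "dist_ridge": 2.0, "step_length": 3.0, "week": 4.0},
                         {"tri": 1.0, "dist_ridge": 1.0, "step_length": 1.0, "week": 1.0})
    fit = fit_conditional_logit(d, tp)
    back = SSFModelFit.from_json(fit.to_json())
    np.testing.assert_allclose(back.beta, fit.beta)
    np.testing.assert_allclose(back.se, fit.se)
    assert back.transform.means == tp.means
    assert back.terms == fit.terms
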