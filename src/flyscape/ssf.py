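"""Conditional-logistic step-selection model with individual random slopes.

The fixed-effects model maximizes the matched-stratum likelihood

    L(beta) = prod_s  exp(beta' x_used,s) / sum_{j in s} exp(beta' x_j)

over strata of one used and n alternative steps.  The design holds main
effects of TRI, ridge distance, and step length (all z-scored) plus the twoand
three-way interactions of the two terrain covariates with step length and
week since emigration, and the step-length-by-week interaction.  A week main
effect is constant within a stratum, hence unidentifiable under stratum
conditioning, and is not part of the design.

Individual variation enters as independent Gaussian random slopes on TRI and
ridge distance, integrated out by a Laplace approximation.  This is the same
estimator as the Poisson reformulation with stratum intercepts profiled out
(profiling the stratum intercepts of a Poisson log-linear model returns
exactly the conditional-logit likelihood), fitted here directly on the
conditional likelihood.

Optimization is damped Newton on the strictly convex fixed-effects problem
with analytic gradient and Hessian and log-sum-exp stabilization; standard
errors come from the inverse observed information.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .sampling import TransformParams

log = logging.getLogger(__name__)

#: Fixed-effect design, all on z-scores.
TERMS = (
    "tri",
    "dist_ridge",
    "step_length",
    "step_length:week",
    "tri:step_length",
    "tri:week",
    "tri:step_length:week",
    "dist_ridge:step_length",
    "dist_ridge:week",
    "dist_ridge:step_length:week",
)

RANDOM_TERMS = ("tri", "dist_ridge")


class SeparationError(RuntimeError):
    pass


@dataclass
class DesignMatrices:
    X: np.ndarray
    y: np.ndarray
    stratum: np.ndarray          # int codes, non-decreasing along rows
    individual: np.ndarray       # int codes, aligned with rows
    individual_labels: np.ndarray
    terms: tuple = TERMS

    @property
    def starts(self) -> np.ndarray:
        return np.flatnonzero(np.r_[True, np.diff(self.stratum) != 0])

    @property
    def counts(self) -> np.ndarray:
        return np.diff(np.r_[self.starts, len(self.stratum)])

    @property
    def n_strata(self) -> int:
        return len(self.starts)


def term_columns(z: dict) -> np.ndarray:
    """Stack the model terms from z-scored covariate arrays
    (keys tri, dist_ridge, step_length, week; broadcastable shapes)."""
    zt, zd, zl, zw = (np.asarray(z[k], dtype=float) for k in ("tri", "dist_ridge", "step_length", "week"))
    zt, zd, zl, zw = np.broadcast_arrays(zt, zd, zl, zw)
    cols = [zt, zd, zl, zl * zw, zt * zl, zt * zw, zt * zl * zw, zd * zl, zd * zw, zd * zl * zw]
    return np.stack([np.ravel(c) for c in cols], axis=1)


def build_design(dataset: pd.DataFrame) -> DesignMatrices:
    """Model matrices from an annotated, z-transformed stratified dataset.

    Rows are sorted by stratum (individuals nest strata).  Raises when a
    required ``*_z`` column is missing or a stratum lacks exactly one used row.
    """
    needed = ["tri_z", "dist_ridge_z", "step_length_z", "week_z", "stratum_id", "individual_id", "used"]
    missing = [c for c in needed if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    df = dataset.sort_values(["individual_id", "stratum_id"], kind="stable").reset_index(drop=True)
    used_per = df.groupby("stratum_id")["used"].sum()
    if (used_per != 1).any():
        bad = used_per.index[used_per != 1].tolist()
        raise ValueError(f"strata without exactly one used row: {bad[:10]}")
    X = term_columns(
        {"tri": df["tri_z"], "dist_ridge": df["dist_ridge_z"],
         "step_length": df["step_length_z"], "week": df["week_z"]}
    )
    stratum = pd.factorize(df["stratum_id"])[0]
    indiv, labels = pd.factorize(df["individual_id"])
    return DesignMatrices(X, df["used"].to_numpy(dtype=float), stratum, indiv, np.asarray(labels))


def _segments(eta, starts, counts):
    mx = np.maximum.reduceat(eta, starts)
    ex = np.exp(eta - np.repeat(mx, counts))
    denom = np.add.reduceat(ex, starts)
    return mx, ex, denom


def nll_grad_hess(beta, X, y, starts, counts, want_hess: bool = True):
    """Negative conditional log-likelihood, analytic gradient, and (optionally)
    Hessian, with per-stratum log-sum-exp stabilization."""
    eta = X @ beta
    mx, ex, denom = _segments(eta, starts, counts)
    lse = np.log(denom) + mx
    nll = lse.sum() - eta[y == 1].sum()
    p = ex / np.repeat(denom, counts)
    grad = X.T @ (p - y)
    if not want_hess:
        return nll, grad, None
    Xp = X * p[:, None]
    M = np.add.reduceat(Xp, starts, axis=0)
    H = X.T @ Xp - M.T @ M
    return nll, grad, H


@dataclass
class SSFModelFit:
    """Fitted step-selection model: estimates, uncertainty, and diagnostics."""

    terms: tuple
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray = field(repr=False)
    loglik: float
    n_strata: int
    n_rows: int
    converged: bool
    method: str = "fixed"
    transform: TransformParams | None = None
    random_slope_sd: dict | None = None
    random_modes: pd.DataFrame | None = field(repr=False, default=None)
    warnings: list = field(default_factory=list)
    n_iter: int = 0

    @property
    def ci_low(self) -> np.ndarray:
        return self.beta - 1.96 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.beta + 1.96 * self.se

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": list(self.terms), "estimate": self.beta, "se": self.se,
             "ci_low": self.ci_low, "ci_high": self.ci_high}
        )

    def linear_predictor(self, z: dict) -> np.ndarray:
        """Fixed-effects linear predictor on z-scored covariates
        (random effects at the population mean of zero)."""
        return term_columns(z) @ self.beta

    def to_json(self, path=None) -> str:
        d = {
            "terms": list(self.terms),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "n_strata": self.n_strata,
            "n_rows": self.n_rows,
            "converged": self.converged,
            "method": self.method,
            "random_slope_sd": self.random_slope_sd,
            "warnings": self.warnings,
            "n_iter": self.n_iter,
            "transform": None
            if self.transform is None
            else {"means": self.transform.means, "sds": self.transform.sds},
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SSFModelFit":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        tp = d["transform"]
        return cls(
            terms=tuple(d["terms"]),
            beta=np.asarray(d["beta"]),
            se=np.asarray(d["se"]),
            vcov=np.asarray(d["vcov"]),
            loglik=d["loglik"],
            n_strata=d["n_strata"],
            n_rows=d["n_rows"],
            converged=d["converged"],
            method=d.get("method", "fixed"),
            transform=None if tp is None else TransformParams(tp["means"], tp["sds"]),
            random_slope_sd=d.get("random_slope_sd"),
            warnings=d.get("warnings", []),
            n_iter=d.get("n_iter", 0),
        )


def fit_conditional_logit(
    design: DesignMatrices,
    transform: TransformParams | None = None,
    max_iter: int = 500,
    gtol: float = 1e-6,
    beta_cap: float = 50.0,
) -> SSFModelFit:
    """Fixed-effects fit by damped Newton iteration.

    Convergence requires the gradient sup-norm below ``gtol``.  A coefficient
    norm above ``beta_cap`` on the z scale signals quasi-separation (some
    covariate perfectly ranks the used steps) and raises, naming the worst
    covariate.
    """
    X, y = design.X, design.y
    starts, counts = design.starts, design.counts
    beta = np.zeros(X.shape[1])
    nll, grad, H = nll_grad_hess(beta, X, y, starts, counts)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.abs(grad).max() < gtol:
            break
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.trace(H) / len(grad)
            step = np.linalg.solve(H + ridge * np.eye(len(grad)), grad)
        t = 1.0
        for _ in range(60):
            cand = beta - t * step
            cand_nll, cand_grad, cand_H = nll_grad_hess(cand, X, y, starts, counts)
            if cand_nll <= nll + 1e-12:
                break
            t /= 2
        beta, nll, grad, H = cand, cand_nll, cand_grad, cand_H
        if np.linalg.norm(beta) > beta_cap:
            worst = TERMS[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"coefficients diverged (||beta|| > {beta_cap}); covariate '{worst}' "
                "appears to separate used from available steps"
            )
    converged = bool(np.abs(grad).max() < gtol)
    if not converged:
        raise RuntimeError(
            f"conditional logit did not converge in {max_iter} iterations "
            f"(|grad|_inf = {np.abs(grad).max():.3e})"
        )
    vcov = np.linalg.inv(H)
    se = np.sqrt(np.diag(vcov))
    return SSFModelFit(
        terms=TERMS, beta=beta, se=se, vcov=vcov, loglik=-nll,
        n_strata=design.n_strata, n_rows=len(y), converged=converged,
        method="fixed", transform=transform, n_iter=n_iter,
    )


# --- mixed model (Laplace) ----------------------------------------------


def _per_individual_slices(design: DesignMatrices):
    idx = design.individual
    starts = np.flatnonzero(np.r_[True, np.diff(idx) != 0])
    ends = np.r_[starts[1:], len(idx)]
    return [(idx[s], slice(s, e)) for s, e in zip(starts, ends)]


def _inner_mode(beta, sigma2, Xg, yg, starts_g, counts_g, Zcols, u0):
    """Mode of the penalized per-individual conditional log-likelihood over
    the random slopes u, by Newton iteration (dimension = len(Zcols))."""
    u = u0.copy()
    Dinv = 1.0 / sigma2
    offset = Xg @ beta
    Z = Xg[:, Zcols]
    for _ in range(50):
        eta = offset + Z @ u
        mx, ex, denom = _segments(eta, starts_g, counts_g)
        p = ex / np.repeat(denom, counts_g)
        g = Z.T @ (p - yg) + Dinv * u
        Zp = Z * p[:, None]
        M = np.add.reduceat(Zp, starts_g, axis=0)
        Hc = Z.T @ Zp - M.T @ M
        H = Hc + np.diag(Dinv)
        step = np.linalg.solve(H, g)
        u = u - step
        if np.abs(step).max() < 1e-10:
            break
    eta = offset + Z @ u
    mx, ex, denom = _segments(eta, starts_g, counts_g)
    lse = np.log(denom) + mx
    cnll = lse.sum() - eta[yg == 1].sum()
    p = ex / np.repeat(denom, counts_g)
    Zp = Z * p[:, None]
    M = np.add.reduceat(Zp, starts_g, axis=0)
    Hc = Z.T @ Zp - M.T @ M
    H = Hc + np.diag(Dinv)
    f = cnll + 0.5 * float(u @ (Dinv * u))
    return u, f, H


def fit_mixed_conditional_logit(
    design: DesignMatrices,
    transform: TransformParams | None = None,
    random_terms=RANDOM_TERMS,
    max_iter: int = 200,
    compute_se: bool = True,
    sd_bounds=(1e-4, 10.0),
) -> SSFModelFit:
    """Conditional logit with independent Gaussian random slopes per
    individual on the ``random_terms`` covariates, Laplace-approximated.

    Falls back to the fixed-effects fit (with a prominent warning recorded on
    the fit object) if the marginal optimization fails.  Standard errors for
    the fixed effects condition on the estimated variance components.
    """
    labels = design.individual_labels
    if len(labels) < 5:
        raise ValueError(
            f"only {len(labels)} individuals: random slopes are not identifiable; "
            "use fit_conditional_logit instead"
        )
    Zcols = [TERMS.index(t) for t in random_terms]
    groups = _per_individual_slices(design)
    per_group = []
    for gid, sl in groups:
        strat = design.stratum[sl]
        s = np.flatnonzero(np.r_[True, np.diff(strat) != 0])
        c = np.diff(np.r_[s, sl.stop - sl.start])
        per_group.append((gid, sl, s, c))

    base = fit_conditional_logit(design, transform)
    q = len(Zcols)
    modes = {gid: np.zeros(q) for gid, *_ in per_group}

    def marginal_nll(theta):
        beta = theta[:-q]
        log_sd = theta[-q:]
        sigma2 = np.exp(2 * log_sd)
        total = 0.0
        for gid, sl, s, c in per_group:
            u, f, H = _inner_mode(beta, sigma2, design.X[sl], design.y[sl], s, c, Zcols, modes[gid])
            modes[gid] = u
            sign, logdetH = np.linalg.slogdet(H)
            if sign <= 0:
                return 1e10
            total += f + 0.5 * logdetH + float(np.sum(log_sd))
        return total

    theta0 = np.r_[base.beta, np.full(q, np.log(0.3))]
    bounds = [(None, None)] * len(base.beta) + [(np.log(sd_bounds[0]), np.log(sd_bounds[1]))] * q
    warnings_list: list[str] = []
    try:
        res = optimize.minimize(
            marginal_nll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-7},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("non-finite marginal likelihood")
    except Exception as exc:  # pragma: no cover - defensive fallback
        msg = f"mixed-model Laplace optimization failed ({exc}); falling back to fixed effects"
        log.warning(msg)
        base.warnings.append(msg)
        return base
    if not res.success:
        msg = f"mixed-model optimizer stopped without full convergence: {res.message}"
        log.warning(msg)
        warnings_list.append(msg)

    beta = res.x[:-q]
    sds = np.exp(res.x[-q:])
    if compute_se:
        def beta_nll(b):
            return marginal_nll(np.r_[b, res.x[-q:]])

        k = len(beta)
        h = 1e-4 * np.maximum(np.abs(beta), 1.0)
        Hnum = np.zeros((k, k))
        f0 = beta_nll(beta)
        fi = np.empty(k)
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            fi[i] = beta_nll(beta + e)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            for j in range(i, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                fij = beta_nll(beta + ei + ej)
                Hnum[i, j] = Hnum[j, i] = (fij - fi[i] - fi[j] + f0) / (h[i] * h[j])
        try:
            vcov = np.linalg.inv(Hnum)
            se = np.sqrt(np.clip(np.diag(vcov), 0, None))
        except np.linalg.LinAlgError:
            vcov = np.full((k, k), np.nan)
            se = np.full(k, np.nan)
            warnings_list.append("singular numerical information; SEs unavailable")
    else:
        vcov = np.full((len(beta), len(beta)), np.nan)
        se = np.full(len(beta), np.nan)

    final = marginal_nll(res.x)  # refresh modes at the optimum
    mode_rows = pd.DataFrame(
        {"individual_id": [labels[gid] for gid, *_ in per_group]}
        | {t: [modes[gid][k] for gid, *_ in per_group] for k, t in enumerate(random_terms)}
    )
    return SSFModelFit(
        terms=TERMS, beta=beta, se=se, vcov=vcov, loglik=-final,
        n_strata=design.n_strata, n_rows=len(design.y), converged=bool(res.success),
        method="mixed", transform=transform,
        random_slope_sd={t: float(sds[k]) for k, t in enumerate(random_terms)},
        random_modes=mode_rows, warnings=warnings_list, n_iter=int(res.nit),
    )


def normalized_rmse(fit: SSFModelFit, design: DesignMatrices) -> float:
    """RMSE of the inverse-logit fixed-effects prediction against the 0/1
    used indicator, normalized by the observed indicator's range."""
    p = expit(design.X @ fit.beta)
    y = design.y
    rng = y.max() - y.min()
    if rng == 0:
        raise ValueError("used indicator has zero range; nRMSE undefined")
    return float(np.sqrt(np.mean((p - y) ** 2)) / rng)
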