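"""Variance-components linear mixed models with a kinship kernel.

The engine fits, by REML, models of the form::

    y = X beta + u + v + e,   u ~ N(0, sigma_g^2 * 2K),
                              v ~ N(0, sigma_v^2 * B),
                              e ~ N(0, sigma_e^2 * I)

where ``2K`` is twice the kinship matrix (the additive genetic kernel) and
``B`` is a block-diagonal matrix of ones within families (a shared-family
environmental kernel).  Either random kernel may be omitted; the identity
residual is always present.  This powers single-probe association scans,
module-eigengene association tests, expression decorrelation, and probe
heritability estimation.

Estimation profiles out the fixed effects and the residual scale: with
``V(theta) = I + sum_q theta_q * K_q`` (theta_q = sigma_q^2 / sigma_e^2)
the restricted log-likelihood is maximized over the non-negative variance
ratios.  The search runs a Nelder-Mead over the interior in log-ratio space
plus bounded searches on every boundary sub-model (each subset of ratios
pinned to zero), and returns the best evaluated point, so negative
component estimates can never occur and boundary solutions are exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedkin import KinshipMatrix, Pedigree

__all__ = [
    "LMMError",
    "ConvergenceError",
    "LMMSpec",
    "LMMFit",
    "fit_lmm",
    "wald_test",
    "decorrelate",
    "heritability",
    "genetic_kernel",
    "family_block_kernel",
    "reml_grid_fit",
]

logger = logging.getLogger(__name__)

_LOG_THETA_LO = -12.0
_LOG_THETA_HI = 6.0


class LMMError(ValueError):
    """Invalid mixed-model specification."""


class ConvergenceError(RuntimeError):
    """REML optimizer failed; carries the last iterate in ``last_theta``."""

    def __init__(self, message: str, last_theta: np.ndarray | None = None):
        super().__init__(message)
        self.last_theta = last_theta


@dataclass
class LMMSpec:
    """A mixed-model problem: response, fixed design, random kernels.

    ``kernels`` lists the non-identity covariance structures as
    ``(name, matrix)`` pairs (e.g. ``("genetic", 2K)``,
    ``("family", B)``); the identity residual kernel is implicit and
    always present.  Column 0 of ``fixed_design`` is expected to be the
    intercept.
    """

    response: np.ndarray
    fixed_design: np.ndarray
    kernels: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float).ravel()
        self.fixed_design = np.atleast_2d(np.asarray(self.fixed_design, dtype=float))
        n = self.response.shape[0]
        if self.fixed_design.shape[0] != n:
            raise LMMError("response and fixed design have different lengths")
        for name, K in self.kernels:
            K = np.asarray(K, dtype=float)
            if K.shape != (n, n):
                raise LMMError(f"kernel {name!r} shape {K.shape} != ({n}, {n})")
            if not np.allclose(K, K.T, atol=1e-10):
                raise LMMError(f"kernel {name!r} is not symmetric")
        if n < self.fixed_design.shape[1] + 2:
            raise LMMError("need at least n_fixed_effects + 2 observations")


@dataclass
class LMMFit:
    """REML fit: variance components, GLS fixed effects, residuals."""

    variance_components: dict[str, float]
    beta: np.ndarray
    beta_se: np.ndarray
    reml_loglik: float
    conditional_residuals: np.ndarray
    marginal_residuals: np.ndarray
    n_obs: int
    n_fixed: int
    kernel_names: list[str]
    n_evaluations: int = 0

    @property
    def sigma_e2(self) -> float:
        return self.variance_components["residual"]


def genetic_kernel(K: KinshipMatrix, sample_ids: Sequence[str]) -> np.ndarray:
    """Additive genetic covariance structure 2K for the given samples."""
    return 2.0 * K.subset(list(sample_ids)).values


def family_block_kernel(ped: Pedigree, sample_ids: Sequence[str]) -> np.ndarray:
    """Shared-environment kernel: 1 within a family, 0 across families."""
    fams = np.array([ped.family_of(s) for s in sample_ids])
    return (fams[:, None] == fams[None, :]).astype(float)


def _check_psd(name: str, K: np.ndarray) -> None:
    w = np.linalg.eigvalsh(K)
    if w[0] < -1e-8 * max(1.0, abs(w[-1])):
        raise LMMError(f"kernel {name!r} is not positive semidefinite")


def _reml_objective(theta, y, X, kernels):
    """Profiled restricted log-likelihood at variance ratios theta.

    Returns (loglik, extras) with extras holding the quantities needed to
    finish the fit at the optimum.
    """
    n, p = X.shape
    V = np.eye(n)
    for th, (_, K) in zip(theta, kernels):
        if th > 0:
            V += th * K
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf, None
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    Xt = linalg.solve_triangular(L, X, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    XtX = Xt.T @ Xt
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    if sign <= 0:
        raise LMMError("fixed design is singular (rank-deficient)")
    beta = linalg.solve(XtX, Xt.T @ yt, assume_a="pos")
    resid_t = yt - Xt @ beta
    rss = float(resid_t @ resid_t)
    df = n - p
    sigma2 = rss / df
    if sigma2 <= 0:
        return -np.inf, None
    ll = -0.5 * (df * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_V + logdet_XtX)
    return ll, {"beta": beta, "sigma2": sigma2, "L": L, "XtX": XtX}


def fit_lmm(spec: LMMSpec, tol: float = 1e-8, max_iter: int = 2000) -> LMMFit:
    """REML fit of a variance-components mixed model.

    The variance ratios of all non-identity kernels are optimized jointly;
    every boundary sub-model (subsets of ratios fixed at zero) is searched
    as well and the best evaluated point wins.  With no non-identity
    kernel the fit collapses to ordinary least squares.
    """
    y = spec.response
    X = spec.fixed_design
    kernels = [(name, np.asarray(K, dtype=float)) for name, K in spec.kernels]
    for name, K in kernels:
        _check_psd(name, K)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise LMMError("fixed design is singular (rank-deficient)")

    k = len(kernels)
    n_eval = 0

    # Degenerate response: OLS residual variance ~ 0 (e.g. a constant probe).
    beta_ols, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    ols_resid = y - X @ beta_ols
    if float(ols_resid @ ols_resid) < 1e-12 * max(1.0, float(y @ y)):
        warnings.warn("response is (numerically) fully explained by the fixed "
                      "design; returning a zero-variance fit")
        comps = {name: 0.0 for name, _ in kernels}
        comps["residual"] = 0.0
        return LMMFit(comps, beta_ols, np.full(p, np.nan), np.inf,
                      np.zeros(n), ols_resid, n, p, [nm for nm, _ in kernels])

    def objective(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        ll, _ = _reml_objective(theta, y, X, kernels)
        return -ll

    best_theta = np.zeros(k)
    best_nll = objective(best_theta)  # all-zero boundary == OLS

    # Optimize every sub-model with a non-empty active set.
    for size in range(1, k + 1):
        for active in combinations(range(k), size):
            def nll_active(log_t: np.ndarray) -> float:
                theta = np.zeros(k)
                theta[list(active)] = np.exp(np.atleast_1d(log_t))
                return objective(theta)

            if size == 1:
                res = optimize.minimize_scalar(
                    lambda lt: nll_active(np.array([lt])),
                    bounds=(_LOG_THETA_LO, _LOG_THETA_HI),
                    method="bounded",
                    options={"xatol": 1e-6},
                )
                x = np.array([res.x])
                fun = res.fun
            else:
                # equal-thirds start: all variances equal => ratios 1
                res = optimize.minimize(
                    nll_active,
                    x0=np.zeros(size),
                    method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": tol,
                             "maxiter": max_iter, "maxfev": max_iter},
                )
                x = res.x
                fun = res.fun
                if not res.success and not np.isfinite(fun):
                    raise ConvergenceError(
                        f"REML optimizer failed for active set {active}",
                        last_theta=np.exp(x),
                    )
            if fun < best_nll - 0.0:
                best_nll = fun
                best_theta = np.zeros(k)
                best_theta[list(active)] = np.exp(x)

    # Tiny ratios from the bounded log search are boundary solutions.
    best_theta[best_theta < 2.0 * np.exp(_LOG_THETA_LO)] = 0.0

    ll, extras = _reml_objective(best_theta, y, X, kernels)
    if extras is None:
        raise ConvergenceError("REML objective undefined at the optimum",
                               last_theta=best_theta)
    sigma_e2 = extras["sigma2"]
    beta = extras["beta"]
    L = extras["L"]
    XtX = extras["XtX"]
    beta_cov = sigma_e2 * linalg.inv(XtX)
    beta_se = np.sqrt(np.diag(beta_cov))

    marginal = y - X @ beta
    # conditional residuals: e_hat = sigma_e^2 * Vfull^{-1} * marginal
    #                              = V(theta)^{-1} * marginal  (scale cancels)
    Vinv_r = linalg.cho_solve((L, True), marginal)
    conditional = Vinv_r  # == sigma_e2 * (sigma_e2*V)^{-1} r

    comps = {name: float(th * sigma_e2) for (name, _), th in zip(kernels, best_theta)}
    comps["residual"] = float(sigma_e2)
    return LMMFit(
        variance_components=comps,
        beta=beta,
        beta_se=beta_se,
        reml_loglik=float(ll),
        conditional_residuals=conditional,
        marginal_residuals=marginal,
        n_obs=n,
        n_fixed=p,
        kernel_names=[name for name, _ in kernels],
        n_evaluations=n_eval,
    )


def wald_test(fit: LMMFit, column: int) -> tuple[float, float, float]:
    """Two-sided Wald test of one fixed effect against a standard normal.

    ``column`` indexes a non-intercept column of the fixed design.
    Returns ``(beta, se, p)``.
    """
    if column == 0:
        raise LMMError("column 0 is the intercept; test a covariate column")
    if not 0 < column < fit.n_fixed:
        raise LMMError(f"column {column} out of range for {fit.n_fixed} fixed effects")
    beta = float(fit.beta[column])
    se = float(fit.beta_se[column])
    if not np.isfinite(se) or se <= 0:
        raise LMMError("standard error unavailable for the requested effect")
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta, se, float(p)


def heritability(fit: LMMFit) -> float:
    """Narrow-sense heritability sigma_g^2 / (sigma_g^2 + sigma_v^2 + sigma_e^2)."""
    total = sum(fit.variance_components.values())
    if total <= 0:
        raise LMMError("all variance components are zero; heritability undefined")
    return fit.variance_components.get("genetic", 0.0) / total


# ---------------------------------------------------------------------------
# Batched grid REML for many responses sharing one design and kernel set.
# ---------------------------------------------------------------------------

_DEFAULT_GRID = np.concatenate([[0.0], np.geomspace(0.02, 24.0, 13)])


def reml_grid_fit(
    Y: np.ndarray,
    X: np.ndarray,
    kernels: Sequence[tuple[str, np.ndarray]],
    grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Profile-REML over a shared variance-ratio grid for many responses.

    ``Y`` is responses-by-samples.  All responses share ``X`` and the
    kernels, so each grid point's Cholesky factorization is computed once
    and applied to every response.  For each response the best grid point
    is selected; exact per-response ``fit_lmm`` gives the same answer up
    to grid resolution and is the reference path.

    Returns a DataFrame with one row per response (variance components,
    heritability, restricted log-likelihood) and the matrix of
    conditional residuals, same shape as ``Y``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P, n = Y.shape
    p = X.shape[1]
    df = n - p
    if grid is None:
        grid = _DEFAULT_GRID
    k = len(kernels)
    axes = [np.asarray(grid, dtype=float)] * k
    mesh = np.meshgrid(*axes, indexing="ij") if k else []
    thetas = (np.stack([m.ravel() for m in mesh], axis=1)
              if k else np.zeros((1, 0)))

    Yc = Y.T  # n x P
    best_ll = np.full(P, -np.inf)
    best_idx = np.zeros(P, dtype=int)
    const = -0.5 * df * (np.log(2.0 * np.pi) + 1.0 - np.log(df))
    for g, theta in enumerate(thetas):
        V = np.eye(n)
        for th, (_, K) in zip(theta, kernels):
            if th > 0:
                V += th * K
        L = linalg.cholesky(V, lower=True)
        logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
        Xt = linalg.solve_triangular(L, X, lower=True)
        Yt = linalg.solve_triangular(L, Yc, lower=True)
        XtX = Xt.T @ Xt
        sign, logdet_XtX = np.linalg.slogdet(XtX)
        if sign <= 0:
            raise LMMError("fixed design is singular (rank-deficient)")
        B = linalg.solve(XtX, Xt.T @ Yt, assume_a="pos")  # p x P
        R = Yt - Xt @ B
        rss = np.einsum("ij,ij->j", R, R)
        with np.errstate(divide="ignore"):
            ll = const - 0.5 * (df * np.log(rss) + logdet_V + logdet_XtX)
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_idx[better] = g

    # Final pass: components and conditional residuals at each probe's optimum.
    comps = np.zeros((P, k))
    sigma_e2 = np.zeros(P)
    resid = np.zeros_like(Y)
    for g in np.unique(best_idx):
        sel = best_idx == g
        theta = thetas[g]
        V = np.eye(n)
        for th, (_, K) in zip(theta, kernels):
            if th > 0:
                V += th * K
        L = linalg.cholesky(V, lower=True)
        Xt = linalg.solve_triangular(L, X, lower=True)
        Yt = linalg.solve_triangular(L, Yc[:, sel], lower=True)
        XtX = Xt.T @ Xt
        B = linalg.solve(XtX, Xt.T @ Yt, assume_a="pos")
        marginal = Yc[:, sel] - X @ B
        cond = linalg.cho_solve((L, True), marginal)
        resid[sel, :] = cond.T
        Rt = Yt - Xt @ B
        s2 = np.einsum("ij,ij->j", Rt, Rt) / df
        sigma_e2[sel] = s2
        comps[sel, :] = theta[None, :] * s2[:, None]

    out = pd.DataFrame(
        {name: comps[:, q] for q, (name, _) in enumerate(kernels)}
    )
    out["residual"] = sigma_e2
    total = out.sum(axis=1).to_numpy()
    genetic = out["genetic"].to_numpy() if "genetic" in out else np.zeros(P)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["h2"] = np.where(total > 0, genetic / total, np.nan)
    out["reml_loglik"] = best_ll
    return out, resid


def decorrelate(
    expr: pd.DataFrame,
    K: KinshipMatrix,
    ped: Pedigree,
    marginal: bool = False,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Remove family structure from expression by per-probe mixed models.

    Each probe (row) is fitted with an intercept-only model carrying the
    genetic (2K), shared-family and identity kernels; the probe is replaced
    by the fit's conditional residuals (or marginal residuals when
    ``marginal=True``).  Conditional residuals subtract the BLUPs of the
    random effects and therefore remove within-family covariance, not just
    family means.

    Probes with (numerically) zero variance are replaced by zero rows and
    reported via a warning.
    """
    sample_ids = list(expr.columns)
    missing = [s for s in sample_ids if s not in K.ids]
    if missing:
        raise LMMError(f"samples absent from kinship matrix: {missing[:5]}")
    kernels = [
        ("genetic", genetic_kernel(K, sample_ids)),
        ("family", family_block_kernel(ped, sample_ids)),
    ]
    Y = expr.to_numpy(dtype=float)
    sd = Y.std(axis=1)
    flat = sd < 1e-12
    if flat.any():
        names = list(expr.index[flat])
        warnings.warn(f"{flat.sum()} constant probe(s) set to zero residuals: "
                      f"{names[:5]}")
        logger.warning("constant probes in decorrelate: %s", names[:10])
    X = np.ones((Y.shape[1], 1))
    out = np.zeros_like(Y)
    if (~flat).any():
        fits, resid = reml_grid_fit(Y[~flat], X, kernels, grid=grid)
        if marginal:
            resid = _marginal_residuals(Y[~flat], X, kernels, fits)
        out[~flat] = resid
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def _marginal_residuals(Y, X, kernels, fits: pd.DataFrame) -> np.ndarray:
    resid = np.zeros_like(Y)
    n = Y.shape[1]
    for i in range(Y.shape[0]):
        V = fits.iloc[i]["residual"] * np.eye(n)
        for name, K in kernels:
            V += fits.iloc[i][name] * K
        L = linalg.cholesky(V, lower=True)
        Xt = linalg.solve_triangular(L, X, lower=True)
        yt = linalg.solve_triangular(L, Y[i], lower=True)
        beta = linalg.solve(Xt.T @ Xt, Xt.T @ yt, assume_a="pos")
        resid[i] = Y[i] - X @ beta
    return resid
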