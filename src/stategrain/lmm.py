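"""Linear mixed models with crossed random effects.

A compact REML fitter for models of the form::

    y = X beta + Z b + e,   b ~ N(0, sigma^2 Lambda Lambda'),  e ~ N(0, sigma^2 I)

where Z collects one block per random *term* (a grouping factor with a
per-observation design, e.g. intercept + slope), and Lambda is
block-diagonal with one small relative-covariance factor per term
repeated over that factor's levels.  The profiled REML criterion and
its Cholesky-based evaluation follow the standard mixed-model
equations; degrees of freedom for fixed-effect contrasts use the
Satterthwaite approximation, computed from finite-difference
derivatives of the contrast variance with respect to the variance
parameters and the curvature of the REML deviance — the reference
behavior of the usual fractional-df t tests for such models.

The model sizes here (a few hundred levels per factor) keep the q × q
system small enough for dense Cholesky factorizations, which makes the
fitter simple and fast without sparse solvers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

__all__ = ["RandomTerm", "MixedLMResult", "ConvergenceError", "fit_lmm"]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """REML optimization failed to converge."""


@dataclass
class RandomTerm:
    """One random-effects term: ``(design | groups)``.

    ``groups`` are integer level codes (0..g−1) per observation and
    ``design`` the within-level regressors, shape (n, k) — e.g. a column
    of ones plus a slope code.  ``diagonal=True`` fixes the
    between-column correlations of the term's covariance at zero.
    """

    name: str
    groups: np.ndarray
    design: np.ndarray
    colnames: list[str] = field(default_factory=list)
    diagonal: bool = False

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=int)
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.design.shape[0] != len(self.groups):
            raise ValueError("design rows must match group codes")
        if not self.colnames:
            self.colnames = [f"{self.name}{j}" for j in range(self.design.shape[1])]

    @property
    def n_levels(self) -> int:
        return int(self.groups.max()) + 1

    @property
    def k(self) -> int:
        return self.design.shape[1]

    @property
    def n_theta(self) -> int:
        return self.k if self.diagonal else self.k * (self.k + 1) // 2

    def lambda_factor(self, th: np.ndarray) -> np.ndarray:
        lam = np.zeros((self.k, self.k))
        if self.diagonal:
            np.fill_diagonal(lam, th)
        else:
            lam[np.tril_indices(self.k)] = th
        return lam

    def theta_start(self) -> np.ndarray:
        th = np.zeros(self.n_theta)
        if self.diagonal:
            th[:] = 1.0
        else:
            lam = np.eye(self.k)
            th = lam[np.tril_indices(self.k)]
        return th

    def theta_bounds(self) -> list[tuple[float | None, float | None]]:
        if self.diagonal:
            return [(0.0, None)] * self.k
        bounds = []
        rows, cols = np.tril_indices(self.k)
        for r, c in zip(rows, cols):
            bounds.append((0.0, None) if r == c else (None, None))
        return bounds

    def build_z(self) -> sparse.csr_matrix:
        n, k, g = len(self.groups), self.k, self.n_levels
        rows = np.repeat(np.arange(n), k)
        cols = (self.groups[:, None] * k + np.arange(k)[None, :]).ravel()
        return sparse.csr_matrix(
            (self.design.ravel(), (rows, cols)), shape=(n, g * k)
        )


@dataclass
class MixedLMResult:
    """Fitted mixed model: fixed effects, variance components, diagnostics."""

    fixed_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: np.ndarray
    p: np.ndarray
    sigma2: float
    theta: np.ndarray
    terms: list[RandomTerm]
    term_cov: dict[str, np.ndarray]  # per-term covariance sigma^2 * lam lam'
    cov_beta: np.ndarray
    deviance: float
    n: int
    converged: bool
    singular: bool
    notes: list[str] = field(default_factory=list)
    _state: dict = field(default_factory=dict, repr=False)

    @property
    def p_fixed(self) -> int:
        return len(self.beta)

    def variance_components(self) -> dict[str, float]:
        out = {}
        for term in self.terms:
            cov = self.term_cov[term.name]
            for j, name in enumerate(term.colnames):
                out[f"{term.name}:{name}"] = float(cov[j, j])
        out["residual"] = float(self.sigma2)
        return out

    def contrast(self, c: np.ndarray) -> tuple[float, float, float, float, float]:
        """Estimate, SE, t, Satterthwaite df, p for a fixed-effect contrast."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        var = float(c @ self.cov_beta @ c)
        se = np.sqrt(var)
        tval = est / se
        df = _satterthwaite_df(self._state, c)
        pval = 2.0 * stats.t.sf(abs(tval), df=df)
        return est, se, tval, df, pval


# ---------------------------------------------------------------------
# profiled REML machinery
# ---------------------------------------------------------------------

class _REMLProblem:
    def __init__(self, y: np.ndarray, X: np.ndarray, terms: list[RandomTerm]):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            raise ValueError("X rows must match y")
        self.y, self.X, self.terms = y, X, terms
        self.n, self.p = X.shape
        Z = sparse.hstack([t.build_z() for t in terms], format="csr")
        self.q = Z.shape[1]
        self.ZtZ = np.asarray((Z.T @ Z).todense())
        self.ZtX = np.asarray(Z.T @ X)
        self.Zty = np.asarray(Z.T @ y).ravel()
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.Z = Z
        # slices of theta per term and of Z columns per term
        self.theta_slices, self.col_slices = [], []
        i = j = 0
        for t in terms:
            self.theta_slices.append(slice(i, i + t.n_theta))
            self.col_slices.append(slice(j, j + t.n_levels * t.k))
            i += t.n_theta
            j += t.n_levels * t.k

    def lambda_sparse(self, theta: np.ndarray) -> sparse.csr_matrix:
        blocks = []
        for t, sl in zip(self.terms, self.theta_slices):
            lam = t.lambda_factor(theta[sl])
            blocks.append(sparse.kron(sparse.eye(t.n_levels), lam, format="csr"))
        return sparse.block_diag(blocks, format="csr")

    def _decompose(self, theta: np.ndarray):
        lam = self.lambda_sparse(theta)
        A = np.asarray((lam.T @ self.ZtZ) @ lam.todense())
        A[np.diag_indices_from(A)] += 1.0
        L = cholesky(A, lower=True, check_finite=False)
        ztx = np.asarray(lam.T @ self.ZtX)
        zty = np.asarray(lam.T @ self.Zty).ravel()
        cu = solve_triangular(L, zty, lower=True, check_finite=False)
        RZX = solve_triangular(L, ztx, lower=True, check_finite=False)
        rxtrx = self.XtX - RZX.T @ RZX
        RX = cholesky(rxtrx, lower=True, check_finite=False)
        cb = solve_triangular(RX, self.Xty - RZX.T @ cu, lower=True,
                              check_finite=False)
        beta = solve_triangular(RX.T, cb, lower=False, check_finite=False)
        pwrss = max(self.yty - cu @ cu - cb @ cb, 1e-12)
        logdet_l = 2.0 * np.log(np.diag(L)).sum()
        logdet_rx = 2.0 * np.log(np.diag(RX)).sum()
        return beta, pwrss, logdet_l, logdet_rx, rxtrx

    def profiled_deviance(self, theta: np.ndarray) -> float:
        try:
            _, pwrss, ld_l, ld_rx, _ = self._decompose(theta)
        except np.linalg.LinAlgError:
            return np.inf
        nmp = self.n - self.p
        return ld_l + ld_rx + nmp * (1.0 + np.log(2.0 * np.pi * pwrss / nmp))

    def deviance_full(self, theta: np.ndarray, sigma: float) -> float:
        """REML deviance with sigma not profiled out (for the Hessian)."""
        _, pwrss, ld_l, ld_rx, _ = self._decompose(theta)
        nmp = self.n - self.p
        return (
            ld_l + ld_rx + nmp * np.log(2.0 * np.pi * sigma**2) + pwrss / sigma**2
        )

    def contrast_variance(self, theta: np.ndarray, sigma: float, c: np.ndarray) -> float:
        *_, rxtrx = self._decompose(theta)
        sol = cho_solve(cho_factor(rxtrx, check_finite=False), c)
        return sigma**2 * float(c @ sol)


def _satterthwaite_df(state: dict, c: np.ndarray) -> float:
    """Satterthwaite df: 2·Var(c'β̂)² / Var̂(Var(c'β̂)) via the delta method."""
    prob: _REMLProblem = state["problem"]
    theta, sigma = state["theta"], state["sigma"]
    phi = np.concatenate([theta, [sigma]])
    vcov_phi = state.get("vcov_phi")
    if vcov_phi is None:
        vcov_phi = _vcov_variance_params(prob, theta, sigma)
        state["vcov_phi"] = vcov_phi

    def f(ph: np.ndarray) -> float:
        return prob.contrast_variance(ph[:-1], abs(ph[-1]), c)

    h = 1e-4 * np.maximum(np.abs(phi), 1.0)
    grad = np.zeros_like(phi)
    for i in range(len(phi)):
        e = np.zeros_like(phi)
        e[i] = h[i]
        grad[i] = (f(phi + e) - f(phi - e)) / (2 * h[i])
    fval = f(phi)
    denom = float(grad @ vcov_phi @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return float(prob.n - prob.p)  # flat curvature: residual-df fallback
    df = 2.0 * fval**2 / denom
    return float(np.clip(df, 1.0, prob.n - prob.p))


def _vcov_variance_params(
    prob: _REMLProblem, theta: np.ndarray, sigma: float
) -> np.ndarray:
    """Asymptotic covariance of (θ, σ): 2·H⁻¹ of the REML deviance."""
    phi = np.concatenate([theta, [sigma]])
    m = len(phi)
    h = 1e-4 * np.maximum(np.abs(phi), 1.0)

    def g(ph: np.ndarray) -> float:
        return prob.deviance_full(ph[:-1], abs(ph[-1]))

    H = np.zeros((m, m))
    f0 = g(phi)
    for i in range(m):
        ei = np.zeros(m)
        ei[i] = h[i]
        H[i, i] = (g(phi + ei) - 2 * f0 + g(phi - ei)) / h[i] ** 2
        for j in range(i + 1, m):
            ej = np.zeros(m)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                g(phi + ei + ej) - g(phi + ei - ej) - g(phi - ei + ej)
                + g(phi - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        return 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("singular deviance Hessian; using pseudo-inverse for df")
        return 2.0 * np.linalg.pinv(H)


_SINGULAR_TOL = 1e-4


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    fixed_names: list[str],
    terms: list[RandomTerm],
    xtol: float = 1e-8,
) -> MixedLMResult:
    """Fit by profiled REML and return fixed effects with Satterthwaite df.

    The optimizer runs over the relative-covariance parameters θ
    (Cholesky factors per term, diagonal bounded at zero).  A fit is
    flagged ``singular`` when any diagonal θ lands on (or numerically
    at) the zero boundary.
    """
    prob = _REMLProblem(y, X, terms)
    theta0 = np.concatenate([t.theta_start() for t in terms])
    bounds = [b for t in terms for b in t.theta_bounds()]
    res = optimize.minimize(
        prob.profiled_deviance,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": xtol},
    )
    converged = bool(res.success)
    if not converged:
        logger.warning("REML optimizer did not report success: %s", res.message)
    theta = res.x
    beta, pwrss, *_ , rxtrx = prob._decompose(theta)
    sigma2 = pwrss / (prob.n - prob.p)
    cov_beta = sigma2 * np.linalg.inv(rxtrx)

    singular = False
    term_cov = {}
    for t, sl in zip(prob.terms, prob.theta_slices):
        lam = t.lambda_factor(theta[sl])
        term_cov[t.name] = sigma2 * lam @ lam.T
        if np.any(np.abs(np.diag(lam)) < _SINGULAR_TOL):
            singular = True

    state = {"problem": prob, "theta": theta, "sigma": float(np.sqrt(sigma2))}
    p = len(beta)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    dfs = np.empty(p)
    pvals = np.empty(p)
    for j in range(p):
        c = np.zeros(p)
        c[j] = 1.0
        dfs[j] = _satterthwaite_df(state, c)
        pvals[j] = 2.0 * stats.t.sf(abs(tvals[j]), df=dfs[j])

    return MixedLMResult(
        fixed_names=list(fixed_names),
        beta=beta,
        se=se,
        t=tvals,
        df=dfs,
        p=pvals,
        sigma2=float(sigma2),
        theta=theta,
        terms=terms,
        term_cov=term_cov,
        cov_beta=cov_beta,
        deviance=float(res.fun),
        n=prob.n,
        converged=converged,
        singular=singular,
        _state=state,
    )
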