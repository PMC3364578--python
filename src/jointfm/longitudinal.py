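"""Longitudinal trait submodel: polynomial means and GLM covariance.

The trait of progeny ``i`` with QTL genotype ``j`` measured on occasions
``t = 1, ..., T`` is

    y_i(t) = u_j(t) + r_i(t) + e_i(t),

with a genotype mean curve ``u_j(t) = beta_j0 + beta_j1 t + ... + beta_jr t^r``,
a subject-specific random curve ``r_i(t)`` with coefficients
``theta_i ~ MVN(0, sigma^2 I)``, and residuals ``e_i ~ MVN(0, Sigma)``.

``Sigma`` is parameterized through its modified Cholesky decomposition
``M Sigma M' = D``: the unit-lower-triangular ``M`` carries the negatives of
the autoregressive coefficients ``phi_{t,t'}``, themselves a polynomial in
the lag ``t - t'`` with coefficients ``delta``, and the diagonal ``D`` holds
innovation variances ``sigma^2(t) = exp(eta_0 + eta_1 t + ...)``.  Every
finite ``(eta, delta)`` yields a symmetric positive-definite ``Sigma``,
which is what makes this an unconstrained (GLM-style) covariance regression.
Classical AR(1) and compound-symmetry structures are provided for
comparison fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

__all__ = [
    "PolyMeanModel",
    "RandomEffectModel",
    "CholeskyCovModel",
    "AR1CovModel",
    "CSCovModel",
    "design_matrix",
    "polyval_grid",
    "mean_trajectory",
    "build_M_D",
    "build_sigma",
    "build_chol",
    "marginal_moments",
    "longitudinal_loglik",
    "mvn_loglik_chol",
    "read_phenotypes",
]

LOG2PI = float(np.log(2.0 * np.pi))


def design_matrix(time_grid, order: int) -> np.ndarray:
    """T x (order+1) polynomial basis; row t is (1, t, t^2, ..., t^order)."""
    t = np.asarray(time_grid, dtype=float)
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    return np.vander(t, N=order + 1, increasing=True)


def polyval_grid(coef, time_grid) -> np.ndarray:
    """Evaluate sum_p coef[p] * t^p on a grid (increasing-power coding)."""
    return design_matrix(time_grid, len(coef) - 1) @ np.asarray(coef, float)


@dataclass
class PolyMeanModel:
    """Genotype-specific polynomial mean curves; ``beta`` is 2 x (r+1)."""

    order_r: int
    beta: np.ndarray

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, float))
        if self.beta.shape != (2, self.order_r + 1):
            raise ValueError("beta must be 2 x (order_r + 1)")


@dataclass
class RandomEffectModel:
    """Subject random curves: ``theta`` is n x (m+1), theta_i ~ MVN(0, sigma2 I)."""

    order_m: int
    theta: np.ndarray
    sigma2: float

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, float))
        if self.theta.shape[1] != self.order_m + 1:
            raise ValueError("theta must be n x (order_m + 1)")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class CholeskyCovModel:
    """Modified-Cholesky covariance: innovation variances eta, lag poly delta."""

    order_g: int
    order_h: int
    eta: np.ndarray
    delta: np.ndarray
    time_grid: np.ndarray

    def __post_init__(self):
        self.eta = np.asarray(self.eta, float)
        self.delta = np.asarray(self.delta, float)
        self.time_grid = np.asarray(self.time_grid, float)
        if self.eta.shape != (self.order_g + 1,):
            raise ValueError("eta must have length order_g + 1")
        if self.delta.shape != (self.order_h + 1,):
            raise ValueError("delta must have length order_h + 1")


def mean_trajectory(mean: PolyMeanModel, re: RandomEffectModel | None,
                    i: int, j: int, time_grid) -> np.ndarray:
    """mu_ij(t) = X^(r) beta_j + X^(m) theta_i on the time grid (j in {1, 2})."""
    if j not in (1, 2):
        raise ValueError("genotype index j must be 1 or 2")
    mu = polyval_grid(mean.beta[j - 1], time_grid)
    if re is not None:
        mu = mu + polyval_grid(re.theta[i], time_grid)
    return mu


def build_M_D(cov: CholeskyCovModel) -> tuple[np.ndarray, np.ndarray]:
    """Unit-lower-triangular M (with -phi_{t,t'} below the diagonal) and
    diagonal D of innovation variances exp(eta poly)."""
    t = cov.time_grid
    T = t.size
    M = np.eye(T)
    for a in range(T):
        for b in range(a):
            lag = t[a] - t[b]
            M[a, b] = -np.polynomial.polynomial.polyval(lag, cov.delta)
    D = np.diag(np.exp(polyval_grid(cov.eta, t)))
    return M, D


def build_chol(cov: CholeskyCovModel) -> np.ndarray:
    """Lower Cholesky factor of Sigma without forming M^{-1}.

    From M Sigma M' = D, Sigma = (M^{-1} D^{1/2})(M^{-1} D^{1/2})', and
    M^{-1} D^{1/2} is lower triangular with positive diagonal — it *is* the
    Cholesky factor, obtained by a triangular solve.
    """
    M, D = build_M_D(cov)
    return solve_triangular(M, np.diag(np.sqrt(np.diag(D))), lower=True)


def build_sigma(cov: CholeskyCovModel) -> np.ndarray:
    """Sigma = M^{-1} D M^{-T}; symmetric positive definite by construction."""
    L = build_chol(cov)
    return L @ L.T


@dataclass
class AR1CovModel:
    """First-order autoregressive comparison structure: sig2 * rho^|t-t'|."""

    sig2: float
    rho: float
    time_grid: np.ndarray

    def sigma(self) -> np.ndarray:
        t = np.asarray(self.time_grid, float)
        lag = np.abs(t[:, None] - t[None, :])
        return self.sig2 * self.rho ** lag


@dataclass
class CSCovModel:
    """Compound-symmetry comparison structure: sig2 * [(1-rho) I + rho J]."""

    sig2: float
    rho: float
    time_grid: np.ndarray

    def sigma(self) -> np.ndarray:
        T = len(self.time_grid)
        return self.sig2 * ((1.0 - self.rho) * np.eye(T) + self.rho * np.ones((T, T)))


def marginal_moments(mean: PolyMeanModel, re: RandomEffectModel,
                     cov: CholeskyCovModel, j: int, time_grid):
    """Exact marginal moments of y_i with theta_i integrated out:
    (X^(r) beta_j,  Sigma + sigma^2 X^(m) X^(m)')."""
    mu = polyval_grid(mean.beta[j - 1], time_grid)
    Xm = design_matrix(time_grid, re.order_m)
    V = build_sigma(cov) + re.sigma2 * Xm @ Xm.T
    return mu, V


def mvn_loglik_chol(resid: np.ndarray, L: np.ndarray) -> np.ndarray:
    """MVN(0, LL') log density for residual row-vectors (vectorized over rows)."""
    r = np.atleast_2d(resid)
    z = solve_triangular(L, r.T, lower=True)
    quad = np.einsum("ij,ij->j", z, z)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    out = -0.5 * (r.shape[1] * LOG2PI + logdet + quad)
    return out if resid.ndim > 1 else float(out[0])


def longitudinal_loglik(y_i, mu_ij, sigma) -> float:
    """Log MVN density of one trait vector given its mean and covariance."""
    y_i = np.asarray(y_i, float)
    mu_ij = np.asarray(mu_ij, float)
    L = np.linalg.cholesky(np.asarray(sigma, float))
    return float(mvn_loglik_chol(y_i - mu_ij, L))


def read_phenotypes(path, delimiter=None):
    """Read an n x T trait table; the header row carries the time grid.

    Returns ``(Y, time_grid)``.  Missing values are not supported: the model
    assumes complete series on a common grid.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python", index_col=0)
    if df.isna().any().any():
        raise ValueError("phenotype matrix must be complete (no missing values)")
    time_grid = np.array([float(c) for c in df.columns])
    return df.to_numpy(float), time_grid
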