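"""Joint likelihood: mixture over unobserved QTL genotypes.

Each progeny's contribution is a two-component mixture over its QTL
genotype, weighted by the flanking-marker conditional probabilities
``omega_{j|i}``:

    L(Theta | y, s) = prod_i sum_j omega_{j|i}
                        * f(y_i | Q_i = j, theta_i) * lambda_i(s_i) e^{-Lambda_i(s_i)}

with ``f`` the MVN longitudinal density (conditional on the subject random
effect ``theta_i``) and the event factor from the PH submodel.  All math is
in log space; the mixture uses log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .longitudinal import (
    CholeskyCovModel,
    PolyMeanModel,
    RandomEffectModel,
    build_sigma,
    longitudinal_loglik,
    mean_trajectory,
    polyval_grid,
)
from .survival import PiecewiseHazard, log_event_density

__all__ = ["JointModel", "subject_loglik_given_Q", "mixture_loglik"]


@dataclass
class JointModel:
    """Bundle of the two submodels plus the QTL genotype prior omega (n x 2)."""

    mean: PolyMeanModel
    re: RandomEffectModel
    cov: CholeskyCovModel
    hazard: PiecewiseHazard
    omega: np.ndarray
    time_grid: np.ndarray

    def __post_init__(self):
        self.omega = np.atleast_2d(np.asarray(self.omega, float))
        self.time_grid = np.asarray(self.time_grid, float)
        if self.omega.shape[1] != 2:
            raise ValueError("omega must be n x 2")
        if np.any(np.abs(self.omega.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("omega rows must sum to 1")


def _mu_fn(model: JointModel, i: int, j: int):
    """Continuous-time mean curve t -> mu_ij(t) for the hazard."""
    coef_b = model.mean.beta[j - 1]
    coef_t = model.re.theta[i]

    def mu(t):
        return polyval_grid(coef_b, np.atleast_1d(t))[0] + \
            polyval_grid(coef_t, np.atleast_1d(t))[0]

    return mu


def subject_loglik_given_Q(model: JointModel, i: int, j: int, y_i, s_i,
                           quad_points: int = 64) -> float:
    """log pi(y_i, s_i | Q_i = j, theta_i): MVN trait term + PH event term."""
    mu = mean_trajectory(model.mean, model.re, i, j, model.time_grid)
    ll = longitudinal_loglik(y_i, mu, build_sigma(model.cov))
    ll += log_event_density(model.hazard, _mu_fn(model, i, j), s_i, quad_points)
    return float(ll)


def mixture_loglik(model: JointModel, y, s, quad_points: int = 64) -> float:
    """Total log L(Theta | y, s), mixing over QTL genotypes per progeny."""
    y = np.atleast_2d(np.asarray(y, float))
    s = np.atleast_1d(np.asarray(s, float))
    n = y.shape[0]
    if model.omega.shape[0] != n or s.size != n:
        raise ValueError("inconsistent numbers of progeny across inputs")
    total = 0.0
    for i in range(n):
        lj = np.array([
            subject_loglik_given_Q(model, i, j, y[i], s[i], quad_points)
            for j in (1, 2)
        ])
        total += logsumexp(lj, b=model.omega[i])
    return float(total)
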