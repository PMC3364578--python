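"""Metropolis-within-Gibbs sampler for the joint QTL model.

Unknowns are the genotype mean coefficients ``beta_1, beta_2``, subject
random-effect coefficients ``theta_i`` with scale ``sigma^2``, covariance
parameters (``eta``, ``delta`` for the modified-Cholesky structure, or the
two parameters of the AR(1)/CS comparison structures), the trait-event link
``gamma``, the baseline steps ``lambda_0k``, the QTL position ``D*``, and
the latent genotypes ``Q_i``.

Updates run in a fixed systematic scan:

    beta -> theta/sigma^2 -> eta -> delta -> gamma -> lambda0 -> D* -> Q

``beta``, ``theta``, ``eta``, ``delta`` and ``gamma`` use random-walk
Metropolis-Hastings (proposal scales adapted into the 0.25-0.40 acceptance
band during burn-in only, then frozen).  ``sigma^2`` is conjugate
inverse-gamma given ``theta`` (Gibbs; an MH mode is available),
``lambda_0k`` is conjugate gamma given event counts and exposures (Gibbs),
``D*`` uses the truncated-uniform window proposal with its Hastings width
correction, and ``Q_i`` is drawn from its two-cell full conditional.

The sampler optionally tempers the likelihood (``temp`` in [0, 1]) for
power-posterior evidence estimation: all likelihood terms in MH ratios are
multiplied by ``temp``, the gamma full conditional of ``lambda_0k`` uses
tempered counts/exposures, and the ``Q`` full conditional tempers the
data term while keeping the genetic prior ``omega`` intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import LinkageMap, MarkerGenotypes, qtl_conditional_probs
from .longitudinal import design_matrix, mvn_loglik_chol, polyval_grid

__all__ = [
    "JointData",
    "ModelSpec",
    "Priors",
    "ProposalSettings",
    "MCMCState",
    "Chain",
    "Sampler",
    "run_chain",
    "draw_state_from_prior",
]

LOG2PI = float(np.log(2.0 * np.pi))
_LAM_FLOOR = 1e-290  # keep log lambda0 finite for near-zero gamma draws


# ---------------------------------------------------------------------------
# containers


@dataclass
class JointData:
    """Observed data for one linkage group: traits, events, markers."""

    y: np.ndarray           # n x T longitudinal matrix
    time_grid: np.ndarray   # length T
    s: np.ndarray           # n event times (uncensored)
    lmap: LinkageMap
    markers: MarkerGenotypes

    def __post_init__(self):
        self.y = np.atleast_2d(np.asarray(self.y, float))
        self.time_grid = np.asarray(self.time_grid, float)
        self.s = np.asarray(self.s, float)
        n = self.y.shape[0]
        if self.s.size != n or self.markers.n_progeny != n:
            raise ValueError("progeny counts differ across y, s, markers")

    @property
    def n(self) -> int:
        return self.y.shape[0]


@dataclass
class ModelSpec:
    """Model orders and structural settings."""

    order_r: int = 2
    order_m: int = 2
    order_g: int = 2
    order_h: int = 2
    K: int = 5
    quad_points: int = 64           # trapezoid sub-segments per baseline interval
    cov_structure: str = "glm"      # "glm" | "ar1" | "cs"
    knots: np.ndarray | None = None  # override baseline cut points
    sigma2_update: str = "gibbs"    # "gibbs" | "mh"

    def baseline_knots(self, s: np.ndarray) -> np.ndarray:
        if self.knots is not None:
            return np.asarray(self.knots, float)
        return np.linspace(0.0, float(np.max(s)), self.K + 1)


@dataclass
class Priors:
    """Prior hyperparameters (defaults follow the soybean application)."""

    beta_var: float = 100.0                 # Sigma_beta = beta_var * I
    sigma2_ig: tuple = (3.0, 1.0)           # inverse gamma (alpha1, alpha2)
    gamma_bounds: tuple = (-3.0, -0.1)      # uniform support
    lambda0_gamma: tuple = (0.04, 1.0)      # gamma (a, rate b), iid over k
    eta_var: float = 30.0                   # Sigma_eta = eta_var * I
    delta_var: float = 20.0                 # Sigma_delta = delta_var * I

    def log_beta(self, b):
        b = np.asarray(b, float)
        return -0.5 * (b.size * (LOG2PI + np.log(self.beta_var))
                       + np.sum(b * b) / self.beta_var)

    def log_sigma2(self, v):
        a1, a2 = self.sigma2_ig
        if v <= 0:
            return -np.inf
        return a1 * np.log(a2) - _lgamma(a1) - (a1 + 1) * np.log(v) - a2 / v

    def log_gamma_link(self, g):
        lo, hi = self.gamma_bounds
        return -np.log(hi - lo) if lo <= g <= hi else -np.inf

    def log_lambda0(self, lam):
        a, b = self.lambda0_gamma
        lam = np.asarray(lam, float)
        if np.any(lam <= 0):
            return -np.inf
        return float(np.sum(a * np.log(b) - _lgamma(a)
                            + (a - 1) * np.log(lam) - b * lam))

    def log_cov_a(self, a):
        a = np.asarray(a, float)
        return -0.5 * (a.size * (LOG2PI + np.log(self.eta_var))
                       + np.sum(a * a) / self.eta_var)

    def log_cov_b(self, b):
        b = np.asarray(b, float)
        return -0.5 * (b.size * (LOG2PI + np.log(self.delta_var))
                       + np.sum(b * b) / self.delta_var)


def _lgamma(x):
    from scipy.special import gammaln
    return float(gammaln(x))


@dataclass
class ProposalSettings:
    """Random-walk scales; adapted only during burn-in."""

    beta_scale: float = 0.05
    theta_scale: float = 0.02
    eta_scale: float = 0.05
    delta_scale: float = 0.05
    gamma_scale: float = 0.10
    sigma2_scale: float = 0.30      # log-scale step for the optional MH mode
    psi_cM: float = 5.0             # D* window half-width
    target_band: tuple = (0.25, 0.40)
    adapt_every: int = 25


@dataclass
class MCMCState:
    """Complete unknown set plus latents."""

    beta: np.ndarray        # 2 x (r+1)
    theta: np.ndarray       # n x (m+1)
    sigma2: float
    cov_a: np.ndarray       # eta (glm) or [log sig2] (ar1/cs)
    cov_b: np.ndarray       # delta (glm) or [transformed rho]
    gamma: float
    lam0: np.ndarray        # K step heights
    Dstar: float
    Q: np.ndarray           # n genotype labels in {1, 2}

    def copy(self):
        return MCMCState(self.beta.copy(), self.theta.copy(), float(self.sigma2),
                         self.cov_a.copy(), self.cov_b.copy(), float(self.gamma),
                         self.lam0.copy(), float(self.Dstar), self.Q.copy())

    @property
    def eta(self):
        return self.cov_a

    @property
    def delta(self):
        return self.cov_b


@dataclass
class Chain:
    """Thinned posterior samples plus run metadata."""

    samples: dict
    acceptance: dict
    seed: int
    burn_in: int
    thin: int
    iterations: int
    q1_freq: np.ndarray | None = None     # per-subject mean of 1{Q_i = 1}
    final_state: MCMCState | None = None
    spec: ModelSpec | None = None

    def __len__(self):
        return 0 if not self.samples else len(self.samples["Dstar"])

    def posterior_mean(self, name):
        return np.mean(self.samples[name], axis=0)

    def credible_interval(self, name, level=0.95):
        lo = 100 * (1 - level) / 2
        arr = np.asarray(self.samples[name])
        return np.percentile(arr, [lo, 100 - lo], axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {}
        for name, arr in self.samples.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                cols[name] = arr
            else:
                flat = arr.reshape(arr.shape[0], -1)
                for p in range(flat.shape[1]):
                    cols[f"{name}_{p}"] = flat[:, p]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# covariance-structure plumbing


def _cov_chol(spec: ModelSpec, time_grid, a, b):
    """Lower Cholesky factor of Sigma for the active structure, or None if
    the proposed parameters are outside the SPD region (ar1/cs only)."""
    t = np.asarray(time_grid, float)
    if spec.cov_structure == "glm":
        lag = t[:, None] - t[None, :]
        phi = np.polynomial.polynomial.polyval(lag, np.asarray(b, float))
        M = np.eye(t.size) - np.tril(phi, -1)
        log_d = polyval_grid(np.asarray(a, float), t)
        if np.max(np.abs(log_d)) > 600:  # exp would over/underflow
            return None
        from scipy.linalg import solve_triangular
        L = solve_triangular(M, np.diag(np.exp(0.5 * log_d)), lower=True)
        return L if np.all(np.isfinite(L)) else None
    sig2 = float(np.exp(a[0]))
    rho = float(np.tanh(b[0]))
    if spec.cov_structure == "ar1":
        lagm = np.abs(t[:, None] - t[None, :])
        S = sig2 * rho ** lagm
    elif spec.cov_structure == "cs":
        S = sig2 * ((1 - rho) * np.eye(t.size) + rho * np.ones((t.size, t.size)))
    else:
        raise ValueError(f"unknown covariance structure {spec.cov_structure!r}")
    try:
        return np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return None


def _cov_dims(spec: ModelSpec):
    if spec.cov_structure == "glm":
        return spec.order_g + 1, spec.order_h + 1
    return 1, 1


# ---------------------------------------------------------------------------
# workspace: everything that depends only on (data, spec)


class _Workspace:
    def __init__(self, data: JointData, spec: ModelSpec):
        self.data = data
        self.spec = spec
        t = data.time_grid
        self.Xr = design_matrix(t, spec.order_r)
        self.Xm = design_matrix(t, spec.order_m)
        self.knots = spec.baseline_knots(data.s)
        if np.max(data.s) > self.knots[-1] + 1e-12:
            raise ValueError("event times beyond the baseline support")
        K = self.knots.size - 1
        self.K = K
        P = spec.quad_points

        nodes, node_int = [], []
        for k in range(K):
            nodes.append(np.linspace(self.knots[k], self.knots[k + 1], P + 1))
            node_int.append(np.full(P + 1, k, dtype=int))
        self.nodes = np.concatenate(nodes)
        self.node_int = np.concatenate(node_int)
        nq = self.nodes.size

        self.Br = design_matrix(self.nodes, spec.order_r)
        self.Bm = design_matrix(self.nodes, spec.order_m)
        self.Sr = design_matrix(data.s, spec.order_r)
        self.Sm = design_matrix(data.s, spec.order_m)

        s = data.s
        idx = np.searchsorted(self.knots, s, side="left") - 1
        self.s_int = np.clip(idx, 0, K - 1)

        # Per-subject trapezoid weights for Lambda(s_i): full sub-segments get
        # standard weights; the partial segment [floor node, s_i] contributes
        # (s_i - floor)/2 to the floor node and the same weight (wpart) to the
        # integrand evaluated at s_i itself.
        n = data.n
        W = np.zeros((n, nq))
        wpart = np.zeros(n)
        for i in range(n):
            k = self.s_int[i]
            for kk in range(k):
                a0, b0 = self.knots[kk], self.knots[kk + 1]
                h = (b0 - a0) / P
                blk = slice(kk * (P + 1), (kk + 1) * (P + 1))
                w = np.full(P + 1, h)
                w[0] = w[-1] = 0.5 * h
                W[i, blk] += w
            a0, b0 = self.knots[k], self.knots[k + 1]
            h = (b0 - a0) / P
            base = k * (P + 1)
            j = int(np.floor((s[i] - a0) / h + 1e-12))
            j = min(j, P)
            if j >= 1:
                w = np.full(j + 1, h)
                w[0] = w[-1] = 0.5 * h
                W[i, base:base + j + 1] += w
            part = 0.5 * (s[i] - self.nodes[base + j])
            W[i, base + j] += part
            wpart[i] = part
        self.W = W
        self.wpart = wpart
        self.nq = nq

    def omega(self, Dstar: float) -> np.ndarray:
        return qtl_conditional_probs(self.data.lmap, self.data.markers, Dstar)


# ---------------------------------------------------------------------------
# the sampler


class Sampler:
    """Holds the current state and cached likelihood terms; exposes one
    update method per parameter block plus ``step`` for a full scan."""

    def __init__(self, data: JointData, spec: ModelSpec | None = None,
                 priors: Priors | None = None,
                 settings: ProposalSettings | None = None,
                 seed: int = 0, temp: float = 1.0, null: bool = False,
                 init_state: MCMCState | None = None):
        self.data = data
        self.spec = spec or ModelSpec()
        self.priors = priors or Priors()
        self.settings = settings or ProposalSettings()
        self.rng = np.random.default_rng(seed)
        self.temp = float(temp)
        self.null = bool(null)
        self.ws = _Workspace(data, self.spec)
        self.state = init_state.copy() if init_state is not None else self._init_state()
        self._scales = {
            "beta": self.settings.beta_scale,
            "theta": self.settings.theta_scale,
            "recenter": self.settings.theta_scale,
            "eta": self.settings.eta_scale,
            "delta": self.settings.delta_scale,
            "gamma": self.settings.gamma_scale,
            "sigma2": self.settings.sigma2_scale,
        }
        self.accept = {k: [0.0, 0] for k in
                       ("beta", "theta", "recenter", "eta", "delta", "gamma",
                        "sigma2", "Dstar")}
        self._batch = {k: [0.0, 0] for k in self.accept}
        self._n_adapt = 0
        self._iter = 0
        self._refresh_all()
        if not np.isfinite(self.log_posterior()):
            raise RuntimeError("non-finite log posterior at initialization")

    # -- initialization ----------------------------------------------------

    def _init_state(self) -> MCMCState:
        data, spec = self.data, self.spec
        n = data.n
        Xr = design_matrix(data.time_grid, spec.order_r)
        ybar = data.y.mean(axis=0)
        beta0, *_ = np.linalg.lstsq(Xr, ybar, rcond=None)
        Dm = data.lmap.length_cM
        # midpoint of the marker interval containing the group midpoint: an
        # interior start whose omega is never an exact indicator
        from .genmap import locate_interval
        k, k1 = locate_interval(data.lmap, 0.5 * Dm)
        p = data.lmap.positions_cM - data.lmap.positions_cM[0]
        Dstar = 0.5 * (p[k] + p[k1])
        omega = self.ws.omega(Dstar)
        Q = 1 + (self.rng.uniform(size=n) > omega[:, 0]).astype(np.int64)
        # genotype-wise least squares puts beta near each group's mean curve;
        # starting both rows at the pooled fit makes the walk to separated
        # means needlessly long when the likelihood is tight
        beta = np.vstack([beta0, beta0])
        if not self.null:
            for _ in range(3):  # k-means-style refinement of the split
                for j in (1, 2):
                    mask = Q == j
                    if mask.sum() >= 3:
                        bj, *_ = np.linalg.lstsq(Xr, data.y[mask].mean(axis=0),
                                                 rcond=None)
                        beta[j - 1] = bj
                fit = beta @ Xr.T               # 2 x T candidate mean curves
                sse = ((data.y[:, None, :] - fit[None]) ** 2).sum(axis=2)
                Q = 1 + np.argmin(sse, axis=1).astype(np.int64)
        pa, pb = _cov_dims(spec)
        logvar = np.log(np.maximum(data.y.var(axis=0, ddof=1), 1e-8))
        if spec.cov_structure == "glm":
            Xg = design_matrix(data.time_grid, spec.order_g)
            cov_a, *_ = np.linalg.lstsq(Xg, logvar, rcond=None)
            cov_b = np.zeros(pb)
        else:
            cov_a = np.array([float(np.mean(logvar))])
            cov_b = np.array([np.arctanh(0.3)])
        lo, hi = self.priors.gamma_bounds
        gamma = 0.5 * (lo + hi)
        a1, a2 = self.priors.sigma2_ig
        sigma2 = a2 / max(a1 - 1.0, 0.5)
        state = MCMCState(
            beta=beta, theta=np.zeros((n, spec.order_m + 1)), sigma2=float(sigma2),
            cov_a=np.asarray(cov_a, float), cov_b=np.asarray(cov_b, float),
            gamma=float(gamma), lam0=np.ones(self.ws.K), Dstar=float(Dstar), Q=Q,
        )
        # crude empirical baseline: matches counts to exposures at the start
        self.state = state
        self._refresh_all()
        a, b = self.priors.lambda0_gamma
        d_k, E_k = self._counts_exposures()
        state.lam0 = (a + d_k) / (b + E_k)
        return state

    # -- cached quantities -------------------------------------------------

    def _refresh_all(self):
        st, ws = self.state, self.ws
        self.L = _cov_chol(self.spec, self.data.time_grid, st.cov_a, st.cov_b)
        if self.L is None:
            raise RuntimeError("initial covariance parameters are not SPD")
        self.omega = ws.omega(st.Dstar)
        self.TB = st.theta @ ws.Bm.T          # theta part at quad nodes
        self.TX = st.theta @ ws.Xm.T          # theta part on the time grid
        self.Ts = np.sum(ws.Sm * st.theta, axis=1)  # theta part at s_i
        bsel = st.beta[st.Q - 1]
        self.Mq = bsel @ ws.Br.T + self.TB
        self.Ms = np.sum(ws.Sr * bsel, axis=1) + self.Ts
        self.resid = self.data.y - bsel @ ws.Xr.T - self.TX
        self.lo = mvn_loglik_chol(self.resid, self.L)
        self.ev, self.G, self.A, self.gs = self._event_terms(self.Mq, self.Ms,
                                                             st.gamma, st.lam0)

    def _event_terms(self, Mq, Ms, gamma, lam0, rows=None):
        ws = self.ws
        W = ws.W if rows is None else ws.W[rows]
        wpart = ws.wpart if rows is None else ws.wpart[rows]
        s_int = ws.s_int if rows is None else ws.s_int[rows]
        # clamp the link exponent: tempered chains can wander to mean levels
        # where exp overflows; the clamped value still yields a huge
        # cumulative hazard, so such states are rejected, not visited
        G = np.exp(np.minimum(gamma * Mq, 700.0))
        gs = np.exp(np.minimum(gamma * Ms, 700.0))
        A = W * G
        lam_node = lam0[ws.node_int]
        lam_s = lam0[s_int]
        Lam = A @ lam_node + lam_s * wpart * gs
        ev = np.log(lam_s) + gamma * Ms - Lam
        return ev, G, A, gs

    def _counts_exposures(self):
        ws = self.ws
        d_k = np.bincount(ws.s_int, minlength=ws.K).astype(float)
        E_k = np.bincount(ws.node_int, weights=self.A.sum(axis=0), minlength=ws.K)
        E_k = E_k + np.bincount(ws.s_int, weights=ws.wpart * self.gs,
                                minlength=ws.K)
        return d_k, E_k

    def _theta_logprior_rows(self, theta):
        return -0.5 * np.sum(theta * theta, axis=1) / self.state.sigma2

    # -- log posterior -----------------------------------------------------

    def complete_data_loglik(self) -> float:
        """Sum over subjects of log pi(y_i, s_i | Q_i, theta_i, Theta)."""
        return float(np.sum(self.lo + self.ev))

    def log_posterior(self, mixture: bool = False) -> float:
        """Unnormalized log posterior.  With ``mixture=True`` the latent Q is
        summed out (log-sum-exp over the two genotypes per subject); the
        default conditions on the current Q draw and includes its omega
        prior term."""
        st, pr = self.state, self.priors
        lp = pr.log_sigma2(st.sigma2) + pr.log_gamma_link(st.gamma)
        lp += pr.log_lambda0(st.lam0) + pr.log_cov_a(st.cov_a) + pr.log_cov_b(st.cov_b)
        if self.null:
            lp += pr.log_beta(st.beta[0])
        else:
            lp += pr.log_beta(st.beta[0]) + pr.log_beta(st.beta[1])
        Dm = self.data.lmap.length_cM
        if not (0.0 <= st.Dstar <= Dm):
            return -np.inf
        lp += -np.log(Dm)
        lp += float(np.sum(self._theta_logprior_rows(st.theta))
                    - 0.5 * st.theta.size * (LOG2PI + np.log(st.sigma2)))
        if mixture:
            from scipy.special import logsumexp
            l1, l2 = self._both_genotype_logliks()
            both = self.temp * np.stack([l1, l2], axis=1)
            lp += float(np.sum(logsumexp(both, b=self.omega, axis=1)))
        else:
            lp += self.temp * self.complete_data_loglik()
            with np.errstate(divide="ignore"):
                lp += float(np.sum(np.log(
                    self.omega[np.arange(self.data.n), st.Q - 1])))
        return float(lp)

    def _both_genotype_logliks(self):
        ws, st = self.ws, self.state
        out = []
        for j in (0, 1):
            Mq = self.TB + (ws.Br @ st.beta[j])[None, :]
            Ms = self.Ts + ws.Sr @ st.beta[j]
            resid = self.data.y - self.TX - (ws.Xr @ st.beta[j])[None, :]
            lo = mvn_loglik_chol(resid, self.L)
            ev, *_ = self._event_terms(Mq, Ms, st.gamma, st.lam0)
            out.append(lo + ev)
        return out

    # -- update blocks -----------------------------------------------------

    def _mh_accept(self, block, log_ratio) -> bool:
        acc = np.log(self.rng.uniform()) < log_ratio
        a = self.accept[block]
        a[0] += float(acc)
        a[1] += 1
        b = self._batch[block]
        b[0] += float(acc)
        b[1] += 1
        return bool(acc)

    def update_beta(self):
        st, ws = self.state, self.ws
        groups = ((0,),) if self.null else ((0,), (1,))
        for grp in groups:
            j = grp[0]
            cur = st.beta[j]
            prop = cur + self._scales["beta"] * self.rng.standard_normal(cur.size)
            if self.null:
                rows = np.arange(self.data.n)
            else:
                rows = np.flatnonzero(st.Q == j + 1)
            d = prop - cur
            dprior = self.priors.log_beta(prop) - self.priors.log_beta(cur)
            if rows.size == 0:
                if self._mh_accept("beta", dprior):
                    st.beta[j] = prop
                    if self.null:
                        st.beta[1] = prop
                continue
            Mq_new = self.Mq[rows] + (ws.Br @ d)[None, :]
            Ms_new = self.Ms[rows] + ws.Sr[rows] @ d
            resid_new = self.resid[rows] - (ws.Xr @ d)[None, :]
            lo_new = mvn_loglik_chol(resid_new, self.L)
            ev_new, G_new, A_new, gs_new = self._event_terms(
                Mq_new, Ms_new, st.gamma, st.lam0, rows=rows)
            dll = np.sum(lo_new + ev_new) - np.sum(self.lo[rows] + self.ev[rows])
            if self._mh_accept("beta", self.temp * dll + dprior):
                st.beta[j] = prop
                if self.null:
                    st.beta[1] = prop
                self.Mq[rows] = Mq_new
                self.Ms[rows] = Ms_new
                self.resid[rows] = resid_new
                self.lo[rows] = lo_new
                self.ev[rows] = ev_new
                self.G[rows] = G_new
                self.A[rows] = A_new
                self.gs[rows] = gs_new

    def update_recenter(self):
        """Translation move: shift beta_j and compensate the theta_i of the
        subjects carrying genotype j so every subject mean is unchanged.

        Because the mean and random-effect bases share their leading
        columns, beta and theta are strongly coupled; this move travels
        along the likelihood-invariant direction and is accepted on the
        prior ratio alone, which is what identifies beta (theta is
        centered at zero a priori)."""
        st, ws = self.state, self.ws
        ps = min(st.beta.shape[1], st.theta.shape[1])
        groups = ((0, np.arange(self.data.n)),) if self.null else \
            ((0, np.flatnonzero(st.Q == 1)), (1, np.flatnonzero(st.Q == 2)))
        for j, rows in groups:
            delta = self._scales["recenter"] * self.rng.standard_normal(ps)
            beta_new = st.beta[j].copy()
            beta_new[:ps] += delta
            th = st.theta[rows]
            th_new = th.copy()
            th_new[:, :ps] -= delta
            dprior = self.priors.log_beta(beta_new) - self.priors.log_beta(st.beta[j])
            dprior += float(np.sum(self._theta_logprior_rows(th_new)
                                   - self._theta_logprior_rows(th)))
            if self._mh_accept("recenter", dprior):
                st.beta[j] = beta_new
                if self.null:
                    st.beta[1] = beta_new
                st.theta[rows] = th_new
                self.TB[rows] -= (ws.Bm[:, :ps] @ delta)[None, :]
                self.TX[rows] -= (ws.Xm[:, :ps] @ delta)[None, :]
                self.Ts[rows] -= ws.Sm[rows, :ps] @ delta

    def update_sigma2_theta(self):
        self.update_theta()
        self.update_sigma2()

    def update_theta(self):
        st, ws = self.state, self.ws
        n, p = st.theta.shape
        dT = self._scales["theta"] * self.rng.standard_normal((n, p))
        theta_new = st.theta + dT
        Mq_new = self.Mq + dT @ ws.Bm.T
        Ms_new = self.Ms + np.sum(ws.Sm * dT, axis=1)
        resid_new = self.resid - dT @ ws.Xm.T
        lo_new = mvn_loglik_chol(resid_new, self.L)
        ev_new, G_new, A_new, gs_new = self._event_terms(Mq_new, Ms_new,
                                                         st.gamma, st.lam0)
        logr = self.temp * (lo_new + ev_new - self.lo - self.ev)
        logr += self._theta_logprior_rows(theta_new) - self._theta_logprior_rows(st.theta)
        acc = np.log(self.rng.uniform(size=n)) < logr
        rate = float(np.mean(acc))
        self.accept["theta"][0] += rate
        self.accept["theta"][1] += 1
        self._batch["theta"][0] += rate
        self._batch["theta"][1] += 1
        if np.any(acc):
            st.theta[acc] = theta_new[acc]
            self.TB[acc] += dT[acc] @ ws.Bm.T
            self.TX[acc] += dT[acc] @ ws.Xm.T
            self.Ts[acc] = np.sum(ws.Sm[acc] * st.theta[acc], axis=1)
            self.Mq[acc] = Mq_new[acc]
            self.Ms[acc] = Ms_new[acc]
            self.resid[acc] = resid_new[acc]
            self.lo[acc] = lo_new[acc]
            self.ev[acc] = ev_new[acc]
            self.G[acc] = G_new[acc]
            self.A[acc] = A_new[acc]
            self.gs[acc] = gs_new[acc]

    def update_sigma2(self):
        st = self.state
        a1, a2 = self.priors.sigma2_ig
        if self.spec.sigma2_update == "gibbs":
            shape = a1 + 0.5 * st.theta.size
            rate = a2 + 0.5 * float(np.sum(st.theta ** 2))
            st.sigma2 = rate / self.rng.gamma(shape)
            self.accept["sigma2"][0] += 1
            self.accept["sigma2"][1] += 1
        else:  # MH on log sigma^2 (includes the log-normal Jacobian)
            cur = st.sigma2
            prop = float(np.exp(np.log(cur)
                                + self._scales["sigma2"] * self.rng.standard_normal()))
            m1 = st.theta.shape[1]
            n = st.theta.shape[0]
            ssq = float(np.sum(st.theta ** 2))

            def cond(v):
                return (self.priors.log_sigma2(v)
                        - 0.5 * n * m1 * np.log(v) - 0.5 * ssq / v)

            logr = cond(prop) - cond(cur) + np.log(prop) - np.log(cur)
            if self._mh_accept("sigma2", logr):
                st.sigma2 = prop

    def _update_cov_block(self, which: str):
        st = self.state
        cur = st.cov_a if which == "eta" else st.cov_b
        prop = cur + self._scales[which] * self.rng.standard_normal(cur.size)
        a = prop if which == "eta" else st.cov_a
        b = st.cov_b if which == "eta" else prop
        L_new = _cov_chol(self.spec, self.data.time_grid, a, b)
        prior_fn = self.priors.log_cov_a if which == "eta" else self.priors.log_cov_b
        if L_new is None:
            self._mh_accept(which, -np.inf)
            return
        lo_new = mvn_loglik_chol(self.resid, L_new)
        logr = (self.temp * float(np.sum(lo_new - self.lo))
                + prior_fn(prop) - prior_fn(cur))
        if self._mh_accept(which, logr):
            if which == "eta":
                st.cov_a = prop
            else:
                st.cov_b = prop
            self.L = L_new
            self.lo = lo_new

    def update_eta(self):
        self._update_cov_block("eta")

    def update_delta(self):
        self._update_cov_block("delta")

    def update_eta_delta(self):
        self.update_eta()
        self.update_delta()

    def update_gamma(self):
        st = self.state
        prop = st.gamma + self._scales["gamma"] * self.rng.standard_normal()
        lo_b, hi_b = self.priors.gamma_bounds
        if not (lo_b <= prop <= hi_b):
            self._mh_accept("gamma", -np.inf)
            return
        ev_new, G_new, A_new, gs_new = self._event_terms(self.Mq, self.Ms,
                                                         prop, st.lam0)
        logr = self.temp * float(np.sum(ev_new - self.ev))
        if self._mh_accept("gamma", logr):
            st.gamma = prop
            self.ev, self.G, self.A, self.gs = ev_new, G_new, A_new, gs_new

    def update_lambda0(self):
        st = self.state
        a, b = self.priors.lambda0_gamma
        d_k, E_k = self._counts_exposures()
        shape = a + self.temp * d_k
        rate = b + self.temp * E_k
        st.lam0 = np.maximum(self.rng.gamma(shape) / rate, _LAM_FLOOR)
        # refresh the event term under the new baseline (G unchanged)
        lam_node = st.lam0[self.ws.node_int]
        lam_s = st.lam0[self.ws.s_int]
        Lam = self.A @ lam_node + lam_s * self.ws.wpart * self.gs
        self.ev = np.log(lam_s) + st.gamma * self.Ms - Lam

    def update_Dstar(self):
        st = self.state
        Dm = self.data.lmap.length_cM
        psi = self.settings.psi_cM

        def window(x):
            return max(0.0, x - psi), min(x + psi, Dm)

        lo_w, hi_w = window(st.Dstar)
        prop = self.rng.uniform(lo_w, hi_w)
        lo_p, hi_p = window(prop)
        omega_new = self.ws.omega(prop)
        rows = np.arange(self.data.n)
        with np.errstate(divide="ignore"):
            cur_term = float(np.sum(np.log(self.omega[rows, st.Q - 1])))
            new_term = float(np.sum(np.log(omega_new[rows, st.Q - 1])))
        logr = new_term - cur_term + np.log(hi_w - lo_w) - np.log(hi_p - lo_p)
        if self._mh_accept("Dstar", logr):
            st.Dstar = float(prop)
            self.omega = omega_new

    def update_Q(self):
        st, ws = self.state, self.ws
        l1, l2 = self._both_genotype_logliks()
        with np.errstate(divide="ignore"):
            lp = np.log(self.omega) + self.temp * np.stack([l1, l2], axis=1)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        p1 = p[:, 0] / p.sum(axis=1)
        Q_new = 1 + (self.rng.uniform(size=self.data.n) >= p1).astype(np.int64)
        changed = Q_new != st.Q
        st.Q = Q_new
        if np.any(changed):
            rows = np.flatnonzero(changed)
            bsel = st.beta[st.Q[rows] - 1]
            self.Mq[rows] = self.TB[rows] + bsel @ ws.Br.T
            self.Ms[rows] = self.Ts[rows] + np.sum(ws.Sr[rows] * bsel, axis=1)
            self.resid[rows] = self.data.y[rows] - self.TX[rows] - bsel @ ws.Xr.T
            self.lo[rows] = mvn_loglik_chol(self.resid[rows], self.L)
            ev_new, G_new, A_new, gs_new = self._event_terms(
                self.Mq[rows], self.Ms[rows], st.gamma, st.lam0, rows=rows)
            self.ev[rows] = ev_new
            self.G[rows] = G_new
            self.A[rows] = A_new
            self.gs[rows] = gs_new

    # -- adaptation and the main loop --------------------------------------

    def _adapt(self):
        self._n_adapt += 1
        lo_t, hi_t = self.settings.target_band
        target = 0.5 * (lo_t + hi_t)
        step = 1.0 / np.sqrt(self._n_adapt)
        for k in ("beta", "theta", "recenter", "eta", "delta", "gamma", "sigma2"):
            acc, n = self._batch[k]
            if n == 0:
                continue
            rate = acc / n
            self._scales[k] = float(np.clip(
                self._scales[k] * np.exp(step * (rate - target)), 1e-6, 1e3))
            self._batch[k] = [0.0, 0]

    def step(self, adapt: bool = False):
        self.update_beta()
        self.update_recenter()
        self.update_sigma2_theta()
        self.update_eta()
        self.update_delta()
        self.update_gamma()
        self.update_lambda0()
        self.update_Dstar()
        self.update_Q()
        self._iter += 1
        if adapt and (self._iter % self.settings.adapt_every) == 0:
            self._adapt()

    def acceptance_rates(self) -> dict:
        return {k: (a / n if n else np.nan) for k, (a, n) in self.accept.items()}


def run_chain(data: JointData, spec: ModelSpec | None = None,
              priors: Priors | None = None,
              settings: ProposalSettings | None = None,
              iterations: int = 120_000, burn_in: int = 20_000, thin: int = 1,
              seed: int = 0, temp: float = 1.0, null: bool = False,
              init_state: MCMCState | None = None,
              adapt: bool = True, store_theta: bool = False) -> Chain:
    """Run the systematic-scan sampler; deterministic given the seed.

    ``iterations`` counts total sweeps including ``burn_in``; one state is
    recorded every ``thin`` sweeps after burn-in.
    """
    if burn_in > iterations:
        raise ValueError("burn_in cannot exceed iterations")
    smp = Sampler(data, spec, priors, settings, seed=seed, temp=temp,
                  null=null, init_state=init_state)
    keep = (iterations - burn_in) // thin
    rec = {
        "beta": np.empty((keep, 2, smp.state.beta.shape[1])),
        "sigma2": np.empty(keep),
        "cov_a": np.empty((keep, smp.state.cov_a.size)),
        "cov_b": np.empty((keep, smp.state.cov_b.size)),
        "gamma": np.empty(keep),
        "lam0": np.empty((keep, smp.ws.K)),
        "Dstar": np.empty(keep),
        "loglik": np.empty(keep),
    }
    if store_theta:
        rec["theta"] = np.empty((keep, *smp.state.theta.shape))
    q1 = np.zeros(data.n)
    kept = 0
    for it in range(iterations):
        smp.step(adapt=adapt and it < burn_in)
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < keep:
            st = smp.state
            rec["beta"][kept] = st.beta
            rec["sigma2"][kept] = st.sigma2
            rec["cov_a"][kept] = st.cov_a
            rec["cov_b"][kept] = st.cov_b
            rec["gamma"][kept] = st.gamma
            rec["lam0"][kept] = st.lam0
            rec["Dstar"][kept] = st.Dstar
            rec["loglik"][kept] = smp.complete_data_loglik()
            if store_theta:
                rec["theta"][kept] = st.theta
            q1 += (st.Q == 1)
            kept += 1
    samples = {k: v[:kept] for k, v in rec.items()}
    return Chain(samples=samples, acceptance=smp.acceptance_rates(), seed=seed,
                 burn_in=burn_in, thin=thin, iterations=iterations,
                 q1_freq=(q1 / kept if kept else None),
                 final_state=smp.state.copy(), spec=smp.spec)


def draw_state_from_prior(data: JointData, spec: ModelSpec, priors: Priors,
                          rng: np.random.Generator) -> MCMCState:
    """Draw a complete state (parameters and latents) from the prior; used
    by prior-predictive simulation and sampler-validation tests."""
    pa, pb = _cov_dims(spec)
    p_r, p_m = spec.order_r + 1, spec.order_m + 1
    beta = np.sqrt(priors.beta_var) * rng.standard_normal((2, p_r))
    a1, a2 = priors.sigma2_ig
    sigma2 = a2 / rng.gamma(a1)
    theta = np.sqrt(sigma2) * rng.standard_normal((data.n, p_m))
    cov_a = np.sqrt(priors.eta_var) * rng.standard_normal(pa)
    cov_b = np.sqrt(priors.delta_var) * rng.standard_normal(pb)
    glo, ghi = priors.gamma_bounds
    gamma = rng.uniform(glo, ghi)
    la, lb = priors.lambda0_gamma
    K = spec.baseline_knots(data.s).size - 1
    lam0 = np.maximum(rng.gamma(la, size=K) / lb, _LAM_FLOOR)
    Dstar = rng.uniform(0.0, data.lmap.length_cM)
    omega = qtl_conditional_probs(data.lmap, data.markers, Dstar)
    Q = 1 + (rng.uniform(size=data.n) > omega[:, 0]).astype(np.int64)
    return MCMCState(beta=beta, theta=theta, sigma2=float(sigma2), cov_a=cov_a,
                     cov_b=cov_b, gamma=float(gamma), lam0=lam0,
                     Dstar=float(Dstar), Q=Q)
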