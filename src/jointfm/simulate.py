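"""Synthetic RIL mapping populations for the simulation study.

The default design emulates the validation study of the soybean
application: 200 RIL progeny, 11 evenly spaced markers spanning 100 cM,
one QTL at 43 cM, T = 8 longitudinal measurements on the grid t = 1..8,
and genotype mean-curve truths taken from the detected group-20 QTL
(beta_1 = (-1.1524, 2.6829, 0.2295), beta_2 = (-3.1004, 5.3250, -0.0250)).

Marker and QTL genotypes are generated by a sequential (Markov) walk along
the chromosome: the leftmost locus is a fair coin, and each subsequent
locus recombines against its left neighbour with the design's two-point
recombination fraction (Haldane, with the selfed-RIL accumulation
transform R = 2r/(1+2r) for RIL populations).

Event times are generated from the proportional-hazards submodel itself by
inverting the survival curve.  The covariance/link/baseline truths are
conventions of this generator (the original study reused event times from
unavailable field data): gamma = -0.5 and a constant baseline of 2.0 per
step give event times spread over the observation window at this design's
trait scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import LinkageMap, MarkerGenotypes, haldane, ril_transform
from .longitudinal import CholeskyCovModel, build_chol, design_matrix
from .mcmc import JointData

__all__ = [
    "GROUP20_BETA1",
    "GROUP20_BETA2",
    "SimulationDesign",
    "SimulatedDataset",
    "sample_event_times",
    "simulate_population",
    "simulate_null_population",
]

# Group-20 truths used by the validation study (alternative model).
GROUP20_BETA1 = (-1.1524, 2.6829, 0.2295)
GROUP20_BETA2 = (-3.1004, 5.3250, -0.0250)


@dataclass
class SimulationDesign:
    """Generating configuration; defaults reproduce the validation design."""

    n_progeny: int = 200
    n_markers: int = 11
    group_length_cM: float = 100.0
    qtl_cM: float = 43.0
    design: str = "RIL"
    T: int = 8
    beta1: tuple = GROUP20_BETA1
    beta2: tuple = GROUP20_BETA2
    eta: tuple = (-4.0, 0.1, 0.0)
    delta: tuple = (0.2, -0.05, 0.0)
    sigma2: float = 0.001
    gamma: float = -0.5
    lambda0: float = 2.0
    K: int = 5
    cov_structure: str = "glm"          # generating structure: glm | ar1 | cs
    ar_sig2: float = 2.0                # used when cov_structure != glm
    ar_rho: float = 0.6
    quad_points: int = 64
    order_m: int = 2
    knots: np.ndarray | None = None     # override the baseline partition
    on_overflow: str = "resample"       # event time beyond support: resample|truncate

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(1.0, self.T + 1.0)

    @property
    def event_knots(self) -> np.ndarray:
        if self.knots is not None:
            return np.asarray(self.knots, float)
        return np.linspace(0.0, float(self.T), self.K + 1)

    def marker_positions(self) -> np.ndarray:
        return np.linspace(0.0, self.group_length_cM, self.n_markers)

    def linkage_map(self) -> LinkageMap:
        pos = self.marker_positions()
        return LinkageMap(group_id="sim",
                          marker_names=tuple(f"M{i+1}" for i in range(pos.size)),
                          positions_cM=pos)

    def residual_sigma(self) -> np.ndarray:
        t = self.time_grid
        if self.cov_structure == "glm":
            cov = CholeskyCovModel(order_g=len(self.eta) - 1,
                                   order_h=len(self.delta) - 1,
                                   eta=np.asarray(self.eta),
                                   delta=np.asarray(self.delta), time_grid=t)
            L = build_chol(cov)
            return L @ L.T
        lag = np.abs(t[:, None] - t[None, :])
        if self.cov_structure == "ar1":
            return self.ar_sig2 * self.ar_rho ** lag
        if self.cov_structure == "cs":
            return self.ar_sig2 * ((1 - self.ar_rho) * np.eye(t.size)
                                   + self.ar_rho * np.ones((t.size, t.size)))
        raise ValueError(f"unknown covariance structure {self.cov_structure!r}")


@dataclass
class SimulatedDataset:
    """A complete simulated population with its generating truth record."""

    lmap: LinkageMap
    markers: MarkerGenotypes
    Q_true: np.ndarray
    theta: np.ndarray
    y: np.ndarray
    s: np.ndarray
    time_grid: np.ndarray
    design: SimulationDesign
    seed: int | None = None

    def to_joint_data(self) -> JointData:
        return JointData(y=self.y, time_grid=self.time_grid, s=self.s,
                         lmap=self.lmap, markers=self.markers)

    def truth_record(self) -> dict:
        d = self.design
        return {
            "beta1": list(d.beta1), "beta2": list(d.beta2),
            "eta": list(d.eta), "delta": list(d.delta),
            "sigma2": d.sigma2, "gamma": d.gamma, "lambda0": d.lambda0,
            "K": d.K, "qtl_cM": d.qtl_cM, "design": d.design,
            "cov_structure": d.cov_structure, "seed": self.seed,
        }

    def write(self, outdir) -> None:
        """Write the delimited files the fitting commands read, plus a truth
        sidecar for recovery scoring."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pos = self.lmap.positions_cM
        pd.DataFrame({
            "marker": self.lmap.marker_names,
            "group": self.lmap.group_id,
            "position_cM": pos,
        }).to_csv(outdir / "map.csv", index=False)
        ids = [f"P{i+1}" for i in range(self.y.shape[0])]
        geno = pd.DataFrame(self.markers.codes, index=ids,
                            columns=self.lmap.marker_names)
        geno.replace(0, np.nan).to_csv(outdir / "genotypes.csv")
        pd.DataFrame(self.y, index=ids,
                     columns=[str(t) for t in self.time_grid]
                     ).to_csv(outdir / "phenotypes.csv")
        pd.DataFrame({"progeny_id": ids, "event_time": self.s}
                     ).to_csv(outdir / "events.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth_record(), fh, indent=1)


def _simulate_genotypes(design: SimulationDesign, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sequential recombination walk over markers + QTL; returns the marker
    matrix (n x m) and the true QTL genotype labels (n,)."""
    mpos = design.marker_positions()
    loci = np.sort(np.append(mpos, design.qtl_cM))
    qtl_idx = int(np.searchsorted(loci, design.qtl_cM))
    # when the QTL coincides with a marker, searchsorted finds the left copy
    n, L = design.n_progeny, loci.size
    r = haldane(np.diff(loci) / 100.0)
    if design.design == "RIL":
        r = ril_transform(r)
    g = np.empty((n, L), dtype=np.int64)
    g[:, 0] = 1 + (rng.uniform(size=n) < 0.5)
    for k in range(1, L):
        flip = rng.uniform(size=n) < r[k - 1]
        g[:, k] = np.where(flip, 3 - g[:, k - 1], g[:, k - 1])
    Q = g[:, qtl_idx]
    marker_cols = [k for k in range(L) if not (k == qtl_idx and design.qtl_cM not in mpos)]
    markers = g[:, marker_cols]
    return markers, Q


def sample_event_times(gamma, lambda0, knots, mu_coefs, rng,
                       quad_points: int = 64,
                       on_overflow: str = "resample") -> np.ndarray:
    """Vectorized inversion sampling of PH event times for many subjects.

    ``mu_coefs`` is an n x p matrix of per-subject polynomial mean
    coefficients (increasing powers); ``lambda0`` a scalar or a length-K
    step vector over ``knots``.  An event falling beyond the support is
    redrawn by default (i.e. the draw is conditioned on landing inside the
    observation window), or truncated at the last knot.
    """
    knots = np.asarray(knots, float)
    K = knots.size - 1
    nodes, node_int = [], []
    for k in range(K):
        nodes.append(np.linspace(knots[k], knots[k + 1], quad_points + 1))
        node_int.append(np.full(quad_points + 1, k, dtype=int))
    nodes = np.concatenate(nodes)
    node_int = np.concatenate(node_int)
    mu_coefs = np.atleast_2d(np.asarray(mu_coefs, float))
    B = design_matrix(nodes, mu_coefs.shape[1] - 1)
    mu_curves = mu_coefs @ B.T
    lam_node = (np.full(K, float(lambda0)) if np.isscalar(lambda0)
                else np.asarray(lambda0, float))[node_int]
    f = lam_node[None, :] * np.exp(gamma * mu_curves)
    widths = np.diff(nodes)
    contrib = 0.5 * widths[None, :] * (f[:, :-1] + f[:, 1:])
    cum = np.concatenate([np.zeros((f.shape[0], 1)), np.cumsum(contrib, axis=1)],
                         axis=1)
    target = -np.log(rng.uniform(size=f.shape[0]))
    if on_overflow == "resample":
        for _ in range(200):
            over = target >= cum[:, -1]
            if not np.any(over):
                break
            target[over] = -np.log(rng.uniform(size=int(np.sum(over))))
    s = np.empty(f.shape[0])
    for i in range(f.shape[0]):
        if target[i] >= cum[i, -1]:
            s[i] = nodes[-1]
            continue
        j = int(np.searchsorted(cum[i], target[i]))
        lo_c, hi_c = cum[i, j - 1], cum[i, j]
        frac = (target[i] - lo_c) / max(hi_c - lo_c, 1e-300)
        s[i] = nodes[j - 1] + frac * (nodes[j] - nodes[j - 1])
    return np.maximum(s, 1e-9)


def simulate_population(design: SimulationDesign | None = None,
                        rng=None, seed: int | None = None) -> SimulatedDataset:
    """Generate a full mapping population under the (alternative) design."""
    design = design or SimulationDesign()
    if rng is None:
        rng = np.random.default_rng(seed)
    lmap = design.linkage_map()
    codes, Q = _simulate_genotypes(design, rng)
    markers = MarkerGenotypes(codes=codes, design=design.design)

    t = design.time_grid
    p_r = len(design.beta1) - 1
    Xr = design_matrix(t, p_r)
    m_order = design.order_m
    Xm = design_matrix(t, m_order)
    beta = np.vstack([design.beta1, design.beta2])
    theta = np.sqrt(design.sigma2) * rng.standard_normal((design.n_progeny,
                                                          m_order + 1))
    mean = beta[Q - 1] @ Xr.T + theta @ Xm.T
    L = np.linalg.cholesky(design.residual_sigma())
    y = mean + rng.standard_normal(mean.shape) @ L.T

    p = max(p_r, m_order) + 1
    coefs = np.zeros((design.n_progeny, p))
    coefs[:, :p_r + 1] += beta[Q - 1]
    coefs[:, :m_order + 1] += theta
    s = sample_event_times(design.gamma, design.lambda0, design.event_knots,
                           coefs, rng, quad_points=design.quad_points,
                           on_overflow=design.on_overflow)

    return SimulatedDataset(lmap=lmap, markers=markers, Q_true=Q, theta=theta,
                            y=y, s=s, time_grid=t, design=design, seed=seed)


def simulate_null_population(design: SimulationDesign | None = None,
                             beta_common=GROUP20_BETA1, rng=None,
                             seed: int | None = None) -> SimulatedDataset:
    """Generate a population with no QTL effect: beta_1 = beta_2."""
    design = design or SimulationDesign()
    from dataclasses import replace
    design = replace(design, beta1=tuple(beta_common), beta2=tuple(beta_common))
    return simulate_population(design, rng=rng, seed=seed)
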