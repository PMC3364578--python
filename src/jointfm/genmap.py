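"""Genetic linkage maps and conditional QTL genotype probabilities.

A linkage group is an ordered set of markers with cumulative positions in
centiMorgans.  For a putative QTL at position ``D*`` (cM from the first
marker of the group) the probability of each of the two QTL genotype
classes, given the genotypes of the two markers flanking the QTL, follows
from the recombination fractions between the QTL and its flanks under the
Haldane (no-interference) map function.

Two experimental designs with two genotype classes per locus are supported:

* ``backcross`` — recombination fractions are used as-is;
* ``RIL`` (selfed recombinant inbred lines) — repeated selfing to fixation
  accumulates recombination, so each two-point fraction ``r`` is replaced by
  ``R = 2r / (1 + 2r)`` before entering the conditional-probability table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = 0  # integer code for a missing marker genotype

__all__ = [
    "MISSING",
    "LinkageMap",
    "MarkerGenotypes",
    "QtlPosition",
    "haldane",
    "haldane_inverse",
    "ril_transform",
    "locate_interval",
    "qtl_conditional_probs",
    "read_map",
    "read_genotypes",
]


def haldane(d):
    """Map distance (Morgans) -> recombination fraction, r = (1 - e^{-2d})/2.

    Strictly increasing, r(0) = 0, r -> 1/2 as d -> infinity.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    out = 0.5 * (-np.expm1(-2.0 * d))
    return out if out.ndim else float(out)


def haldane_inverse(r):
    """Recombination fraction in [0, 0.5) -> map distance in Morgans."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = -0.5 * np.log1p(-2.0 * r)
    return out if out.ndim else float(out)


def ril_transform(r):
    """Selfed-RIL accumulated recombination: R = 2r / (1 + 2r)."""
    r = np.asarray(r, dtype=float)
    out = 2.0 * r / (1.0 + 2.0 * r)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LinkageMap:
    """One ordered linkage group: marker names and cumulative cM positions."""

    group_id: str
    marker_names: tuple[str, ...]
    positions_cM: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions_cM, dtype=float)
        object.__setattr__(self, "positions_cM", pos)
        if pos.ndim != 1 or pos.size != len(self.marker_names):
            raise ValueError("positions and marker names must align")
        if pos.size < 2:
            raise ValueError("an analyzable group needs at least 2 markers")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def length_cM(self) -> float:
        """Total group length D_m (position of the last marker)."""
        return float(self.positions_cM[-1] - self.positions_cM[0])


@dataclass(frozen=True)
class MarkerGenotypes:
    """n x m matrix of marker genotype codes {1, 2, 0=missing}."""

    codes: np.ndarray
    design: str = "RIL"

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 2:
            raise ValueError("genotype codes must be a 2-D matrix")
        if not np.isin(codes, (MISSING, 1, 2)).all():
            raise ValueError("genotype codes must be in {1, 2, 0 (missing)}")
        if self.design not in ("RIL", "backcross"):
            raise ValueError("design must be 'RIL' or 'backcross'")

    @property
    def n_progeny(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]


@dataclass(frozen=True)
class QtlPosition:
    """Putative QTL position D* in cM from the first marker of the group."""

    D_star: float

    def __post_init__(self):
        if not np.isfinite(self.D_star) or self.D_star < 0:
            raise ValueError("D* must be finite and nonnegative")


def locate_interval(lmap: LinkageMap, pos: QtlPosition | float) -> tuple[int, int]:
    """Flanking marker indices (k, k+1), 0-based, for a QTL at D*.

    A QTL exactly on an interior marker belongs to the interval to its left.
    """
    d = pos.D_star if isinstance(pos, QtlPosition) else float(pos)
    p = lmap.positions_cM - lmap.positions_cM[0]
    if d < 0 or d > p[-1]:
        raise ValueError(f"QTL position {d} cM outside group span [0, {p[-1]}]")
    k = int(np.searchsorted(p, d, side="left")) - 1
    k = min(max(k, 0), lmap.n_markers - 2)
    return k, k + 1


def _two_point_fractions(lmap: LinkageMap, d_star: float, design: str):
    """(k, r1, r2): flanking interval and QTL-to-flank recombination fractions."""
    k, _ = locate_interval(lmap, d_star)
    p = lmap.positions_cM - lmap.positions_cM[0]
    d1 = (d_star - p[k]) / 100.0  # cM -> Morgans
    d2 = (p[k + 1] - d_star) / 100.0
    r1, r2 = haldane(d1), haldane(d2)
    if design == "RIL":
        r1, r2 = ril_transform(r1), ril_transform(r2)
    return k, r1, r2


def qtl_conditional_probs(
    lmap: LinkageMap, markers: MarkerGenotypes, pos: QtlPosition | float
) -> np.ndarray:
    """n x 2 matrix of omega_{j|i} = P(Q_i = j | flanking marker genotypes).

    Conditioning uses only the two markers flanking D*.  Under no
    interference the joint probability of (flank_left, Q, flank_right)
    factorizes over the two sub-intervals, so the conditional table for
    observed flanks (a, b) is proportional to ``t1(a) * t2(b)`` with
    ``t(obs matching Q) = 1 - r`` and ``t(mismatch) = r``; rows are then
    normalized.  A progeny missing one flank conditions on the other alone;
    missing both flanks falls back to the unconditional (1/2, 1/2).
    """
    d = pos.D_star if isinstance(pos, QtlPosition) else float(pos)
    k, r1, r2 = _two_point_fractions(lmap, d, markers.design)
    a = markers.codes[:, k]
    b = markers.codes[:, k + 1]

    # P(Q=j | left flank alone) and | right flank alone; 0.5 when missing.
    def _single(obs, r):
        w = np.full((obs.size, 2), 0.5)
        w[obs == 1] = (1.0 - r, r)
        w[obs == 2] = (r, 1.0 - r)
        return w

    w = _single(a, r1) * _single(b, r2)
    w /= w.sum(axis=1, keepdims=True)
    return w


# ---------------------------------------------------------------------------
# file I/O — delimited text tables


def read_map(path, delimiter=None) -> dict[str, LinkageMap]:
    """Read a map table (columns: marker, group, position_cM) into groups."""
    df = pd.read_csv(path, sep=delimiter, engine="python")
    need = {"marker", "group", "position_cM"}
    if not need.issubset(df.columns):
        raise ValueError(f"map file must have columns {sorted(need)}")
    groups = {}
    for gid, sub in df.groupby("group", sort=False):
        sub = sub.sort_values("position_cM")
        groups[str(gid)] = LinkageMap(
            group_id=str(gid),
            marker_names=tuple(sub["marker"].astype(str)),
            positions_cM=sub["position_cM"].to_numpy(float),
        )
    return groups


def read_genotypes(path, design="RIL", delimiter=None) -> MarkerGenotypes:
    """Read an n x m genotype table (entries 1/2/NA) with a marker header."""
    df = pd.read_csv(path, sep=delimiter, engine="python", index_col=0)
    codes = df.to_numpy(float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int64)
    return MarkerGenotypes(codes=codes, design=design)
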