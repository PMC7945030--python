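"""Hierarchical complexity of binary networks.

The neighborhood degree sequence of a node of degree p is the ascending
sequence of its neighbors' degrees.  Hierarchical complexity measures, for
each degree class K_p (the set of nodes of degree p), the positional
variance of these sequences, and averages over the degree hierarchy:

    R = (1/D) * sum over p with |K_p| > 1 of
        [1 / (p (|K_p| - 1))] * sum_j sum_{i in K_p} (s_i^p(j) - mu^p(j))^2

where D is the number of distinct degrees in the network and mu^p(j) the
mean j-th entry over the class.  High R means nodes that are hierarchically
equivalent (same degree) are wired in diverse ways; R = 0 for any
vertex-transitive graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import BinaryConnectome

__all__ = [
    "DegreeInfo",
    "HCResult",
    "degree_info",
    "neighborhood_degree_sequence",
    "per_degree_variability",
    "hierarchical_complexity",
    "tier_hc",
]


@dataclass
class DegreeInfo:
    degrees: np.ndarray
    distinct_degrees: np.ndarray        # sorted distinct degree values
    classes: dict[int, np.ndarray]      # degree p -> node ids of class K_p

    @property
    def D(self) -> int:
        return len(self.distinct_degrees)


@dataclass
class HCResult:
    R: float
    per_degree: dict[int, float]                  # p -> R_p, only degrees with |K_p| > 1
    position_means: dict[int, np.ndarray]         # p -> mu^p(j), j = 1..p
    D: int
    degenerate: bool = False                      # True when no class has >= 2 members


def degree_info(G: BinaryConnectome) -> DegreeInfo:
    k = G.degrees()
    distinct = np.unique(k)
    classes = {int(p): np.flatnonzero(k == p) for p in distinct}
    return DegreeInfo(k, distinct, classes)


def neighborhood_degree_sequence(G: BinaryConnectome, i: int) -> np.ndarray:
    """Ascending degrees of node i's neighbors (length k_i; empty if isolated)."""
    if not (0 <= i < G.n):
        raise ValueError(f"invalid node id {i}")
    k = G.degrees()
    return np.sort(k[G.A[i] == 1])


def _class_sequences(A: np.ndarray, k: np.ndarray, members: np.ndarray, p: int) -> np.ndarray:
    """|K_p| x p matrix of ascending-sorted neighbor degrees, one row per member."""
    rows = [np.sort(k[A[i] == 1]) for i in members]
    return np.vstack(rows) if p > 0 else np.empty((len(members), 0))


def per_degree_variability(G: BinaryConnectome, p: int) -> float:
    """R_p for degree class K_p; raises if |K_p| <= 1 (undefined, distinct from 0)."""
    info = degree_info(G)
    members = info.classes.get(int(p))
    if members is None or len(members) <= 1:
        raise ValueError(f"per-degree variability undefined: |K_{p}| <= 1")
    if p == 0:
        return 0.0
    S = _class_sequences(G.A, info.degrees, members, p)
    mu = S.mean(axis=0)
    return float(((S - mu) ** 2).sum() / (p * (len(members) - 1)))


def hierarchical_complexity(G: BinaryConnectome) -> HCResult:
    """Global hierarchical complexity R with its per-degree decomposition."""
    if G.n == 0:
        raise ValueError("empty graph")
    info = degree_info(G)
    per_degree: dict[int, float] = {}
    position_means: dict[int, np.ndarray] = {}
    total = 0.0
    for p, members in info.classes.items():
        if len(members) <= 1:
            continue
        if p == 0:
            # isolated nodes: empty sequences contribute 0 but the class is defined
            per_degree[p] = 0.0
            position_means[p] = np.empty(0)
            continue
        S = _class_sequences(G.A, info.degrees, members, p)
        mu = S.mean(axis=0)
        rp = float(((S - mu) ** 2).sum() / (p * (len(members) - 1)))
        per_degree[p] = rp
        position_means[p] = mu
        total += rp
    degenerate = len(per_degree) == 0
    if degenerate:
        warnings.warn("no degree class has >= 2 members; hierarchical complexity set to 0")
        R = 0.0
    else:
        R = total / info.D
    return HCResult(R=R, per_degree=per_degree, position_means=position_means,
                    D=info.D, degenerate=degenerate)


def tier_hc(G: BinaryConnectome, degree_range: tuple[float, float]) -> tuple[float, bool]:
    """Mean R_p over distinct degrees p in [lo, hi] with |K_p| > 1.

    Returns ``(value, defined)``; ``defined`` is False (value 0) when no
    eligible degree lies in the range.
    """
    lo, hi = degree_range
    if lo > hi:
        raise ValueError(f"invalid degree range [{lo}, {hi}]")
    res = hierarchical_complexity(G)
    vals = [rp for p, rp in res.per_degree.items() if lo <= p <= hi]
    if not vals:
        return 0.0, False
    return float(np.mean(vals)), True
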