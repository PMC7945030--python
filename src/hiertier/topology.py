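"""Tier topology: hemispheric symmetry of homotopic neighborhoods,
common/uncommon connections, connection-type categories, the group
consensus connectome, and volume-normalized connection lengths.

The symmetry score of a homotopic pair (l, r) counts connections of l whose
mirror image is a connection of r, and normalizes by the count expected if
both neighborhoods were drawn independently at random from the n regions
(k_l * k_r / n).  A score of 1 is chance level; the maximum, reached when
N(r) is exactly the mirror of N(l), is n / k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .connectome import BinaryConnectome, LengthMatrix, NodeTable
from .tiers import TierModel, assign_tiers

__all__ = [
    "SymmetryScore",
    "ConnectionProfile",
    "CONNECTION_CATEGORIES",
    "mirror_map",
    "pair_symmetry",
    "tier_symmetry",
    "common_uncommon",
    "classify_connection",
    "connection_profile",
    "group_connectome",
    "tier_lengths",
]

CONNECTION_CATEGORIES = [
    "central-cortical",
    "intra-hemispheric cortico-cortical",
    "inter-hemispheric cortico-cortical",
    "central",
    "cortico-cerebellar",
    "central-cerebellar",
    "cerebellar",
]


@dataclass
class SymmetryScore:
    pair: tuple[int, int]
    observed_matches: int
    expected_matches: float
    score: float


@dataclass
class ConnectionProfile:
    """Per-tier counts over the seven connection categories."""

    counts: dict[int, dict[str, int]]

    def totals(self) -> dict[int, int]:
        return {t: sum(c.values()) for t, c in self.counts.items()}


def mirror_map(nodes: NodeTable) -> np.ndarray:
    """node -> homotopic partner; midline nodes map to themselves."""
    partner = nodes.partner.copy()
    partner[partner == -1] = np.flatnonzero(partner == -1)
    # NodeTable validated the involution already; keep the cheap re-check
    if not np.array_equal(partner[partner], np.arange(nodes.n)):
        raise ValueError("broken homotopic involution")
    return partner


def pair_symmetry(G: BinaryConnectome, pair: tuple[int, int], mapping: np.ndarray) -> SymmetryScore:
    """Normalized matching index between a homotopic pair's neighborhoods.

    observed = |N(l) ∩ mirror(N(r))| over all n candidate regions;
    expected = k_l k_r / n; score = observed / expected.
    """
    l, r = pair
    A = G.A
    k = G.degrees()
    if k[l] == 0 or k[r] == 0:
        raise ValueError(f"pair ({l},{r}): symmetry undefined for degree-0 node")
    nl = np.flatnonzero(A[l])
    nr_mirrored = mapping[np.flatnonzero(A[r])]
    observed = len(np.intersect1d(nl, nr_mirrored, assume_unique=True))
    expected = k[l] * k[r] / G.n
    return SymmetryScore(pair=(l, r), observed_matches=observed,
                         expected_matches=expected, score=observed / expected)


def tier_symmetry(
    G: BinaryConnectome, model: TierModel, mapping: np.ndarray
) -> dict[int, float]:
    """Mean pair symmetry score per tier.

    A pair is counted in the common tier of its members, or in the
    better-ranked (lower-numbered) tier when they differ.  Degree-0 members
    are excluded; tiers with no eligible pair are absent from the result.
    """
    tiers = assign_tiers(G, model)
    k = G.degrees()
    per_tier: dict[int, list[float]] = {}
    for l, r in G.nodes.homotopic_pairs():
        if k[l] == 0 or k[r] == 0:
            continue
        t = min(tiers[l], tiers[r])
        per_tier.setdefault(int(t), []).append(pair_symmetry(G, (l, r), mapping).score)
    return {t: float(np.mean(v)) for t, v in sorted(per_tier.items())}


def common_uncommon(G: BinaryConnectome, tier_nodes: np.ndarray) -> tuple[list[int], list[int]]:
    """ROIs commonly / uncommonly connected to a tier.

    A region is common to the tier if it links to at least 80% of the
    tier's regions, and uncommon if it links to more than none but at most
    20% of them.
    """
    tier_nodes = np.asarray(tier_nodes, int)
    if tier_nodes.size == 0:
        raise ValueError("empty tier")
    size = tier_nodes.size
    links = G.A[:, tier_nodes].sum(axis=1)
    eps = 1e-9
    common = [int(i) for i in range(G.n) if links[i] >= 0.8 * size - eps]
    uncommon = [int(i) for i in range(G.n) if 0 < links[i] <= 0.2 * size + eps]
    return common, uncommon


def classify_connection(edge: tuple[int, int], nodes: NodeTable) -> str:
    """One of the seven endpoint-class categories for an edge."""
    i, j = edge
    cls = nodes.tissue_class
    hemi = nodes.hemisphere
    ci, cj = cls[i], cls[j]
    pair = frozenset((ci, cj))
    if pair == {"cortical"}:
        return ("intra-hemispheric cortico-cortical"
                if hemi[i] == hemi[j] else "inter-hemispheric cortico-cortical")
    if pair == {"central", "cortical"}:
        return "central-cortical"
    if pair == {"central"}:
        return "central"
    if pair == {"cortical", "cerebellar"}:
        return "cortico-cerebellar"
    if pair == {"central", "cerebellar"}:
        return "central-cerebellar"
    if pair == {"cerebellar"}:
        return "cerebellar"
    raise ValueError(f"unknown tissue classes for edge {edge}: {ci}, {cj}")


def _edge_tier(tiers: np.ndarray, i: int, j: int) -> int:
    """An edge belongs to the better-ranked (lower-numbered) tier of its endpoints."""
    return int(min(tiers[i], tiers[j]))


def connection_profile(G: BinaryConnectome, model: TierModel) -> ConnectionProfile:
    """Category counts of each tier's connections (partition of the edge set)."""
    tiers = assign_tiers(G, model)
    counts: dict[int, dict[str, int]] = {}
    iu, ju = np.triu_indices(G.n, k=1)
    for i, j in zip(iu, ju):
        if not G.A[i, j]:
            continue
        t = _edge_tier(tiers, i, j)
        cat = classify_connection((int(i), int(j)), G.nodes)
        counts.setdefault(t, {c: 0 for c in CONNECTION_CATEGORIES})[cat] += 1
    return ConnectionProfile({t: counts[t] for t in sorted(counts)})


def group_connectome(
    group: list[BinaryConnectome], min_frac: float = 2 / 3
) -> BinaryConnectome:
    """Consensus network: edge present iff shared by >= ceil(min_frac * S) subjects."""
    if not group:
        raise ValueError("empty group")
    n = group[0].n
    ref = group[0].nodes.df
    for G in group[1:]:
        if G.n != n or not G.nodes.df[["label", "hemisphere", "tissue_class"]].equals(
            ref[["label", "hemisphere", "tissue_class"]]
        ):
            raise ValueError("subjects must share an aligned node table")
    S = len(group)
    need = math.ceil(min_frac * S - 1e-9)
    need = max(need, 1)
    stack = np.sum([G.A for G in group], axis=0)
    A = (stack >= need).astype(np.int8)
    np.fill_diagonal(A, 0)
    return BinaryConnectome(A, group[0].nodes)


def tier_lengths(
    L: LengthMatrix,
    G: BinaryConnectome,
    model: TierModel,
    brain_volume: float | None = None,
    exponent: float = 1 / 3,
) -> dict[int, np.ndarray]:
    """Connection lengths per tier, normalized by brain_volume ** exponent.

    The default exponent 1/3 keeps the normalized quantity in length-like
    units.  With ``brain_volume=None`` raw lengths are returned (flagged by
    the caller).  Each edge contributes to the better-ranked tier of its
    endpoints.
    """
    tiers = assign_tiers(G, model)
    scale = 1.0 if brain_volume is None else float(brain_volume) ** exponent
    out: dict[int, list[float]] = {}
    iu, ju = np.triu_indices(G.n, k=1)
    for i, j in zip(iu, ju):
        if not G.A[i, j]:
            continue
        out.setdefault(_edge_tier(tiers, i, j), []).append(L.L[i, j] / scale)
    return {t: np.array(v) for t, v in sorted(out.items())}
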