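"""Synthetic connectome cohorts with planted hierarchical structure.

The generator emulates the statistical features the tier/complexity
analysis relies on, without any claim of biophysical realism:

* degrees drawn from a multi-component Gaussian mixture (the planted
  degree tiers), sampled per homotopic pair so left/right partners share a
  degree;
* wiring from a stub-matching configuration model in which each created
  link is mirrored across hemispheres with probability ``mirror_prob``
  (hemispheric symmetry is planted at generation time, degrees exact);
* per-tier "order" knobs eta in [0, 1]: degree-preserving double-edge
  swaps that raise neighborhood overlap among same-tier nodes toward a
  target interpolating between the configuration-model baseline (eta = 0)
  and the maximal overlap (eta = 1) — eta -> 1 homogenizes a tier and
  lowers its hierarchical complexity;
* mirrored 3-D coordinates giving edge lengths, with mid-tier nodes
  placed in a tighter cluster (shorter mid-tier connections), and a
  subject brain volume;
* i.i.d. lognormal weights on planted edges only, so density thresholding
  at the planted density recovers the planted adjacency exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import (
    BinaryConnectome,
    LengthMatrix,
    NodeTable,
    WeightedConnectome,
    write_matrix,
)

__all__ = [
    "CohortConfig",
    "Subject",
    "Cohort",
    "term_like_config",
    "preterm_like_config",
    "sample_anatomy",
    "sample_degree_sequence",
    "realize_network",
    "mirror_and_annotate",
    "attach_geometry",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

# Default degree mixture emulating a 4-tier aggregated degree distribution
# at 30% density on 84 nodes: component (weight, mean, sd), low to high.
DEFAULT_MIXTURE = ((0.40, 13.0, 3.0), (0.40, 27.0, 3.0), (0.15, 44.0, 3.0), (0.05, 70.0, 3.0))

MAX_GENERATION_RESTARTS = 10_000


@dataclass
class CohortConfig:
    n_nodes: int = 84                 # 41 homotopic pairs + 2 midline central nodes
    n_midline: int = 2
    n_subjects: int = 30
    group_label: str = "group"
    mixture: tuple = DEFAULT_MIXTURE
    eta: tuple = (0.0, 0.0, 0.0, 0.0)  # order knob per tier, Tier 1 (hubs) first
    mirror_prob: float = 0.5
    weight_sigma: float = 0.5          # lognormal sigma of edge weights
    length_noise_sd: float = 2.0       # mm, on Euclidean edge lengths
    brain_volume_mean: float = 4.0e5   # mm^3
    brain_volume_sd: float = 3.0e4
    tier_radius: tuple = (1.0, 0.6, 0.6, 1.0)  # spatial compression per tier
    swap_cap: int = 4000               # ordering-swap proposals per tier
    null_reps_for_target: int = 20     # configuration models behind the eta target
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(c[2] <= 0 for c in self.mixture):
            raise ValueError("mixture sds must be positive")
        if len(self.eta) != len(self.mixture):
            raise ValueError("need one eta per mixture component (tier)")
        if any(not (0 <= e <= 1) for e in self.eta):
            raise ValueError("eta knobs must lie in [0, 1]")
        if not (0 <= self.mirror_prob <= 1):
            raise ValueError("mirror_prob must lie in [0, 1]")
        if (self.n_nodes - self.n_midline) % 2:
            raise ValueError("non-midline node count must be even")


def term_like_config(**kw) -> CohortConfig:
    """Diverse mid-tier wiring (high complexity), ordered hubs."""
    kw.setdefault("eta", (1.0, 0.0, 0.0, 0.0))
    kw.setdefault("group_label", "term-like")
    return CohortConfig(**kw)


def preterm_like_config(**kw) -> CohortConfig:
    """Partially homogenized mid-tier wiring (lower complexity), ordered hubs."""
    kw.setdefault("eta", (1.0, 0.6, 0.6, 0.0))
    kw.setdefault("group_label", "preterm-like")
    return CohortConfig(**kw)


# ---------------------------------------------------------------- degrees


def _component_tier(config: CohortConfig, component: int) -> int:
    """Tier label of a mixture component: Tier 1 = highest-mean component."""
    return len(config.mixture) - component


def sample_anatomy(config: CohortConfig, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Cohort-level mixture-component assignment (the synthetic parcellation).

    One component per homotopic pair (both members share it) and per
    midline node, resampled until every component has at least one pair,
    so all planted tiers exist in the cohort.  Shared by all subjects of a
    cohort the way a parcellation is shared by a study population.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, n_mid = config.n_nodes, config.n_midline
    n_pairs = (n - n_mid) // 2
    weights = np.array([c[0] for c in config.mixture])
    K = len(weights)
    for _ in range(1000):
        comp_pairs = rng.choice(K, size=n_pairs, p=weights)
        comp_mid = rng.choice(K, size=n_mid, p=weights)
        comps = np.empty(n, dtype=int)
        comps[0 : 2 * n_pairs : 2] = comp_pairs
        comps[1 : 2 * n_pairs : 2] = comp_pairs
        comps[2 * n_pairs :] = comp_mid
        if len(np.unique(comp_pairs)) == K:
            return comps
    raise RuntimeError("could not draw an anatomy covering every component")


def sample_degree_sequence(
    config: CohortConfig,
    n: int | None = None,
    seed: int | np.random.Generator = 0,
    components: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Graphical integer degree sequence from the planted mixture.

    A homotopic pair shares one drawn degree with probability
    ``mirror_prob`` (mirror-symmetric wiring needs matched left/right
    degrees) and draws independently otherwise, so at mirror_prob = 0 the
    hemispheres are fully independent.  Midline degrees are rounded to
    even (their mirror copies consume stubs in steps of two).  Degrees are
    rounded, clipped to [1, n-1], parity-repaired, and Erdos-Gallai
    checked with bounded resampling.  With ``components`` (a cohort-level
    anatomy from :func:`sample_anatomy`) the component of every node is
    fixed and only the degrees are drawn.  Returns ``(degrees,
    planted_tiers)`` with Tier 1 = the highest-mean component.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_nodes if n is None else n
    n_mid = config.n_midline if n == config.n_nodes else n % 2
    n_pairs = (n - n_mid) // 2
    weights = np.array([c[0] for c in config.mixture])
    means = np.array([c[1] for c in config.mixture])
    sds = np.array([c[2] for c in config.mixture])

    def draw_comp(size):
        return rng.choice(len(weights), size=size, p=weights)

    def draw_deg(comp):
        return np.clip(np.rint(rng.normal(means[comp], sds[comp])), 1, n - 1).astype(int)

    for _ in range(100):
        if components is not None:
            comp_l = components[0 : 2 * n_pairs : 2]
            comp_r = components[1 : 2 * n_pairs : 2]
            comp_mid = components[2 * n_pairs :]
        else:
            comp_l = draw_comp(n_pairs)
            comp_r = draw_comp(n_pairs)
            comp_mid = draw_comp(n_mid)
        d_l = draw_deg(comp_l)
        d_r = draw_deg(comp_r)
        copy = rng.random(n_pairs) < config.mirror_prob
        comp_r = np.where(copy, comp_l, comp_r)
        d_r = np.where(copy, d_l, d_r)
        d_mid = np.clip(2 * np.rint(draw_deg(comp_mid) / 2), 2, n - 2).astype(int)  # even

        degrees = np.empty(n, dtype=int)
        comps = np.empty(n, dtype=int)
        degrees[0 : 2 * n_pairs : 2] = d_l
        degrees[1 : 2 * n_pairs : 2] = d_r
        comps[0 : 2 * n_pairs : 2] = comp_l
        comps[1 : 2 * n_pairs : 2] = comp_r
        if n_mid:
            degrees[2 * n_pairs :] = d_mid
            comps[2 * n_pairs :] = comp_mid
        if degrees.sum() % 2:  # only lateral independent draws can make it odd
            lateral = rng.permutation(2 * n_pairs) if n_pairs else np.array([], int)
            for i in lateral:
                if degrees[i] < n - 1 and not (config.mirror_prob >= 1.0):
                    degrees[i] += 1
                    break
        if nx.is_graphical(list(degrees), method="eg"):
            tiers = np.array([_component_tier(config, c) for c in comps])
            return degrees, tiers
    raise RuntimeError("could not sample a graphical degree sequence in 100 tries")


# ------------------------------------------------- mirrored stub matching


def _partner_map(n: int, n_mid: int) -> np.ndarray:
    partner = np.arange(n)
    n_pairs = (n - n_mid) // 2
    partner[0 : 2 * n_pairs : 2] += 1
    partner[1 : 2 * n_pairs : 2] -= 1
    return partner


def _mirrored_configuration(
    degrees: np.ndarray, partner: np.ndarray, mirror_prob: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stub matching with probabilistic mirror-image links (see nulls)."""
    from .nulls import _stub_matching

    for _ in range(MAX_GENERATION_RESTARTS):
        out = _stub_matching(degrees, rng, partner=partner, mirror_prob=mirror_prob)
        if out is not None:
            return out
    raise RuntimeError("mirrored stub matching failed to terminate")


# ------------------------------------------------------- ordering swaps


def _tier_overlap(A: np.ndarray, members: np.ndarray) -> float:
    """Mean pairwise Jaccard overlap of neighborhoods within a node set."""
    if len(members) < 2:
        return 0.0
    sub = A[members].astype(float)
    inter = sub @ sub.T
    deg = sub.sum(axis=1)
    union = deg[:, None] + deg[None, :] - inter
    iu = np.triu_indices(len(members), k=1)
    with np.errstate(invalid="ignore"):
        J = np.where(union[iu] > 0, inter[iu] / np.maximum(union[iu], 1e-12), 0.0)
    return float(J.mean())


def _max_overlap(degrees: np.ndarray, members: np.ndarray) -> float:
    """Upper bound on the mean pairwise Jaccard (nested neighborhoods)."""
    if len(members) < 2:
        return 0.0
    k = degrees[members].astype(float)
    iu = np.triu_indices(len(members), k=1)
    lo = np.minimum(k[:, None], k[None, :])[iu]
    hi = np.maximum(k[:, None], k[None, :])[iu]
    return float((lo / hi).mean())


def _shared_count_delta(A, x, y, in_tier, members, sign):
    """Change of same-tier shared-neighbor count when toggling edge (x, y)."""
    d = 0
    for a, b in ((x, y), (y, x)):
        if in_tier[a]:
            m = members[(members != a) & (members != b)]
            d += int(A[b, m].sum())
    return sign * d


def _class_rp(A: np.ndarray, deg: np.ndarray, members: np.ndarray, p: int) -> float:
    if len(members) < 2 or p == 0:
        return 0.0
    S = np.vstack([np.sort(deg[A[i] == 1]) for i in members])
    mu = S.mean(axis=0)
    return float(((S - mu) ** 2).sum() / (p * (len(members) - 1)))


def _order_tiers(
    A: np.ndarray,
    degrees: np.ndarray,
    planted_tiers: np.ndarray,
    eta: dict[int, float],
    protected: np.ndarray,
    rng: np.random.Generator,
    swap_cap: int,
    null_reps: int,
) -> dict[int, dict[str, float]]:
    """Degree-preserving double-edge swaps that raise same-tier neighborhood
    overlap toward target J = eta * J_max + (1 - eta) * J_null per tier.

    A proposed swap is accepted when it either (i) increases the same-tier
    shared-neighbor count without raising hierarchical complexity in any
    affected degree class group (neither the tier's own classes nor the
    total over affected classes), or (ii) strictly lowers the tier's own
    per-degree complexity without raising the total — so the knob orders
    the targeted tier without leaking disorder into the rest of the degree
    hierarchy.  Swaps never remove a protected (mirror-orbit) edge.
    Degrees are untouched throughout.  Returns per-tier diagnostics
    (baseline, target and achieved overlap, proposals used).
    """
    from .nulls import _match_stubs

    diagnostics: dict[int, dict[str, float]] = {}
    active = {t: e for t, e in eta.items() if e > 0}
    members = {t: np.flatnonzero(planted_tiers == t) for t in active}
    active = {t: e for t, e in active.items() if len(members[t]) >= 2}
    if not active:
        return diagnostics

    # configuration-model baseline overlap per tier
    null_J = {t: [] for t in active}
    for r in range(null_reps):
        nr = None
        while nr is None:
            nr = _match_stubs(degrees, rng)
        for t in active:
            null_J[t].append(_tier_overlap(nr, members[t]))
    targets = {}
    for t, e in active.items():
        j_null = float(np.mean(null_J[t]))
        j_max = _max_overlap(degrees, members[t])
        targets[t] = e * j_max + (1 - e) * j_null
        diagnostics[t] = {"eta": e, "J_null": j_null, "J_max": j_max, "target": targets[t]}

    classes = {int(p): np.flatnonzero(degrees == p) for p in np.unique(degrees)}
    rp_cache: dict[int, float] = {}

    def cached_rp(p: int) -> float:
        if p not in rp_cache:
            rp_cache[p] = _class_rp(A, degrees, classes[p], p)
        return rp_cache[p]

    for t in sorted(active, key=lambda t: -active[t]):
        S = members[t]
        in_tier = np.zeros(len(degrees), bool)
        in_tier[S] = True
        tier_degs = {int(degrees[i]) for i in S}
        proposals = 0
        last_accept = 0
        stall_limit = max(500, swap_cap // 8)
        achieved = _tier_overlap(A, S)
        while achieved < targets[t] and proposals < swap_cap:
            if proposals - last_accept > stall_limit:
                break
            proposals += 1
            pop = A[S].sum(axis=0)  # tier-popularity of every node
            v = int(rng.choice(S))
            # a: popular among the tier but not yet a neighbor of v
            a_cand = np.flatnonzero((A[v] == 0) & (pop > 0))
            a_cand = a_cand[a_cand != v]
            if a_cand.size == 0:
                continue
            wa = pop[a_cand].astype(float) ** 2
            a = int(rng.choice(a_cand, p=wa / wa.sum()))
            # b: expendable (unpopular, unprotected) neighbor of v
            b_cand = np.flatnonzero((A[v] == 1) & ~protected[v])
            b_cand = b_cand[b_cand != a]
            if b_cand.size == 0:
                continue
            wb = 1.0 / (1.0 + pop[b_cand]) ** 2
            b = int(rng.choice(b_cand, p=wb / wb.sum()))
            c_cand = np.flatnonzero((A[a] == 1) & ~protected[a])
            c_cand = c_cand[(c_cand != v) & (c_cand != b)]
            c_cand = c_cand[A[b, c_cand] == 0]
            if c_cand.size == 0:
                continue
            wc = 1.0 / (1.0 + pop[c_cand]) ** 2
            c = int(rng.choice(c_cand, p=wc / wc.sum()))
            # swap: remove (v,b),(a,c); add (v,a),(b,c) — degrees unchanged
            affected = {int(degrees[x]) for x in (v, a, b, c)}
            aff_tier = affected & tier_degs
            r0_total = sum(cached_rp(p) for p in affected)  # on pristine A
            r0_tier = sum(rp_cache[p] for p in aff_tier)
            delta = _shared_count_delta(A, v, b, in_tier, S, -1)
            delta += _shared_count_delta(A, a, c, in_tier, S, -1)
            A[v, b] = A[b, v] = 0
            A[a, c] = A[c, a] = 0
            delta += _shared_count_delta(A, v, a, in_tier, S, +1)
            delta += _shared_count_delta(A, b, c, in_tier, S, +1)
            A[v, a] = A[a, v] = 1
            A[b, c] = A[c, b] = 1
            r_after = {p: _class_rp(A, degrees, classes[p], p) for p in affected}
            r1_total = sum(r_after.values())
            r1_tier = sum(r_after[p] for p in aff_tier)
            accept = r1_total <= r0_total and (
                (delta > 0 and r1_tier <= r0_tier) or r1_tier < r0_tier
            )
            if accept:
                rp_cache.update(r_after)
                last_accept = proposals
            else:
                A[v, a] = A[a, v] = 0
                A[b, c] = A[c, b] = 0
                A[v, b] = A[b, v] = 1
                A[a, c] = A[c, a] = 1
            if proposals % 200 == 0:
                achieved = _tier_overlap(A, S)
        diagnostics[t]["proposals"] = proposals
    for t in active:
        diagnostics[t]["achieved"] = _tier_overlap(A, members[t])
    return diagnostics


# --------------------------------------------------------- public surface


def realize_network(
    degrees: np.ndarray,
    eta: dict[int, float] | None = None,
    planted_tiers: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    swap_cap: int = 4000,
    null_reps: int = 20,
) -> tuple[BinaryConnectome, dict]:
    """Configuration-model realization of a degree sequence, then per-tier
    ordering swaps toward the eta targets.  Degrees are preserved exactly."""
    from .nulls import _match_stubs

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    degrees = np.asarray(degrees, int)
    if not nx.is_graphical(list(degrees), method="eg"):
        raise ValueError("degree sequence is not graphical")
    A = None
    while A is None:
        A = _match_stubs(degrees, rng)
    diagnostics = {}
    if eta and planted_tiers is not None:
        protected = np.zeros_like(A, dtype=bool)
        diagnostics = _order_tiers(
            A, degrees, planted_tiers, eta, protected, rng, swap_cap, null_reps
        )
    nodes = NodeTable.trivial(len(degrees))
    return BinaryConnectome(A, nodes), diagnostics


def _build_node_table(config: CohortConfig, planted_tiers: np.ndarray) -> NodeTable:
    """Hemisphere / tissue-class annotation from the planted tiers.

    Top tier mixes central and cortical regions, mid tiers are cortical,
    the bottom tier mixes in central regions and one cerebellar pair;
    midline nodes are central.
    """
    n = config.n_nodes
    n_mid = config.n_midline
    n_pairs = (n - n_mid) // 2
    hemi = np.array(["L", "R"] * n_pairs + ["M"] * n_mid)
    partner = _partner_map(n, n_mid)
    partner_col = partner.copy()
    partner_col[partner == np.arange(n)] = -1

    K = len(config.mixture)
    cls = np.array(["cortical"] * n, dtype=object)
    cls[hemi == "M"] = "central"
    pair_tiers = planted_tiers[0 : 2 * n_pairs : 2]
    top = np.flatnonzero(pair_tiers == 1)
    for idx, p in enumerate(top):  # alternate central/cortical among hub pairs
        if idx % 2 == 0:
            cls[2 * p] = cls[2 * p + 1] = "central"
    bottom = np.flatnonzero(pair_tiers == K)
    if bottom.size:
        p = bottom[0]
        cls[2 * p] = cls[2 * p + 1] = "cerebellar"
        for p in bottom[1::4]:
            cls[2 * p] = cls[2 * p + 1] = "central"
    df = pd.DataFrame(
        {
            "node_id": np.arange(n),
            "label": [f"roi{i:03d}" for i in range(n)],
            "hemisphere": hemi,
            "tissue_class": cls.astype(str),
            "homotopic_partner": partner_col,
            "volume_norm": np.nan,
        }
    )
    return NodeTable(df)


def mirror_and_annotate(
    config: CohortConfig,
    degrees: np.ndarray,
    planted_tiers: np.ndarray,
    mirror_prob: float | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[BinaryConnectome, np.ndarray]:
    """Mirrored configuration-model wiring plus node annotation.

    Each created link is copied to its homotopic mirror image with
    probability ``mirror_prob`` during stub matching, so hemispheric
    symmetry is planted while every node keeps its planted degree.
    Returns the annotated network and the protected mirror-orbit mask
    (edges the ordering swaps must not remove).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = config.mirror_prob if mirror_prob is None else mirror_prob
    partner = _partner_map(config.n_nodes, config.n_midline)
    A, protected = _mirrored_configuration(np.asarray(degrees, int), partner, p, rng)
    nodes = _build_node_table(config, planted_tiers)
    return BinaryConnectome(A, nodes), protected


def attach_geometry(
    G: BinaryConnectome,
    planted_tiers: np.ndarray,
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[LengthMatrix, float]:
    """Mirrored 3-D embedding -> Euclidean edge lengths (+ noise) and a
    subject brain volume.  Mid-tier nodes sit in a tighter cluster, so
    mid-tier connections are on average shorter."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = G.n
    partner = _partner_map(n, int(np.sum(G.nodes.hemisphere == "M")))
    coords = np.zeros((n, 3))
    radius = {t + 1: r for t, r in enumerate(config.tier_radius)}
    for i in range(n):
        j = partner[i]
        if j == i:  # midline
            coords[i] = [0.0, rng.uniform(-50, 50), rng.uniform(-50, 50)]
        elif j > i:  # left member: draw, mirror to partner
            scale = radius.get(int(planted_tiers[i]), 1.0)
            x = rng.uniform(10, 50)
            y, z = rng.uniform(-50, 50, size=2)
            coords[i] = [-x * scale, y * scale, z * scale]
            coords[j] = [x * scale, y * scale, z * scale]
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    noise = rng.normal(0.0, config.length_noise_sd, size=(n, n))
    noise = np.triu(noise, 1)
    L = np.maximum(D + noise + noise.T, 1.0)
    np.fill_diagonal(L, 0.0)
    L = L * (G.A > 0)
    volume = float(np.exp(rng.normal(np.log(config.brain_volume_mean),
                                     config.brain_volume_sd / config.brain_volume_mean)))
    return LengthMatrix(L), volume


@dataclass
class Subject:
    subject_id: str
    network: BinaryConnectome
    weights: WeightedConnectome
    lengths: LengthMatrix
    brain_volume: float
    planted_tiers: np.ndarray
    planted_density: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class Cohort:
    label: str
    subjects: list[Subject]
    config: CohortConfig
    manifest: dict


def _subject(config: CohortConfig, idx: int, anatomy: np.ndarray) -> Subject:
    master = config.seed
    deg_rng = np.random.default_rng([master, idx, 0])
    degrees, tiers = sample_degree_sequence(config, seed=deg_rng, components=anatomy)
    wire_rng = np.random.default_rng([master, idx, 1])
    G, protected = mirror_and_annotate(config, degrees, tiers, seed=wire_rng)
    eta = {t + 1: e for t, e in enumerate(config.eta)}
    swap_rng = np.random.default_rng([master, idx, 2])
    diagnostics = _order_tiers(
        G.A, degrees, tiers, eta, protected, swap_rng,
        config.swap_cap, config.null_reps_for_target,
    )
    G = BinaryConnectome(G.A, G.nodes)  # recompute density after swaps (unchanged edges count)
    geo_rng = np.random.default_rng([master, idx, 3])
    L, volume = attach_geometry(G, tiers, config, seed=geo_rng)
    w_rng = np.random.default_rng([master, idx, 4])
    n = G.n
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    on = G.A[iu, ju] == 1
    real = np.exp(w_rng.normal(0.0, config.weight_sigma, size=int(on.sum())))
    w[iu[on], ju[on]] = real
    # weak spurious connections (strictly below every real weight) emulate the
    # near-fully-connected matrices probabilistic tractography produces, so
    # thresholding above the planted density adds random, not degenerate, links
    spurious = real.min() * w_rng.uniform(0.05, 0.95, size=int((~on).sum()))
    w[iu[~on], ju[~on]] = spurious
    W = WeightedConnectome(w + w.T, G.nodes)
    return Subject(
        subject_id=f"{config.group_label}-{idx:03d}",
        network=G,
        weights=W,
        lengths=L,
        brain_volume=volume,
        planted_tiers=tiers,
        planted_density=G.density,
        diagnostics=diagnostics,
    )


def simulate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate a cohort; optionally write it to disk (matrices, node
    tables, lengths, volumes, manifest)."""
    anatomy = sample_anatomy(config, seed=np.random.default_rng([config.seed, 99]))
    subjects = [_subject(config, i, anatomy) for i in range(config.n_subjects)]
    manifest = {
        "group_label": config.group_label,
        "config": _config_dict(config),
        "seed": config.seed,
        "subject_seeds": [[config.seed, i] for i in range(config.n_subjects)],
        "planted_densities": [s.planted_density for s in subjects],
        "diagnostics": [
            {str(t): d for t, d in s.diagnostics.items()} for s in subjects
        ],
    }
    cohort = Cohort(config.group_label, subjects, config, manifest)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["mixture"] = [list(c) for c in config.mixture]
    d["eta"] = list(config.eta)
    d["tier_radius"] = list(config.tier_radius)
    return d


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vols = {}
    for s in cohort.subjects:
        write_matrix(s.weights.W, out / f"{s.subject_id}_matrix.csv")
        write_matrix(s.lengths.L, out / f"{s.subject_id}_lengths.csv")
        s.network.nodes.write_tsv(out / f"{s.subject_id}_nodes.tsv")
        vols[s.subject_id] = s.brain_volume
    manifest = dict(cohort.manifest)
    manifest["subjects"] = [s.subject_id for s in cohort.subjects]
    manifest["brain_volumes"] = vols
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_cohort(in_dir: str | Path) -> Cohort:
    """Load a written cohort; networks are rebuilt by thresholding each
    subject's weights at its recorded planted density."""
    from .connectome import read_matrix, threshold_to_density

    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    config = CohortConfig(**{
        k: (tuple(tuple(c) for c in v) if k == "mixture"
            else tuple(v) if k in ("eta", "tier_radius") else v)
        for k, v in manifest["config"].items()
    })
    subjects = []
    for sid, density in zip(manifest["subjects"], manifest["planted_densities"]):
        W = WeightedConnectome(
            read_matrix(src / f"{sid}_matrix.csv"),
            NodeTable.read_tsv(src / f"{sid}_nodes.tsv"),
        )
        G = threshold_to_density(W, density)
        L = LengthMatrix(read_matrix(src / f"{sid}_lengths.csv"))
        subjects.append(
            Subject(
                subject_id=sid,
                network=G,
                weights=W,
                lengths=L,
                brain_volume=manifest["brain_volumes"][sid],
                planted_tiers=np.zeros(G.n, int),
                planted_density=density,
            )
        )
    return Cohort(manifest["group_label"], subjects, config, manifest)
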