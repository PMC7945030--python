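"""Configuration-model null networks preserving a subject's degree sequence.

Each node receives as many "stubs" as its degree and stubs are matched at
random into links.  A drawn pair that would create a self-loop or duplicate
an existing link is rejected and redrawn; a stub left with no valid partner
is resolved by relocating an existing link, and a pass that cannot be
completed this way is restarted.  The result is a simple random graph with
exactly the source degree sequence and no other structure — the null
reference for hierarchical complexity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complexity import hierarchical_complexity, tier_hc
from .connectome import BinaryConnectome

__all__ = ["NullEnsemble", "configuration_model", "null_ensemble", "hc_null", "tier_hc_null"]

MAX_RESTARTS = 10_000


@dataclass
class NullEnsemble:
    source: BinaryConnectome
    replicates: list[BinaryConnectome]
    seed: int
    attempts_used: list[int]


def _stub_matching(
    degrees: np.ndarray,
    rng: np.random.Generator,
    partner: np.ndarray | None = None,
    mirror_prob: float = 0.0,
    max_repairs: int | None = None,
) -> tuple[np.ndarray, np.ndarray] | None:
    """One stub-matching pass; returns (adjacency, protected mask) or None.

    The node with the most open stubs is matched next, each of its stubs
    to a stub drawn uniformly at random from the remaining ones (for stub
    matching the processing order does not change the distribution of the
    pairing; leading with the hubs keeps the tail of the pass on
    low-degree nodes, where rejected pairs are easy to resolve).  A pair
    that would create a self-loop or duplicate link is rejected; when a
    stub is blocked entirely, an existing link (x, y) with x unattached
    to the blocked node u and y unattached to another open node v is
    re-drawn as (u, x) and (v, y).  A pass that exceeds the repair budget
    reports failure so the caller can restart it.

    With ``partner``/``mirror_prob`` set, each created link is copied to
    its homotopic mirror image with that probability, consuming the
    mirror nodes' stubs; mirrored orbits are flagged in the protected
    mask.  At mirror_prob == 1 repairs relocate whole orbits so the
    wiring stays exactly mirror-symmetric.  Midline nodes (partner ==
    self) are never linked to each other when mirroring is on, keeping
    their stub counts even so mirror copies through midline nodes always
    fit.
    """
    n = len(degrees)
    mirrored = partner is not None and mirror_prob > 0
    exact_mirror = mirrored and mirror_prob >= 1.0
    if max_repairs is None:
        max_repairs = 100 + 2 * n
    counts = degrees.astype(int).copy()
    A = np.zeros((n, n), dtype=np.int8)
    protected = np.zeros((n, n), dtype=bool)
    edges: list[tuple[int, int]] = []
    edge_idx: dict[tuple[int, int], int] = {}
    midline = (partner == np.arange(n)) if partner is not None else np.zeros(n, bool)
    repairs = 0
    nodes = np.arange(n)

    def add_edge(a: int, b: int) -> None:
        A[a, b] = A[b, a] = 1
        key = (a, b) if a < b else (b, a)
        edge_idx[key] = len(edges)
        edges.append(key)

    def remove_edge(a: int, b: int) -> None:
        A[a, b] = A[b, a] = 0
        protected[a, b] = protected[b, a] = False
        key = (a, b) if a < b else (b, a)
        i = edge_idx.pop(key)
        last = edges.pop()
        if i < len(edges):
            edges[i] = last
            edge_idx[last] = i

    def repair(u: int) -> bool:
        """Consume a blocked stub of u by relocating an existing link."""
        nonlocal repairs
        repairs += 1
        if repairs > max_repairs:
            return False
        up = int(partner[u]) if mirrored else u

        if not exact_mirror:
            others = nodes[(counts > 0) & (nodes != u)]
            others = others[np.argsort(-counts[others], kind="stable")]
            vs = list(map(int, others))
            if not vs and counts[u] >= 2:
                vs = [u]
            xs = np.flatnonzero(A[u] == 0)
            xs = xs[xs != u]
            if mirrored and midline[u]:
                xs = xs[~midline[xs]]
            rng.shuffle(xs)
            for v in vs:
                for x in map(int, xs):
                    ys = np.flatnonzero((A[x] == 1) & (A[v] == 0))
                    ys = ys[(ys != v) & (ys != u)]
                    if mirrored and midline[v]:
                        ys = ys[~midline[ys]]
                    if ys.size == 0:
                        continue
                    y = int(ys[int(rng.integers(ys.size))])
                    remove_edge(x, y)  # may split a mirror orbit at p < 1
                    add_edge(u, x)
                    add_edge(v, y)
                    counts[u] -= 1
                    counts[v] -= 1
                    return True
            return False

        if (up != u and counts[up] < 1) or (up == u and counts[u] < 2):
            return False  # mirror lockstep broken (pair-unequal degrees)
        xs = np.flatnonzero(A[u] == 0)
        xs = xs[(xs != u) & (xs != up)]
        if midline[u]:
            xs = xs[~midline[xs]]
        rng.shuffle(xs)
        for x in map(int, xs):
            ys = np.flatnonzero(A[x] == 1)
            ys = ys[(ys != u) & (ys != up)]
            rng.shuffle(ys)
            for y in map(int, ys):
                xp, yp = int(partner[x]), int(partner[y])
                if {xp, yp} == {x, y}:  # self-mirrored orbit, cannot split
                    continue
                key = (xp, yp) if xp < yp else (yp, xp)
                if key not in edge_idx or A[up, xp]:  # defensive: symmetry broken
                    continue
                remove_edge(x, y)
                remove_edge(xp, yp)
                add_edge(u, x)
                add_edge(up, xp)
                protected[u, x] = protected[x, u] = True
                protected[up, xp] = protected[xp, up] = True
                counts[u] -= 1
                counts[up] -= 1  # u midline: both new links consume u's stubs
                for freed in (y, yp):
                    counts[freed] += 1
                return True
        return False

    while True:
        open_nodes = nodes[counts > 0]
        if open_nodes.size == 0:
            return A, protected
        u = int(open_nodes[np.argmax(counts[open_nodes])])
        valid = (counts > 0) & (A[u] == 0) & (nodes != u)
        if mirrored and midline[u]:
            valid &= ~midline
        cand = nodes[valid]
        if cand.size == 0:
            if not repair(u):
                return None
            continue
        # uniform over remaining stubs of the valid candidates
        w = counts[cand]
        v = int(cand[np.searchsorted(np.cumsum(w), rng.integers(w.sum()), side="right")])
        counts[u] -= 1
        counts[v] -= 1
        add_edge(u, v)
        if mirrored and rng.random() < mirror_prob:
            up, vp = int(partner[u]), int(partner[v])
            if {up, vp} == {u, v}:
                protected[u, v] = protected[v, u] = True
            elif up != vp and counts[up] > 0 and counts[vp] > 0 and not A[up, vp]:
                counts[up] -= 1
                counts[vp] -= 1
                add_edge(up, vp)
                for a, b in ((u, v), (up, vp)):
                    protected[a, b] = protected[b, a] = True


def _match_stubs(degrees: np.ndarray, rng: np.random.Generator) -> np.ndarray | None:
    """Plain (unmirrored) stub-matching pass; adjacency or None on failure."""
    out = _stub_matching(degrees, rng)
    return None if out is None else out[0]


def configuration_model(G: BinaryConnectome, seed: int | np.random.Generator = 0) -> BinaryConnectome:
    """Random simple graph with exactly G's degree sequence."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    degrees = G.degrees()
    for attempt in range(MAX_RESTARTS):
        A = _match_stubs(degrees, rng)
        if A is not None:
            out = BinaryConnectome(A, G.nodes)
            out.attempts_used = attempt + 1  # diagnostic
            return out
    raise RuntimeError(
        f"configuration model failed after {MAX_RESTARTS} restarts "
        f"(degree sequence max={degrees.max()}, n={len(degrees)})"
    )


def null_ensemble(G: BinaryConnectome, n_reps: int, seed: int = 0) -> NullEnsemble:
    """Independent configuration-model replicates, one RNG stream each."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    reps, attempts = [], []
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        rep = configuration_model(G, rng)
        reps.append(rep)
        attempts.append(rep.attempts_used)
    return NullEnsemble(G, reps, seed, attempts)


def hc_null(G: BinaryConnectome, n_reps: int, seed: int = 0) -> np.ndarray:
    """Null distribution of global hierarchical complexity R over replicates."""
    ens = null_ensemble(G, n_reps, seed)
    return np.array([hierarchical_complexity(rep).R for rep in ens.replicates])


def tier_hc_null(
    G: BinaryConnectome, degree_range: tuple[float, float], n_reps: int, seed: int = 0
) -> np.ndarray:
    """Null distribution of tier-restricted hierarchical complexity."""
    ens = null_ensemble(G, n_reps, seed)
    return np.array([tier_hc(rep, degree_range)[0] for rep in ens.replicates])
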