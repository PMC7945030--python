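"""Degree-tier discovery from group-aggregated degree distributions.

Degrees of all nodes of all subjects in a group are pooled, a 1-D Gaussian
mixture is fitted for each candidate component count K, and the K minimizing
BIC is selected.  Boundaries between tiers are placed where the weighted
component densities pi_a N(m_a, s_a^2) and pi_b N(m_b, s_b^2) of adjacent
components intersect between their means.  Tier 1 is the highest-degree
component (the hub tier).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, pearsonr
from sklearn.mixture import GaussianMixture

from .connectome import BinaryConnectome

__all__ = [
    "AggregatedDegrees",
    "MixtureFit",
    "TierModel",
    "TierAssignment",
    "aggregate_degrees",
    "fit_mixture",
    "select_model",
    "component_boundaries",
    "analytic_crossing",
    "build_tier_model",
    "assign_tiers",
    "group_tier_proportions",
    "consensus_tiers",
    "consolidate",
    "tier_consistency",
]

# EM protocol: per-component variances, k-means++ init, 10 restarts,
# loglik tolerance 1e-6.  The variance floor is set at the integer
# rounding scale of degree data: narrower components would be spikes on
# single degree values, which BIC otherwise rewards spuriously.
N_RESTARTS = 10
EM_TOL = 1e-6
VARIANCE_FLOOR = 0.5


@dataclass
class AggregatedDegrees:
    group_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.size == 0:
            raise ValueError("no degree observations")
        if (v < 0).any():
            raise ValueError("degrees must be nonnegative")
        self.values = v.astype(float)


@dataclass
class MixtureFit:
    K: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    converged: bool
    seed: int


@dataclass
class TierModel:
    fit: MixtureFit
    thresholds: np.ndarray          # K-1 ascending crossing points, degree units
    merge_map: dict | None = None   # e.g. {1: "A", 2: "B", 3: "B", 4: "C"}
    bic_table: dict[int, float] = field(default_factory=dict)

    @property
    def n_tiers(self) -> int:
        return self.fit.K

    def tier_of_degree(self, k: float) -> int:
        """Tier label of a degree: Tier 1 = highest degrees.

        A degree exactly equal to a threshold goes to the lower-degree tier.
        """
        below = int(np.sum(self.thresholds < k))
        return self.fit.K - below

    def tier_range(self, tier: int) -> tuple[float, float]:
        """Half-open [lo, hi) degree interval of a tier (Tier 1 unbounded above)."""
        K = self.fit.K
        if not (1 <= tier <= K):
            raise ValueError(f"tier {tier} out of range 1..{K}")
        bounds = np.concatenate([[0.0], self.thresholds, [np.inf]])
        i = K - tier  # index from the bottom
        return float(bounds[i]), float(bounds[i + 1])


def aggregate_degrees(group: list[BinaryConnectome], group_label: str = "") -> AggregatedDegrees:
    """Pooled degrees of all nodes of all subjects in the group."""
    if not group:
        raise ValueError("empty group")
    return AggregatedDegrees(group_label, np.concatenate([G.degrees() for G in group]))


def fit_mixture(values: AggregatedDegrees | np.ndarray, K: int, seed: int = 0) -> MixtureFit:
    """EM fit of a K-component 1-D Gaussian mixture; best of 10 restarts.

    BIC = (3K - 1) ln N - 2 loglik (weights K-1, means K, variances K).
    """
    v = values.values if isinstance(values, AggregatedDegrees) else np.asarray(values, float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if v.size < 10 * K:
        raise ValueError(f"need >= {10 * K} observations to fit K={K}")
    X = v.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        n_init=N_RESTARTS,
        init_params="k-means++",
        tol=EM_TOL,
        reg_covar=VARIANCE_FLOOR,
        max_iter=500,
        random_state=seed,
    ).fit(X)
    order = np.argsort(gm.means_.ravel())
    loglik = float(gm.score(X) * len(v))
    return MixtureFit(
        K=K,
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.ravel()[order]),
        loglik=loglik,
        bic=float(gm.bic(X)),
        converged=bool(gm.converged_),
        seed=seed,
    )


def select_model(
    values: AggregatedDegrees | np.ndarray,
    k_range: range | tuple[int, int] = (2, 6),
    seed: int = 0,
) -> tuple[MixtureFit, dict[int, float]]:
    """Fit K over a range (default 2..6) and return the BIC-minimizing fit
    plus the full BIC-vs-K table."""
    if isinstance(k_range, tuple):
        k_range = range(k_range[0], k_range[1] + 1)
    fits: list[MixtureFit] = []
    for K in k_range:
        try:
            f = fit_mixture(values, K, seed=seed)
        except ValueError:
            continue
        if f.converged:
            fits.append(f)
    if not fits:
        raise ValueError("no mixture fit converged over the requested K range")
    table = {f.K: f.bic for f in fits}
    best = min(fits, key=lambda f: f.bic)
    return best, table


def _log_weighted_pdf(x: float, w: float, m: float, s: float) -> float:
    return np.log(w) + norm.logpdf(x, loc=m, scale=s)


def analytic_crossing(w1: float, m1: float, s1: float, w2: float, m2: float, s2: float) -> float:
    """Crossing of two weighted normal densities between their means (m1 < m2)."""
    if m1 >= m2:
        raise ValueError("components must be ordered by mean")
    f = lambda x: _log_weighted_pdf(x, w1, m1, s1) - _log_weighted_pdf(x, w2, m2, s2)
    lo, hi = m1, m2
    if f(lo) * f(hi) < 0:
        return float(brentq(f, lo, hi, xtol=1e-12))
    raise ValueError("no crossing between the means")


def component_boundaries(fit: MixtureFit) -> np.ndarray:
    """Tier thresholds: crossing of each adjacent pair of weighted component PDFs.

    Falls back to the posterior-equality point (responsibility switch) and
    finally to the midpoint of means when one component dominates throughout.
    """
    if fit.K < 2:
        raise ValueError("boundaries need >= 2 components")
    thresholds = []
    for a in range(fit.K - 1):
        b = a + 1
        try:
            x = analytic_crossing(
                fit.weights[a], fit.means[a], fit.sds[a],
                fit.weights[b], fit.means[b], fit.sds[b],
            )
        except ValueError:
            # responsibility switch restricted to this adjacent pair equals the
            # same log-density equation; if no sign change exists, use midpoint
            import warnings

            warnings.warn(
                f"components {a},{b}: no PDF crossing between means; using midpoint"
            )
            x = 0.5 * (fit.means[a] + fit.means[b])
        thresholds.append(x)
    t = np.array(thresholds)
    if not np.all(np.diff(t) > 0):
        raise ValueError("thresholds are not strictly increasing")
    return t


def build_tier_model(
    values: AggregatedDegrees | np.ndarray,
    k_range: range | tuple[int, int] = (2, 6),
    seed: int = 0,
    merge_map: dict | None = None,
) -> TierModel:
    fit, table = select_model(values, k_range, seed=seed)
    return TierModel(fit=fit, thresholds=component_boundaries(fit),
                     merge_map=merge_map, bic_table=table)


def assign_tiers(G: BinaryConnectome, model: TierModel) -> np.ndarray:
    """Per-node tier labels for one subject (Tier 1 = hubs)."""
    k = G.degrees()
    return np.array([model.tier_of_degree(ki) for ki in k])


@dataclass
class TierAssignment:
    """Group-level tier occupancy: per-node proportion of subjects per tier."""

    labels: list                    # tier labels, ordered high (Tier 1) to low
    proportions: np.ndarray         # n_nodes x n_labels, rows sum to 1
    consensus: list                 # per node: label or None (needs >= 2/3)

    def proportion_of(self, label) -> np.ndarray:
        return self.proportions[:, self.labels.index(label)]


def group_tier_proportions(
    group: list[BinaryConnectome], model: TierModel, min_frac: float = 2 / 3
) -> TierAssignment:
    """Proportion of subjects placing each node in each tier, and the
    consensus tier (assigned when the proportion reaches ``min_frac``)."""
    if not group:
        raise ValueError("empty group")
    labels = list(range(1, model.n_tiers + 1))
    per_subject = np.stack([assign_tiers(G, model) for G in group])  # S x n
    n = per_subject.shape[1]
    props = np.zeros((n, len(labels)))
    for c, lab in enumerate(labels):
        props[:, c] = (per_subject == lab).mean(axis=0)
    assignment = TierAssignment(labels, props, [])
    assignment.consensus = _consensus_from_props(props, labels, min_frac)
    return assignment


def _consensus_from_props(props: np.ndarray, labels: list, min_frac: float) -> list:
    out = []
    for row in props:
        j = int(np.argmax(row))
        out.append(labels[j] if row[j] >= min_frac - 1e-12 else None)
    return out


def consensus_tiers(assignment: TierAssignment, min_frac: float = 2 / 3) -> list:
    return _consensus_from_props(assignment.proportions, assignment.labels, min_frac)


def consolidate(assignment: TierAssignment, merge_map: dict) -> TierAssignment:
    """Relabel tiers (e.g. {1: 'A', 2: 'B', 3: 'B', 4: 'C'}) and re-sum proportions."""
    missing = [lab for lab in assignment.labels if lab not in merge_map]
    if missing:
        raise ValueError(f"merge map does not cover tiers {missing}")
    new_labels = list(dict.fromkeys(merge_map[lab] for lab in assignment.labels))
    n = assignment.proportions.shape[0]
    props = np.zeros((n, len(new_labels)))
    for old_idx, lab in enumerate(assignment.labels):
        props[:, new_labels.index(merge_map[lab])] += assignment.proportions[:, old_idx]
    out = TierAssignment(new_labels, props, [])
    out.consensus = _consensus_from_props(props, new_labels, 2 / 3)
    return out


def tier_consistency(propsA: np.ndarray, propsB: np.ndarray) -> float:
    """Pearson correlation of two groups' per-node tier-occupancy proportions."""
    propsA = np.asarray(propsA, float)
    propsB = np.asarray(propsB, float)
    if propsA.shape != propsB.shape:
        raise ValueError("proportion vectors must share the node set")
    if np.std(propsA) == 0 or np.std(propsB) == 0:
        raise ValueError("tier consistency undefined: zero-variance proportions")
    return float(pearsonr(propsA, propsB)[0])
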