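"""Group statistics: rank-sum tests, effect sizes, FDR, proportion tests,
correlation, and rank-based two-way analysis of variance.

All group contrasts in the pipeline run through this layer so that one
Benjamini–Hochberg family covers every reported P-value of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsReport",
    "Comparison",
    "wilcoxon_rank_sum",
    "cohens_d",
    "bh_fdr",
    "chi_square_proportions",
    "pearson",
    "rank_two_way",
]

EXACT_N_LIMIT = 25  # exact rank-sum enumeration up to this combined sample size


@dataclass
class Comparison:
    name: str
    statistic: float
    p_value: float
    cohens_d: float | None
    n1: int
    n2: int
    rejected: bool | None = None


@dataclass
class StatsReport:
    comparisons: list[Comparison]
    q: float = 0.05
    bh_cutoff: float = 0.0

    def apply_fdr(self) -> "StatsReport":
        pvals = np.array([c.p_value for c in self.comparisons])
        rejected, cutoff = bh_fdr(pvals, self.q)
        for c, r in zip(self.comparisons, rejected):
            c.rejected = bool(r)
        self.bh_cutoff = cutoff
        return self


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when n1 + n2 <= 25 and the pooled sample has no
    ties; otherwise the normal approximation with tie and continuity
    correction.  Returns (U statistic of x, two-sided p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (x.size + y.size <= EXACT_N_LIMIT and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def cohens_d(x, y) -> float:
    """Cohen's d with pooled SD weighted by (n1-1, n2-1)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per sample")
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("Cohen's d undefined: zero pooled SD")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level q.

    Rejects all p <= p_(i*) with i* = max{i : p_(i) <= i q / m}.  Returns
    (rejected flags in input order, realized cutoff = largest rejected p,
    0 when nothing is rejected).
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.zeros(0, bool), 0.0
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ok = ranked <= (np.arange(1, m + 1) * q / m)
    if not ok.any():
        return np.zeros(m, bool), 0.0
    cutoff = ranked[np.nonzero(ok)[0].max()]
    return p <= cutoff, float(cutoff)


def chi_square_proportions(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2 x C contingency table, no continuity
    correction, df = C - 1."""
    T = np.asarray(counts, float)
    if T.ndim != 2 or T.shape[0] != 2:
        raise ValueError("expected a 2 x C table")
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(T, correction=False)
    return float(chi2), float(p)


def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined: zero variance")
    return float(sps.pearsonr(x, y)[0])


def rank_two_way(values, factor_a, factor_b) -> dict[str, float]:
    """Scheirer-Ray-Hare rank-based two-way analysis of variance.

    Values are ranked globally (midranks for ties); sums of squares of a
    crossed two-factor layout are computed on the ranks and each effect's
    H = SS / MS_total is referred to a chi-square distribution with the
    effect's degrees of freedom.  Cell-mean sums of squares are exact for
    balanced designs, which is how the pipeline uses it.

    Returns {'p_a', 'p_b', 'p_interaction', 'H_a', 'H_b', 'H_interaction'}.
    """
    v = np.asarray(values, float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (v.shape == a.shape == b.shape):
        raise ValueError("values and factors must be aligned")
    levels_a = np.unique(a)
    levels_b = np.unique(b)
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs >= 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if not np.any((a == la) & (b == lb)):
                raise ValueError(f"empty cell ({la}, {lb})")
    r = sps.rankdata(v)
    N = r.size
    ms_total = r.var(ddof=1)  # includes the tie correction automatically
    if ms_total == 0:
        ones = {"p_a": 1.0, "p_b": 1.0, "p_interaction": 1.0,
                "H_a": 0.0, "H_b": 0.0, "H_interaction": 0.0}
        return ones
    grand = r.mean()

    def ss_between(levels, fac):
        return sum(np.sum(fac == l) * (r[fac == l].mean() - grand) ** 2 for l in levels)

    ss_a = ss_between(levels_a, a)
    ss_b = ss_between(levels_b, b)
    ss_cells = 0.0
    for la in levels_a:
        for lb in levels_b:
            m = (a == la) & (b == lb)
            ss_cells += m.sum() * (r[m].mean() - grand) ** 2
    ss_ab = ss_cells - ss_a - ss_b
    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b
    H_a = ss_a / ms_total
    H_b = ss_b / ms_total
    H_ab = max(ss_ab, 0.0) / ms_total
    return {
        "H_a": float(H_a),
        "H_b": float(H_b),
        "H_interaction": float(H_ab),
        "p_a": float(sps.chi2.sf(H_a, df_a)),
        "p_b": float(sps.chi2.sf(H_b, df_b)),
        "p_interaction": float(sps.chi2.sf(H_ab, df_ab)),
    }
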