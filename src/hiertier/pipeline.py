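"""End-to-end study orchestration on a cohort of connectomes.

``run_study`` reproduces the full analysis on two or more groups: group
tier models from aggregated degrees, global and per-tier hierarchical
complexity per subject, configuration-model nulls, hemispheric symmetry,
common/uncommon connections, connection-type profiles on the consensus
connectome, length summaries, and a single FDR-controlled family of group
contrasts.  ``density_sweep`` repeats the tier modelling across a range of
density thresholds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np

from . import __version__
from .complexity import hierarchical_complexity, tier_hc
from .connectome import BinaryConnectome, threshold_to_density
from .nulls import hc_null
from .stats import Comparison, StatsReport, cohens_d, wilcoxon_rank_sum
from .synthetic import Cohort
from .tiers import aggregate_degrees, build_tier_model, group_tier_proportions
from .topology import (
    common_uncommon,
    connection_profile,
    group_connectome,
    mirror_map,
    tier_lengths,
    tier_symmetry,
)

__all__ = ["run_study", "density_sweep", "validate_report", "write_report"]

log = logging.getLogger("hiertier")


def _networks_at_density(cohort: Cohort, density: float | None) -> list[BinaryConnectome]:
    if density is None:
        return [s.network for s in cohort.subjects]
    return [threshold_to_density(s.weights, density) for s in cohort.subjects]


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_study(
    cohorts: list[Cohort],
    density: float | None = None,
    k_range: tuple[int, int] = (2, 6),
    q: float = 0.05,
    n_null_reps: int = 1,
    seed: int = 0,
    merge_map: dict | None = None,
) -> dict:
    """Full study report over >= 2 groups.

    ``density=None`` analyses each subject's network as generated (the
    planted density); a float re-thresholds every subject's weighted
    matrix.  One configuration-model null per subject by default, matching
    a subject-wise null comparison.  All contrast P-values form one
    Benjamini-Hochberg family at level q.
    """
    if len(cohorts) < 2:
        raise ValueError("run_study needs >= 2 groups for contrasts")
    manifest = {
        "version": __version__,
        "seed": seed,
        "density": density,
        "k_range": list(k_range),
        "q": q,
        "n_null_reps": n_null_reps,
        "groups": {c.label: len(c.subjects) for c in cohorts},
    }
    manifest["config_hash"] = _config_hash(manifest)
    report: dict = {"manifest": manifest, "groups": {}, "contrasts": [], "bh_cutoff": None}

    per_group: dict[str, dict] = {}
    for gi, cohort in enumerate(cohorts):
        log.info("group %s: thresholding and tier modelling", cohort.label)
        nets = _networks_at_density(cohort, density)
        agg = aggregate_degrees(nets, cohort.label)
        model = build_tier_model(agg, k_range, seed=seed, merge_map=merge_map)
        assignment = group_tier_proportions(nets, model)
        K = model.n_tiers
        tier_ranges = {t: model.tier_range(t) for t in range(1, K + 1)}

        R_subj, tier_R = [], {t: [] for t in range(1, K + 1)}
        null_R = []
        null_tier_R = {t: [] for t in range(1, K + 1)}
        per_degree_tables, D_subj = [], []
        for si, G in enumerate(nets):
            res = hierarchical_complexity(G)
            R_subj.append(res.R)
            per_degree_tables.append({str(p): v for p, v in res.per_degree.items()})
            D_subj.append(res.D)
            for t in range(1, K + 1):
                tier_R[t].append(tier_hc(G, tier_ranges[t])[0])
            null_R.extend(hc_null(G, n_null_reps, seed=int(1e6 * (gi + 1) + si)))
        # one null network per subject for the tier-level null comparison
        from .nulls import configuration_model

        for si, G in enumerate(nets):
            rep = configuration_model(G, np.random.default_rng([seed, gi, si, 7]))
            for t in range(1, K + 1):
                null_tier_R[t].append(tier_hc(rep, tier_ranges[t])[0])

        log.info("group %s: topology", cohort.label)
        mapping = mirror_map(nets[0].nodes)
        sym = [tier_symmetry(G, model, mapping) for G in nets]
        sym_means = {
            t: float(np.mean([s[t] for s in sym if t in s]))
            for t in range(1, K + 1)
            if any(t in s for s in sym)
        }
        cu_counts = {}
        for t in range(1, K + 1):
            commons, uncommons = [], []
            for G in nets:
                tiers_nodes = np.flatnonzero(
                    np.array([model.tier_of_degree(k) for k in G.degrees()]) == t
                )
                if tiers_nodes.size == 0:
                    continue
                c, u = common_uncommon(G, tiers_nodes)
                commons.append(len(c))
                uncommons.append(len(u))
            if commons:
                cu_counts[t] = {
                    "common_mean": float(np.mean(commons)),
                    "uncommon_mean": float(np.mean(uncommons)),
                }
        consensus_net = group_connectome(nets)
        profile = connection_profile(consensus_net, model)
        lengths = {}
        for s, G in zip(cohort.subjects, nets):
            per_tier = tier_lengths(s.lengths, G, model, s.brain_volume)
            for t, vals in per_tier.items():
                lengths.setdefault(t, []).append(float(np.mean(vals)))
        length_summary = {
            t: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
            for t, v in sorted(lengths.items())
        }

        hist_vals, hist_edges = np.histogram(
            agg.values, bins=np.arange(-0.5, agg.values.max() + 1.5)
        )
        per_group[cohort.label] = {
            "n_subjects": len(nets),
            "degree_histogram": {
                "counts": hist_vals.tolist(),
                "bin_edges": hist_edges.tolist(),
            },
            "bic_table": {str(k): v for k, v in model.bic_table.items()},
            "selected_K": K,
            "components": {
                "weights": model.fit.weights.tolist(),
                "means": model.fit.means.tolist(),
                "sds": model.fit.sds.tolist(),
            },
            "thresholds": model.thresholds.tolist(),
            "tier_proportions": assignment.proportions.tolist(),
            "consensus_tiers": [t if t is not None else "N/A" for t in assignment.consensus],
            "global_hc": [float(r) for r in R_subj],
            "per_degree_hc": per_degree_tables,
            "D": D_subj,
            "tier_hc": {str(t): [float(x) for x in v] for t, v in tier_R.items()},
            "null_hc": [float(r) for r in null_R],
            "null_tier_hc": {str(t): [float(x) for x in v] for t, v in null_tier_R.items()},
            "tier_symmetry": {str(t): v for t, v in sym_means.items()},
            "common_uncommon": {str(t): v for t, v in cu_counts.items()},
            "connection_profile": {str(t): c for t, c in profile.counts.items()},
            "length_summary": {str(t): v for t, v in length_summary.items()},
            "_internal": {"model": model, "tier_R": tier_R, "null_tier_R": null_tier_R,
                          "R_subj": R_subj, "null_R": null_R},
        }
        report["groups"] = per_group

    comparisons: list[Comparison] = []

    def add(name, x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.size < 2 or y.size < 2:
            return
        stat, p = wilcoxon_rank_sum(x, y)
        try:
            d = cohens_d(x, y)
        except ValueError:
            d = None
        comparisons.append(Comparison(name, stat, p, d, x.size, y.size))

    labels = [c.label for c in cohorts]
    for a in range(len(labels)):
        ga = per_group[labels[a]]["_internal"]
        # subject networks vs their configuration models
        add(f"{labels[a]}: HC vs null", ga["R_subj"], ga["null_R"])
        for t, v in ga["tier_R"].items():
            add(f"{labels[a]}: tier {t} HC vs null", v, ga["null_tier_R"][t])
        for b in range(a + 1, len(labels)):
            gb = per_group[labels[b]]["_internal"]
            add(f"{labels[a]} vs {labels[b]}: global HC", ga["R_subj"], gb["R_subj"])
            common_tiers = set(ga["tier_R"]) & set(gb["tier_R"])
            for t in sorted(common_tiers):
                add(f"{labels[a]} vs {labels[b]}: tier {t} HC",
                    ga["tier_R"][t], gb["tier_R"][t])
    stats_report = StatsReport(comparisons, q=q).apply_fdr()
    report["contrasts"] = [
        {
            "name": c.name,
            "statistic": c.statistic,
            "p_value": c.p_value,
            "cohens_d": c.cohens_d,
            "n1": c.n1,
            "n2": c.n2,
            "rejected": c.rejected,
        }
        for c in stats_report.comparisons
    ]
    report["bh_cutoff"] = stats_report.bh_cutoff
    for g in per_group.values():
        g.pop("_internal")
    return report


def density_sweep(
    cohorts: list[Cohort],
    grid: np.ndarray | list[float] | None = None,
    k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
) -> list[dict]:
    """Selected component count and tier thresholds per density per group."""
    if grid is None:
        grid = np.arange(0.2, 0.4 + 1e-9, 0.0005)
    grid = np.asarray(grid, float)
    if (grid <= 0).any() or (grid > 1).any():
        raise ValueError("densities must lie in (0, 1]")
    rows = []
    for d in grid:
        for cohort in cohorts:
            nets = [threshold_to_density(s.weights, float(d)) for s in cohort.subjects]
            model = build_tier_model(aggregate_degrees(nets, cohort.label), k_range, seed=seed)
            rows.append(
                {
                    "density": float(d),
                    "group": cohort.label,
                    "selected_K": model.n_tiers,
                    "thresholds": model.thresholds.tolist(),
                }
            )
    return rows


# ------------------------------------------------------------- reporting

_REQUIRED_GROUP_KEYS = {
    "n_subjects": int,
    "degree_histogram": dict,
    "bic_table": dict,
    "selected_K": int,
    "components": dict,
    "thresholds": list,
    "tier_proportions": list,
    "consensus_tiers": list,
    "global_hc": list,
    "per_degree_hc": list,
    "D": list,
    "tier_hc": dict,
    "null_hc": list,
    "null_tier_hc": dict,
    "tier_symmetry": dict,
    "common_uncommon": dict,
    "connection_profile": dict,
    "length_summary": dict,
}


def validate_report(report: dict) -> None:
    """Check the report against the shipped schema (required keys + types)."""
    schema = json.loads(
        resources.files("hiertier").joinpath("report_schema.json").read_text()
    )
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    if not isinstance(report["groups"], dict) or len(report["groups"]) < 1:
        raise ValueError("report.groups must be a non-empty mapping")
    for label, g in report["groups"].items():
        for key, typ in _REQUIRED_GROUP_KEYS.items():
            if key not in g:
                raise ValueError(f"group {label!r} missing key {key!r}")
            if not isinstance(g[key], typ):
                raise ValueError(f"group {label!r} key {key!r} must be {typ.__name__}")
    for c in report["contrasts"]:
        for key in ("name", "statistic", "p_value", "n1", "n2", "rejected"):
            if key not in c:
                raise ValueError(f"contrast missing key {key!r}")


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write report.json plus TSV tables (contrasts, consensus tiers)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    validate_report(report)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    import pandas as pd

    pd.DataFrame(report["contrasts"]).to_csv(out / "contrasts.tsv", sep="\t", index=False)
    for label, g in report["groups"].items():
        pd.DataFrame(
            {"node_id": range(len(g["consensus_tiers"])), "tier": g["consensus_tiers"]}
        ).to_csv(out / f"consensus_tiers_{label}.tsv", sep="\t", index=False)
    return path
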