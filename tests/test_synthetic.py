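import json

import networkx as nx
import numpy as np
import pytest

from hiertier.complexity import hierarchical_complexity, tier_hc
from hiertier.connectome import threshold_to_density
from hiertier.nulls import tier_hc_null
from hiertier.synthetic import (
    CohortConfig,
    attach_geometry,
    mirror_and_annotate,
    preterm_like_config,
    read_cohort,
    realize_network,
    sample_anatomy,
    sample_degree_sequence,
    simulate_cohort,
    term_like_config,
)
from hiertier.topology import mirror_map, pair_symmetry, tier_lengths
from hiertier.tiers import MixtureFit, TierModel


SMALL = dict(n_subjects=3, swap_cap=300, null_reps_for_target=5)


class TestDegreeSampling:
    def test_point_mass_mixture_gives_constant_degrees(self):
        cfg = CohortConfig(n_nodes=10, n_midline=0, mixture=((1.0, 4.0, 1e-6),), eta=(0.0,))
        deg, tiers = sample_degree_sequence(cfg, n=10, seed=0)
        assert set(deg.tolist()) == {4}
        assert set(tiers.tolist()) == {1}

    def test_output_graphical_and_even(self):
        cfg = CohortConfig(seed=0)
        for s in range(10):
            deg, _ = sample_degree_sequence(cfg, seed=s)
            assert deg.sum() % 2 == 0
            assert nx.is_graphical(deg.tolist(), method="eg")
            assert deg.min() >= 1 and deg.max() <= cfg.n_nodes - 1

    def test_matched_pair_degrees_at_full_mirroring(self):
        cfg = CohortConfig(mirror_prob=1.0)
        deg, _ = sample_degree_sequence(cfg, seed=1)
        left, right = deg[0:82:2], deg[1:82:2]
        assert np.array_equal(left, right)

    def test_independent_pair_degrees_without_mirroring(self):
        cfg = CohortConfig(mirror_prob=0.0)
        deg, _ = sample_degree_sequence(cfg, seed=1)
        assert not np.array_equal(deg[0:82:2], deg[1:82:2])

    def test_anatomy_covers_every_component_and_is_pairwise(self):
        cfg = CohortConfig()
        comps = sample_anatomy(cfg, seed=3)
        assert set(comps.tolist()) >= set(range(4))
        assert np.array_equal(comps[0:82:2], comps[1:82:2])

    def test_pooled_degrees_recover_mixture_means(self):
        cfg = CohortConfig(seed=0)
        from hiertier.tiers import select_model

        vals = np.concatenate(
            [sample_degree_sequence(cfg, seed=[9, i])[0] for i in range(50)]
        )
        best, _ = select_model(vals, (2, 6), seed=0)
        assert best.K == 4
        assert np.all(np.abs(best.means - [13, 27, 44, 70]) < 1.5)


class TestRealizeNetwork:
    def test_degree_sequence_preserved_exactly(self):
        cfg = CohortConfig(seed=0)
        deg, tiers = sample_degree_sequence(cfg, seed=2)
        G, _ = realize_network(deg, eta={1: 1.0, 3: 0.5}, planted_tiers=tiers,
                               seed=0, swap_cap=300, null_reps=5)
        assert np.array_equal(G.degrees(), deg)
        assert np.all(np.diag(G.A) == 0) and G.A.max() <= 1

    def test_eta_zero_is_configuration_model_draw(self):
        cfg = CohortConfig(seed=0)
        deg, tiers = sample_degree_sequence(cfg, seed=3)
        G, diag = realize_network(deg, eta={}, planted_tiers=tiers, seed=1)
        assert diag == {}
        assert np.array_equal(G.degrees(), deg)

    def test_hub_ordering_lowers_top_tier_complexity_below_null(self):
        cfg = CohortConfig(seed=0, mirror_prob=1.0)
        wins = trials = 0
        for rep in range(5):
            rng = np.random.default_rng(400 + rep)
            deg, tiers = sample_degree_sequence(cfg, seed=rng)
            if (tiers == 1).sum() < 2:
                continue
            G, _ = realize_network(deg, eta={1: 1.0}, planted_tiers=tiers,
                                   seed=rep, swap_cap=2000, null_reps=10)
            top = deg[tiers == 1]
            obs = tier_hc(G, (top.min(), top.max()))[0]
            null = tier_hc_null(G, (top.min(), top.max()), 10, seed=rep).mean()
            trials += 1
            wins += obs < null
        assert trials >= 3 and wins == trials

    def test_non_graphical_sequence_rejected(self):
        with pytest.raises(ValueError):
            realize_network(np.array([5, 1, 1, 1]), seed=0)


class TestMirroring:
    def test_full_mirroring_gives_symmetric_adjacency(self):
        cfg = CohortConfig(seed=0, mirror_prob=1.0)
        deg, tiers = sample_degree_sequence(cfg, seed=4)
        G, protected = mirror_and_annotate(cfg, deg, tiers, seed=0)
        m = mirror_map(G.nodes)
        assert np.array_equal(G.A, G.A[np.ix_(m, m)])
        k = G.degrees()
        for l, r in G.nodes.homotopic_pairs():
            assert pair_symmetry(G, (l, r), m).score == pytest.approx(G.n / k[l])

    def test_no_mirroring_scores_near_chance(self):
        scores = []
        cfg = CohortConfig(seed=0, mirror_prob=0.0)
        for rep in range(10):
            deg, tiers = sample_degree_sequence(cfg, seed=[5, rep])
            G, _ = mirror_and_annotate(cfg, deg, tiers, seed=rep)
            m = mirror_map(G.nodes)
            k = G.degrees()
            scores += [pair_symmetry(G, p, m).score for p in G.nodes.homotopic_pairs()
                       if k[p[0]] and k[p[1]]]
        assert 0.85 <= np.mean(scores) <= 1.15

    def test_annotation_structure(self):
        cfg = CohortConfig(seed=0)
        deg, tiers = sample_degree_sequence(cfg, seed=6)
        G, _ = mirror_and_annotate(cfg, deg, tiers, seed=0)
        nt = G.nodes
        assert (nt.hemisphere == "M").sum() == 2
        assert set(nt.tissue_class[nt.hemisphere == "M"]) == {"central"}
        assert (nt.tissue_class == "cerebellar").sum() == 2
        assert len(nt.homotopic_pairs()) == 41


class TestGeometry:
    def test_mirrored_coordinates_give_symmetric_lengths(self):
        cfg = CohortConfig(seed=0, mirror_prob=1.0)
        deg, tiers = sample_degree_sequence(cfg, seed=7)
        G, _ = mirror_and_annotate(cfg, deg, tiers, seed=1)
        L, vol = attach_geometry(G, tiers, cfg, seed=2)
        assert np.array_equal(L.L, L.L.T)
        assert vol > 0
        assert np.all(L.L[G.A == 1] >= 1.0)

    def test_mid_tier_connections_are_shorter(self):
        cfg = CohortConfig(seed=0)
        fit = MixtureFit(
            K=4, weights=np.full(4, 0.25),
            means=np.array([13.0, 27.0, 44.0, 70.0]),
            sds=np.full(4, 3.0), loglik=0.0, bic=0.0, converged=True, seed=0,
        )
        from hiertier.tiers import component_boundaries

        model = TierModel(fit=fit, thresholds=component_boundaries(fit))
        mids, outers = [], []
        for rep in range(5):
            deg, tiers = sample_degree_sequence(cfg, seed=[8, rep])
            G, _ = mirror_and_annotate(cfg, deg, tiers, seed=rep)
            L, vol = attach_geometry(G, tiers, cfg, seed=rep)
            per_tier = tier_lengths(L, G, model, brain_volume=vol)
            for t, vals in per_tier.items():
                (mids if t in (2, 3) else outers).append(vals.mean())
        assert np.mean(mids) < np.mean(outers)


class TestCohortSimulation:
    def test_determinism_and_planted_density_recovery(self):
        c1 = simulate_cohort(term_like_config(seed=5, **SMALL))
        c2 = simulate_cohort(term_like_config(seed=5, **SMALL))
        for s1, s2 in zip(c1.subjects, c2.subjects):
            assert np.array_equal(s1.weights.W, s2.weights.W)
            assert np.array_equal(s1.network.A, s2.network.A)
            assert s1.brain_volume == s2.brain_volume
        s = c1.subjects[0]
        B = threshold_to_density(s.weights, s.planted_density)
        assert np.array_equal(B.A, s.network.A)

    def test_distinct_seeds_differ(self):
        c1 = simulate_cohort(term_like_config(seed=5, **SMALL))
        c2 = simulate_cohort(term_like_config(seed=6, **SMALL))
        assert not np.array_equal(c1.subjects[0].network.A, c2.subjects[0].network.A)

    def test_roundtrip_through_disk(self, tmp_path):
        cohort = simulate_cohort(preterm_like_config(seed=9, **SMALL), tmp_path / "c")
        manifest = json.loads((tmp_path / "c" / "manifest.json").read_text())
        assert manifest["group_label"] == "preterm-like"
        back = read_cohort(tmp_path / "c")
        assert len(back.subjects) == len(cohort.subjects)
        for s1, s2 in zip(cohort.subjects, back.subjects):
            assert np.array_equal(s1.network.A, s2.network.A)
            assert s1.brain_volume == pytest.approx(s2.brain_volume)

    def test_networks_simple_with_planted_degrees(self):
        cohort = simulate_cohort(term_like_config(seed=10, **SMALL))
        for s in cohort.subjects:
            A = s.network.A
            assert np.all(np.diag(A) == 0)
            assert np.array_equal(A, A.T)
            assert A.max() <= 1
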