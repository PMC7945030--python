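import numpy as np
import pandas as pd
import pytest

from hiertier.connectome import BinaryConnectome, LengthMatrix, NodeTable
from hiertier.tiers import MixtureFit, TierModel
from hiertier.topology import (
    CONNECTION_CATEGORIES,
    classify_connection,
    common_uncommon,
    connection_profile,
    group_connectome,
    mirror_map,
    pair_symmetry,
    tier_lengths,
    tier_symmetry,
)

from conftest import graph_from_edges, random_connectome


def paired_nodes(n):
    return NodeTable.trivial(n)


def simple_model(thresholds):
    K = len(thresholds) + 1
    return TierModel(
        fit=MixtureFit(
            K=K,
            weights=np.full(K, 1 / K),
            means=np.linspace(5, 40, K),
            sds=np.full(K, 2.0),
            loglik=0.0,
            bic=0.0,
            converged=True,
            seed=0,
        ),
        thresholds=np.asarray(thresholds, float),
    )


class TestMirrorMap:
    def test_partners_map_to_each_other_and_twice_is_identity(self):
        nt = paired_nodes(6)
        m = mirror_map(nt)
        assert m[0] == 1 and m[1] == 0
        assert np.array_equal(m[m], np.arange(6))

    def test_midline_maps_to_itself(self):
        nt = paired_nodes(5)
        assert mirror_map(nt)[4] == 4


class TestPairSymmetry:
    def test_perfectly_mirrored_neighborhoods_hand_example(self):
        # n = 10, pair (0, 1); both connect to pairs (2,3),(4,5),(6,7),(8,9)
        # in mirrored fashion: N(0) = {2,4,6,8}, N(1) = {3,5,7,9}
        edges = [(0, v) for v in (2, 4, 6, 8)] + [(1, v) for v in (3, 5, 7, 9)]
        G = graph_from_edges(edges, 10)
        s = pair_symmetry(G, (0, 1), mirror_map(G.nodes))
        assert s.observed_matches == 4
        assert s.expected_matches == pytest.approx(1.6)
        assert s.score == pytest.approx(2.5)

    def test_disjoint_mirrored_neighborhoods_score_zero(self):
        edges = [(0, 2), (0, 4), (1, 6), (1, 7)]  # mirror(N(1)) = {7,6}, disjoint from {2,4}
        G = graph_from_edges(edges, 8)
        assert pair_symmetry(G, (0, 1), mirror_map(G.nodes)).score == 0.0

    def test_random_neighborhoods_score_near_one_on_average(self):
        rng = np.random.default_rng(0)
        n, k = 40, 10
        scores = []
        candidates = np.arange(2, n)
        for _ in range(100):
            nl = rng.choice(candidates, size=k, replace=False)
            nr = rng.choice(candidates, size=k, replace=False)
            A = np.zeros((n, n), dtype=np.int8)
            A[0, nl] = A[nl, 0] = 1
            A[1, nr] = A[nr, 1] = 1
            A[0, 0] = A[1, 1] = 0
            G = BinaryConnectome(A, paired_nodes(n))
            scores.append(pair_symmetry(G, (0, 1), mirror_map(G.nodes)).score)
        assert 0.9 <= np.mean(scores) <= 1.1

    def test_score_invariant_under_left_right_swap(self):
        G = random_connectome(12, 0.4, 3)
        m = mirror_map(G.nodes)
        a = pair_symmetry(G, (0, 1), m)
        b = pair_symmetry(G, (1, 0), m)
        assert a.score == pytest.approx(b.score)

    def test_degree_zero_member_undefined(self):
        G = graph_from_edges([(0, 2)], 4)
        with pytest.raises(ValueError):
            pair_symmetry(G, (0, 1), mirror_map(G.nodes))


class TestTierSymmetry:
    def test_single_pair_tier_mean_is_pair_score(self):
        edges = [(0, v) for v in (2, 4)] + [(1, v) for v in (3, 5)] + [(2, 3), (4, 5)]
        G = graph_from_edges(edges, 6)
        model = simple_model([10.0])  # everyone below 10 -> all tier 2
        m = mirror_map(G.nodes)
        out = tier_symmetry(G, model, m)
        assert set(out) == {2}
        assert out[2] == pytest.approx(
            np.mean([pair_symmetry(G, p, m).score for p in G.nodes.homotopic_pairs()])
        )

    def test_pair_in_different_tiers_counts_in_better_tier(self):
        # node 0 degree 3 (tier 1 with threshold 2.5), node 1 degree 1 (tier 2)
        edges = [(0, 2), (0, 4), (0, 5), (1, 3)]
        G = graph_from_edges(edges, 6)
        model = simple_model([2.5])
        out = tier_symmetry(G, model, mirror_map(G.nodes))
        assert 1 in out  # the (0,1) pair lands in tier 1


class TestCommonUncommon:
    def test_boundaries_inclusive(self):
        # tier of 5 nodes {0..4}; node 5 links to 4 of them (80%): common;
        # node 6 links to 1 (20%): uncommon; node 7 links to none: neither
        edges = [(5, i) for i in range(4)] + [(6, 0)] + [(7, 8)]
        G = graph_from_edges(edges, 9)
        common, uncommon = common_uncommon(G, np.arange(5))
        assert 5 in common and 6 in uncommon
        assert 7 not in common and 7 not in uncommon

    def test_empty_tier_rejected(self):
        with pytest.raises(ValueError):
            common_uncommon(random_connectome(6, 0.5, 0), np.array([], dtype=int))


class TestClassification:
    def build_nodes(self):
        df = pd.DataFrame(
            {
                "node_id": range(6),
                "label": list("abcdef"),
                "hemisphere": ["L", "R", "L", "R", "M", "M"],
                "tissue_class": [
                    "cortical", "cortical", "cerebellar", "cerebellar", "central", "central",
                ],
                "homotopic_partner": [1, 0, 3, 2, -1, -1],
            }
        )
        return NodeTable(df)

    @pytest.mark.parametrize(
        "edge,expected",
        [
            ((0, 1), "inter-hemispheric cortico-cortical"),
            ((4, 0), "central-cortical"),
            ((4, 5), "central"),
            ((0, 2), "cortico-cerebellar"),
            ((4, 2), "central-cerebellar"),
            ((2, 3), "cerebellar"),
        ],
    )
    def test_category_by_endpoint_classes(self, edge, expected):
        assert classify_connection(edge, self.build_nodes()) == expected

    def test_intra_hemispheric_needs_same_side(self):
        df = self.build_nodes().df.copy()
        df.loc[1, "hemisphere"] = "L"
        df.loc[0, "homotopic_partner"] = -1
        df.loc[1, "homotopic_partner"] = -1
        # re-pair 0 with nobody; direct L-L cortical edge
        nt = NodeTable(df)
        assert classify_connection((0, 1), nt) == "intra-hemispheric cortico-cortical"

    def test_category_counts_partition_edges(self):
        G = random_connectome(16, 0.4, 5)
        model = simple_model([4.0])
        profile = connection_profile(G, model)
        assert sum(profile.totals().values()) == G.n_edges
        for counts in profile.counts.values():
            assert set(counts) == set(CONNECTION_CATEGORIES)


class TestGroupConnectome:
    def test_two_thirds_retention(self):
        g1 = graph_from_edges([(0, 1), (2, 3)], 4)
        g2 = graph_from_edges([(0, 1)], 4)
        g3 = graph_from_edges([(1, 2)], 4)
        gc = group_connectome([g1, g2, g3])
        assert gc.A[0, 1] == 1      # in 2 of 3 subjects
        assert gc.A[2, 3] == 0      # in 1 of 3
        assert gc.A[1, 2] == 0

    def test_identical_subjects_idempotent(self):
        G = random_connectome(10, 0.4, 1)
        gc = group_connectome([G, G, G])
        assert np.array_equal(gc.A, G.A)

    def test_min_frac_limits(self):
        subs = [random_connectome(12, 0.4, s) for s in range(4)]
        inter = group_connectome(subs, min_frac=1.0)
        union = group_connectome(subs, min_frac=1e-9)
        stack = np.sum([G.A for G in subs], axis=0)
        assert np.array_equal(inter.A, (stack == 4).astype(np.int8))
        assert np.array_equal(union.A, (stack >= 1).astype(np.int8))

    def test_mismatched_tables_rejected(self):
        a = random_connectome(6, 0.5, 1)
        b = random_connectome(8, 0.5, 2)
        with pytest.raises(ValueError):
            group_connectome([a, b])


class TestTierLengths:
    def setup_case(self):
        G = random_connectome(10, 0.5, 2)
        L = LengthMatrix(np.full((10, 10), 30.0) - 30.0 * np.eye(10))
        model = simple_model([3.0])
        return G, L, model

    def test_constant_lengths_stay_constant(self):
        G, L, model = self.setup_case()
        out = tier_lengths(L, G, model, brain_volume=8.0)
        for vals in out.values():
            assert np.allclose(vals, 15.0)  # 30 / 8^(1/3)

    def test_volume_scaling_contract(self):
        G, L, model = self.setup_case()
        a = tier_lengths(L, G, model, brain_volume=1000.0)
        b = tier_lengths(L, G, model, brain_volume=2000.0)
        for t in a:
            assert np.allclose(b[t], a[t] / 2 ** (1 / 3))

    def test_missing_volume_returns_raw_lengths(self):
        G, L, model = self.setup_case()
        out = tier_lengths(L, G, model, brain_volume=None)
        for vals in out.values():
            assert np.allclose(vals, 30.0)

    def test_lengths_partition_matches_edges(self):
        G, L, model = self.setup_case()
        out = tier_lengths(L, G, model, brain_volume=1.0)
        assert sum(len(v) for v in out.values()) == G.n_edges
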