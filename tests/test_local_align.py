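"""Seed selection, match/gap classification, scoring, and expansion."""

import numpy as np
import pytest

from leprimalign import (
    GlobalAlignment,
    Params,
    align,
    classify_edges,
    expand_pair,
    inter_score,
    intra_score,
    local_score,
    select_seeds,
)
from leprimalign.entropy_clustering import form_initial_cluster
from leprimalign.network_model import write_cluster_pairs

from conftest import make_crosslinks, make_network


def ga_from(scores, norm_scores=None):
    ga = GlobalAlignment(scores=dict(scores))
    ga.norm_scores = dict(norm_scores or {})
    return ga


class TestSelectSeeds:
    def test_threshold_cut_descending(self):
        ga = ga_from({("a", "x"): 2.5, ("b", "y"): 1.2, ("c", "z"): 0.7})
        assert select_seeds(ga, 1.0) == [("a", "x"), ("b", "y")]

    def test_threshold_above_max_gives_empty(self):
        ga = ga_from({("a", "x"): 2.5})
        assert select_seeds(ga, 3.0) == []

    def test_ties_broken_lexicographically(self):
        ga = ga_from({("a", "y"): 1.5, ("a", "x"): 1.5})
        assert select_seeds(ga, 1.0) == [("a", "x"), ("a", "y")]


class TestClassifyEdges:
    """The two conserved-edge configurations: partners adjacent
    (match) vs partners joined through one unaligned node (gap)."""

    @staticmethod
    def _aligned_from(pairs):
        pairs = set(pairs)
        return lambda u, v: (u, v) in pairs

    def test_adjacent_partners_make_match(self):
        net_a = make_network([("vA1", "vA2", 0.8)], name="netA")
        net_b = make_network([("vB1", "vB2", 0.9)], name="netB")
        cls = classify_edges(
            {"vA1", "vA2"},
            {"vB1", "vB2"},
            net_a,
            net_b,
            self._aligned_from([("vA1", "vB1"), ("vA2", "vB2")]),
        )
        assert cls.match == {("vA1", "vA2")}
        assert cls.gap == set()

    def test_one_unaligned_intermediate_makes_gap(self):
        net_a = make_network([("vA1", "vA2", 0.8)], name="netA")
        net_b = make_network(
            [("vB1", "vB4", 0.9), ("vB4", "vB2", 0.9)], name="netB"
        )
        cls = classify_edges(
            {"vA1", "vA2"},
            {"vB1", "vB2", "vB4"},
            net_a,
            net_b,
            self._aligned_from([("vA1", "vB1"), ("vA2", "vB2")]),
        )
        assert cls.gap == {("vA1", "vA2")}
        assert cls.match == set()

    def test_aligned_intermediate_is_not_a_gap(self):
        # the 2-hop detour only counts when the middle node is aligned
        # to nothing in the partner cluster
        net_a = make_network([("vA1", "vA2", 0.8), ("vA1", "vA3", 0.5)], name="netA")
        net_b = make_network(
            [("vB1", "vB4", 0.9), ("vB4", "vB2", 0.9)], name="netB"
        )
        cls = classify_edges(
            {"vA1", "vA2", "vA3"},
            {"vB1", "vB2", "vB4"},
            net_a,
            net_b,
            self._aligned_from(
                [("vA1", "vB1"), ("vA2", "vB2"), ("vA3", "vB4")]
            ),
        )
        assert ("vA1", "vA2") not in cls.gap

    def test_distant_partners_are_neither(self):
        net_a = make_network([("vA1", "vA2", 0.8)], name="netA")
        net_b = make_network(
            [("vB1", "m1", 0.9), ("m1", "m2", 0.9), ("m2", "vB2", 0.9)],
            name="netB",
        )
        cls = classify_edges(
            {"vA1", "vA2"},
            {"vB1", "vB2", "m1", "m2"},
            net_a,
            net_b,
            self._aligned_from([("vA1", "vB1"), ("vA2", "vB2")]),
        )
        assert cls.match == set() and cls.gap == set()

    def test_match_and_gap_disjoint_match_wins(self):
        # both an adjacent partner pair and an unaligned detour exist
        net_a = make_network([("vA1", "vA2", 0.8)], name="netA")
        net_b = make_network(
            [("vB1", "vB2", 0.9), ("vB1", "u", 0.9), ("u", "vB2", 0.9)],
            name="netB",
        )
        cls = classify_edges(
            {"vA1", "vA2"},
            {"vB1", "vB2", "u"},
            net_a,
            net_b,
            self._aligned_from([("vA1", "vB1"), ("vA2", "vB2")]),
        )
        assert cls.match == {("vA1", "vA2")}
        assert cls.gap == set()


class TestScores:
    @pytest.fixture
    def three_edge_cluster(self):
        """One match (w=0.5), one gap (w=0.4), one unconserved (w=0.9)."""
        net_a = make_network(
            [("a1", "a2", 0.5), ("a3", "a4", 0.4), ("a1", "a3", 0.9)],
            name="netA",
        )
        net_b = make_network(
            [("b1", "b2", 1.0), ("b3", "u", 1.0), ("u", "b4", 1.0)],
            name="netB",
        )
        aligned = lambda u, v: (u, v) in {  # noqa: E731
            ("a1", "b1"), ("a2", "b2"), ("a3", "b3"), ("a4", "b4")
        }
        members_a = {"a1", "a2", "a3", "a4"}
        members_b = {"b1", "b2", "b3", "b4", "u"}
        cls = classify_edges(members_a, members_b, net_a, net_b, aligned)
        assert cls.match == {("a1", "a2")}
        assert cls.gap == {("a3", "a4")}
        return net_a, members_a, cls

    def test_intra_hand_value_beta_one(self, three_edge_cluster):
        net_a, members_a, cls = three_edge_cluster
        assert intra_score(members_a, net_a, cls, beta=1.0) == pytest.approx(0.3)

    def test_intra_hand_value_beta_zero(self, three_edge_cluster):
        net_a, members_a, cls = three_edge_cluster
        s = intra_score(members_a, net_a, cls, beta=0.0)
        assert s == pytest.approx(0.5 / 3, abs=1e-12)
        assert s == pytest.approx(0.1667, abs=5e-5)

    def test_intra_all_matched_unit_weights(self):
        net_a = make_network([("a1", "a2", 1.0), ("a2", "a3", 1.0)], name="netA")
        from leprimalign.local_align import EdgeClassification

        cls = EdgeClassification(match={("a1", "a2"), ("a2", "a3")})
        assert intra_score({"a1", "a2", "a3"}, net_a, cls, 1.0) == 1.0

    def test_intra_no_edges_scores_zero(self):
        net_a = make_network([], extra_nodes=["a1", "a2"], name="netA")
        from leprimalign.local_align import EdgeClassification

        assert intra_score({"a1", "a2"}, net_a, EdgeClassification(), 1.0) == 0.0

    def test_inter_mean_of_best(self):
        ga = ga_from(
            {},
            {("u1", "x"): 0.8, ("u1", "y"): 0.2, ("u2", "y"): 0.6},
        )
        assert inter_score({"u1", "u2"}, {"x", "y"}, ga) == pytest.approx(0.7)

    def test_inter_no_crosslinks_is_zero(self):
        assert inter_score({"u1"}, {"x"}, ga_from({}, {})) == 0.0

    def test_inter_perfect_partners(self):
        ga = ga_from({}, {("u1", "x"): 1.0, ("u2", "x"): 1.0})
        assert inter_score({"u1", "u2"}, {"x"}, ga) == 1.0

    def test_local_score_mixing(self):
        # gamma=0.25, S_inter=0.7, S_intra=0.3 -> 0.4
        net_a = make_network([("a1", "a2", 0.3)], name="netA")
        net_b = make_network([("b1", "b2", 1.0)], name="netB")
        ga = ga_from(
            {("a1", "b1"): 5.0, ("a2", "b2"): 5.0},
            {("a1", "b1"): 0.8, ("a2", "b2"): 0.6},
        )
        # all edges matched: S_intra = 0.3/1; S_inter = 0.7
        s = local_score({"a1", "a2"}, {"b1", "b2"}, net_a, net_b, ga, 1.0, 0.25)
        assert s == pytest.approx(0.25 * 0.7 + 0.75 * 0.3)

    @pytest.mark.parametrize("gamma, expect", [(1.0, 0.7), (0.0, 0.3)])
    def test_local_score_extremes(self, gamma, expect):
        net_a = make_network([("a1", "a2", 0.3)], name="netA")
        net_b = make_network([("b1", "b2", 1.0)], name="netB")
        ga = ga_from(
            {("a1", "b1"): 5.0, ("a2", "b2"): 5.0},
            {("a1", "b1"): 0.8, ("a2", "b2"): 0.6},
        )
        s = local_score({"a1", "a2"}, {"b1", "b2"}, net_a, net_b, ga, 1.0, gamma)
        assert s == pytest.approx(expect)

    def test_scores_bounded_random(self):
        rng = np.random.default_rng(41)
        from conftest import random_instance

        for _ in range(30):
            g1, g2, xl = random_instance(rng)
            from leprimalign import run_global_alignment

            if not xl.entries:
                continue
            ga = run_global_alignment(g1, g2, xl)
            nodes1, nodes2 = sorted(g1.nodes), sorted(g2.nodes)
            m1 = set(rng.choice(nodes1, size=min(4, len(nodes1)), replace=False))
            m2 = set(rng.choice(nodes2, size=min(4, len(nodes2)), replace=False))
            beta = float(rng.uniform(0, 1))
            gamma = float(rng.uniform(0, 1))
            s12 = local_score(m1, m2, g1, g2, ga, beta, gamma, "12")
            s21 = local_score(m2, m1, g2, g1, ga, beta, gamma, "21")
            assert 0.0 <= s12 <= 1.0 and 0.0 <= s21 <= 1.0


def two_triangles(weight=0.8, xl_score=100.0):
    g1 = make_network(
        [("a", "b", weight), ("b", "c", weight), ("a", "c", weight)], name="net1"
    )
    g2 = make_network(
        [("x", "y", weight), ("y", "z", weight), ("x", "z", weight)], name="net2"
    )
    xl = make_crosslinks(
        [("a", "x", xl_score), ("b", "y", xl_score), ("c", "z", xl_score)]
    )
    return g1, g2, xl


class TestExpandPair:
    def test_saturated_pair_unchanged(self):
        g1, g2, xl = two_triangles()
        from leprimalign import run_global_alignment

        ga = run_global_alignment(g1, g2, xl)
        c1 = form_initial_cluster("a", g1)
        c2 = form_initial_cluster("x", g2)
        pair = expand_pair(c1, c2, g1, g2, ga, Params())
        assert pair.c1.members == {"a", "b", "c"}
        assert pair.c2.members == {"x", "y", "z"}

    def test_missing_member_absorbed_and_scores_rise(self):
        # planted triangles; the initial clusters omit one member each.
        # The missing members carry the strongest internal edges and are
        # cross-linked many-to-many into the partner cluster, so each
        # addition raises its cluster's own score and both get absorbed.
        g1 = make_network(
            [("a1", "a2", 0.5), ("a1", "a3", 0.9), ("a2", "a3", 0.9)], name="net1"
        )
        g2 = make_network(
            [("b1", "b2", 0.5), ("b1", "b3", 0.9), ("b2", "b3", 0.9)], name="net2"
        )
        xl = make_crosslinks(
            [("a1", "b1", 50.0), ("a2", "b2", 50.0), ("a3", "b3", 50.0),
             ("a3", "b1", 40.0), ("a3", "b2", 40.0),
             ("a1", "b3", 40.0), ("a2", "b3", 40.0)]
        )
        from leprimalign import run_global_alignment
        from leprimalign.network_model import Cluster

        ga = run_global_alignment(g1, g2, xl)
        params = Params()
        c1 = Cluster("net1", {"a1", "a2"})
        c2 = Cluster("net2", {"b1", "b2"})
        s12_init = local_score(c1.members, c2.members, g1, g2, ga, 1.0, 0.25, "12")
        s21_init = local_score(c2.members, c1.members, g2, g1, ga, 1.0, 0.25, "21")
        trace = []
        pair = expand_pair(c1, c2, g1, g2, ga, params, trace=trace)
        assert "a3" in pair.c1.members and "b3" in pair.c2.members
        assert pair.s_local_12 > s12_init
        assert pair.s_local_21 > s21_init
        # exhaustive check: each recorded acceptance strictly increased
        # the directional score
        assert trace
        assert all(after > before for _, _, before, after in trace)

    def test_termination_when_candidates_exhausted(self):
        g1 = make_network([("a", "b", 0.9)], name="net1", extra_nodes=["q"])
        g2 = make_network([("x", "y", 0.9)], name="net2")
        xl = make_crosslinks([("a", "x", 10.0), ("b", "y", 10.0)])
        from leprimalign import run_global_alignment
        from leprimalign.network_model import Cluster

        ga = run_global_alignment(g1, g2, xl)
        pair = expand_pair(
            Cluster("net1", {"a", "b"}), Cluster("net2", {"x", "y"}),
            g1, g2, ga, Params(),
        )
        assert pair.c1.members == {"a", "b"}


class TestAlign:
    def test_identity_triangles_single_pair(self):
        g1, g2, xl = two_triangles(weight=0.8)
        pairs = align(g1, g2, xl, Params(theta=1.0))
        assert len(pairs) == 1
        pair = pairs[0]
        assert pair.c1.members == {"a", "b", "c"}
        assert pair.c2.members == {"x", "y", "z"}
        # every edge is a match, so S_intra is the mean edge weight
        from leprimalign import run_global_alignment

        ga = run_global_alignment(g1, g2, xl)
        cls = classify_edges(
            pair.c1.members, pair.c2.members, g1, g2, ga.aligned
        )
        assert len(cls.match) == 3 and not cls.gap
        assert intra_score(pair.c1.members, g1, cls, 1.0) == pytest.approx(0.8)

    def test_theta_above_all_scores_gives_empty(self):
        g1, g2, xl = two_triangles()
        assert align(g1, g2, xl, Params(theta=1e6)) == []

    def test_small_final_clusters_discarded(self):
        # a single cross-linked node pair with no useful neighbourhood
        g1 = make_network([], extra_nodes=["a"], name="net1")
        g2 = make_network([], extra_nodes=["x"], name="net2")
        xl = make_crosslinks([("a", "x", 10.0)])
        assert align(g1, g2, xl, Params(theta=0.5)) == []

    def test_deterministic_byte_identical_output(self, tmp_path):
        from leprimalign import SyntheticSpec, generate_pair

        g1, g2, xl, _ = generate_pair(SyntheticSpec(seed=5))
        outputs = []
        for run in range(2):
            pairs = align(g1, g2, xl)
            p1 = tmp_path / f"r{run}_1.tsv"
            p2 = tmp_path / f"r{run}_2.tsv"
            write_cluster_pairs(pairs, str(p1), str(p2))
            outputs.append(p1.read_bytes() + p2.read_bytes())
        assert outputs[0] == outputs[1]

    def test_seed_skipped_only_when_both_endpoints_visited(self):
        from leprimalign import SyntheticSpec, generate_pair
        from leprimalign.global_align import run_global_alignment

        g1, g2, xl, _ = generate_pair(SyntheticSpec(seed=8))
        params = Params()
        pairs = align(g1, g2, xl, params)
        # replay the visited bookkeeping over the seed queue
        ga = run_global_alignment(g1, g2, xl)
        seeds = select_seeds(ga, params.theta)
        visited1, visited2 = set(), set()
        emitted = {p.seed for p in pairs}
        for v1, v2 in seeds:
            if v1 in visited1 and v2 in visited2:
                assert (v1, v2) not in emitted
                continue
            if (v1, v2) in emitted:
                p = next(p for p in pairs if p.seed == (v1, v2))
                visited1 |= p.c1.members
                visited2 |= p.c2.members
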