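"""Shared-neighborhood score: decomposition, weights, leave-one-out."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snslink import (
    CalibrationBank,
    LinkCategory,
    NodeKind,
    PharmGraph,
    calibrate,
    link_weight,
    score_all_pairs,
    shared_count,
    sn_score,
)
from snslink.errors import CalibrationMissingError, GraphValidationError
from snslink.graph_store import CATEGORY_KINDS, CROSS_KIND_CATEGORIES
from snslink.sns_core import ScoringOptions

from conftest import (
    brute_decomposition,
    brute_shared_count,
    injected_bank,
    make_node,
    random_tripartite,
)


class TestSharedCount:
    def test_worked_example_single_shared_node(self, worked_example):
        g, i, j = worked_example
        assert shared_count(g, i, j) == 1

    def test_isolated_nodes_share_nothing(self):
        g = PharmGraph()
        d = make_node(NodeKind.DRUG, "d")
        x = make_node(NodeKind.DISEASE, "x")
        g.add_node(d)
        g.add_node(x)
        assert shared_count(g, d, x) == 0

    def test_direct_edge_does_not_contribute(self, triangle_graph):
        g, n = triangle_graph
        # D1-X1 are directly linked; only P1 is a shared neighbor
        assert shared_count(g, n["D1"], n["X1"]) == 1

    def test_same_node_rejected(self, triangle_graph):
        g, n = triangle_graph
        with pytest.raises(GraphValidationError):
            shared_count(g, n["D1"], n["D1"])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_linear_scan_oracle(self, seed):
        g = random_tripartite(np.random.default_rng(seed))
        nodes = g.nodes()
        for i, j in itertools.combinations(nodes, 2):
            assert shared_count(g, i, j) == brute_shared_count(g, i, j)

    def test_bridge_kind_restriction(self, worked_example):
        g, i, j = worked_example
        only_drug = ScoringOptions(bridge_kinds=frozenset({NodeKind.DRUG}))
        assert shared_count(g, i, j, only_drug) == 0  # m is a protein


class TestLinkWeight:
    bank = injected_bank({1: 0.2, 2: 0.5, 3: 0.7})

    def test_real_link_weighs_one(self, worked_example):
        g, i, j = worked_example
        m = make_node(NodeKind.PROTEIN, "m")
        assert link_weight(g, self.bank, i, m) == 1.0

    def test_virtual_pair_no_shared_neighbors_weighs_zero(self, worked_example):
        g, i, j = worked_example
        assert link_weight(g, self.bank, i, j) != 0  # they share m
        lone = make_node(NodeKind.DISEASE, "lone")
        g.add_node(lone)
        assert link_weight(g, self.bank, i, lone) == 0.0

    def test_virtual_pair_mediated_by_two_nodes_weighs_p2(self, worked_example):
        g, i, _ = worked_example
        k = make_node(NodeKind.PROTEIN, "k")
        assert link_weight(g, self.bank, i, k) == pytest.approx(0.5)  # P(2)

    def test_uncalibrated_category_raises(self, worked_example):
        g, i, j = worked_example
        empty = CalibrationBank()
        with pytest.raises(CalibrationMissingError):
            link_weight(g, empty, i, j)


class TestWorkedExample:
    """Five-node walkthrough: total = s0 + P(2) + P(3)*P(1)."""

    @pytest.mark.parametrize(
        "p1,p2,p3",
        [(0.2, 0.5, 0.7), (0.1, 0.3, 0.9), (0.5, 0.5, 0.5), (0.04, 0.62, 0.88)],
    )
    def test_symbolic_total(self, worked_example, p1, p2, p3):
        g, i, j = worked_example
        bank = injected_bank({1: p1, 2: p2, 3: p3})
        dec = sn_score(g, bank, i, j, "extended")
        assert dec.s0 == 1
        assert dec.s1 == pytest.approx(p2, abs=1e-12)
        assert dec.s2 == pytest.approx(p3 * p1, abs=1e-12)
        assert dec.total == pytest.approx(1 + p2 + p3 * p1, abs=1e-12)

    def test_simple_mode_is_the_count(self, worked_example):
        g, i, j = worked_example
        dec = sn_score(g, injected_bank({}), i, j, "simple")
        assert dec.total == dec.s0 == 1 and dec.s1 == dec.s2 == 0


def all_cross_kind_pairs(g):
    for category in CROSS_KIND_CATEGORIES:
        kind_a, kind_b = CATEGORY_KINDS[category]
        for i in g.nodes(kind_a):
            for j in g.nodes(kind_b):
                yield i, j


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,density", [(s, d) for s in range(5) for d in (0.08, 0.2)])
    def test_decomposition_matches_weight_matrix_brute_force(self, seed, density):
        g = random_tripartite(np.random.default_rng(seed), 7, 12, 7, density=density)
        bank = calibrate(g)
        for i, j in all_cross_kind_pairs(g):
            dec = sn_score(g, bank, i, j, "extended")
            s0, s1, s2 = brute_decomposition(g, bank, i, j)
            assert dec.s0 == s0
            assert dec.s1 == pytest.approx(s1, abs=1e-9)
            assert dec.s2 == pytest.approx(s2, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry(self, seed):
        g = random_tripartite(np.random.default_rng(seed))
        bank = calibrate(g)
        for i, j in itertools.islice(all_cross_kind_pairs(g), 120):
            a = sn_score(g, bank, i, j, "extended")
            b = sn_score(g, bank, j, i, "extended")
            assert (a.s0, a.s1, a.s2) == (b.s0, b.s1, b.s2)

    @pytest.mark.parametrize("seed", range(3))
    def test_zero_calibration_reduces_extended_to_simple(self, seed):
        g = random_tripartite(np.random.default_rng(seed))
        bank = CalibrationBank.zero()
        for i, j in all_cross_kind_pairs(g):
            ext = sn_score(g, bank, i, j, "extended")
            simple = sn_score(g, bank, i, j, "simple")
            assert ext.total == simple.total == ext.s0
            assert ext.s1 == ext.s2 == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_extended_dominates_simple(self, seed):
        g = random_tripartite(np.random.default_rng(seed))
        bank = calibrate(g)
        for i, j in all_cross_kind_pairs(g):
            ext = sn_score(g, bank, i, j, "extended")
            assert ext.s1 >= 0 and ext.s2 >= 0
            assert ext.total >= ext.s0


class TestLeaveOneOut:
    @pytest.mark.parametrize("seed", range(5))
    def test_equals_score_on_edge_deleted_graph(self, seed):
        g = random_tripartite(np.random.default_rng(seed), density=0.18)
        bank = calibrate(g)
        for e in g.edges():
            if e.category == LinkCategory.PROTEIN_PROTEIN:
                continue
            loo = sn_score(g, bank, e.u, e.v, "extended", leave_one_out=True)
            g2 = g.copy()
            g2.remove_edge(e.u, e.v)
            ref = sn_score(g2, bank, e.u, e.v, "extended", leave_one_out=False)
            assert (loo.s0, loo.s1, loo.s2) == (ref.s0, ref.s1, ref.s2)

    def test_graph_restored_after_loo(self, triangle_graph):
        g, n = triangle_graph
        bank = calibrate(g)
        before = {(e.u, e.v) for e in g.edges()}
        sn_score(g, bank, n["D1"], n["X1"], "extended", leave_one_out=True)
        assert {(e.u, e.v) for e in g.edges()} == before

    def test_narrow_reading_only_refreshes_second_order(self, triangle_graph):
        g, n = triangle_graph
        bank = injected_bank({1: 0.3, 2: 0.6})
        narrow = ScoringOptions(loo_all_terms=False)
        dec = sn_score(
            g, bank, n["D1"], n["X1"], "extended", leave_one_out=True, options=narrow
        )
        # s0 still sees the edge-intact graph (P1 bridges both endpoints)
        assert dec.s0 == 1


class TestFrozenCalibrationMonotonicity:
    def test_adding_a_bridge_edge_increases_the_total(self):
        # k is linked to i; adding k-j creates a new real-real bridge
        g = PharmGraph()
        i = make_node(NodeKind.DRUG, "i")
        j = make_node(NodeKind.DISEASE, "j")
        k = make_node(NodeKind.PROTEIN, "k")
        m = make_node(NodeKind.PROTEIN, "m")
        g.add_edge(i, m)
        g.add_edge(m, j)
        g.add_edge(i, k)
        bank = injected_bank({1: 0.2, 2: 0.5})
        before = sn_score(g, bank, i, j, "extended").total
        g.add_edge(k, j)
        after = sn_score(g, bank, i, j, "extended").total
        assert after > before


class TestScoreAllPairs:
    def test_empty_graph_empty_mapping(self):
        g = PharmGraph()
        out = score_all_pairs(g, CalibrationBank.zero(), LinkCategory.DRUG_DISEASE)
        assert out == {}

    def test_triangle_scores_one_drug_disease_pair(self, triangle_graph):
        g, n = triangle_graph
        bank = calibrate(g)
        out = score_all_pairs(g, bank, LinkCategory.DRUG_DISEASE)
        assert set(out) == {(n["D1"], n["X1"])}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pairwise_scoring(self, seed):
        g = random_tripartite(np.random.default_rng(seed), 7, 12, 7, density=0.15)
        bank = calibrate(g)
        batch = score_all_pairs(
            g, bank, LinkCategory.DRUG_DISEASE, leave_one_out_for_connected=True
        )
        # every scoreable pair is present ...
        for i in g.nodes(NodeKind.DRUG):
            for j in g.nodes(NodeKind.DISEASE):
                connected = g.has_edge(i, j)
                dec = sn_score(
                    g, bank, i, j, "extended", leave_one_out=connected
                )
                key = (i, j) if i <= j else (j, i)
                if dec.total > 0 or connected:
                    assert key in batch
                    got = batch[key]
                    assert (got.s0, got.s1, got.s2) == (dec.s0, dec.s1, dec.s2)
                else:
                    assert key not in batch


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_score_symmetry_property(seed):
    """score(i, j) == score(j, i) on random graphs (all modes)."""
    rng = np.random.default_rng(seed)
    g = random_tripartite(rng, 6, 9, 6, density=0.2)
    bank = calibrate(g)
    nodes = g.nodes()
    for _ in range(10):
        i, j = (nodes[t] for t in rng.integers(0, len(nodes), 2))
        if i == j or (i.kind == j.kind and i.kind != NodeKind.PROTEIN):
            continue
        for mode in ("simple", "extended"):
            a = sn_score(g, bank, i, j, mode)
            b = sn_score(g, bank, j, i, mode)
            assert (a.s0, a.s1, a.s2) == (b.s0, b.s1, b.s2)
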