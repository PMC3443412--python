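"""Shared fixtures: toy networks, random graphs, brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from snslink import (
    CalibrationBank,
    ConnectionProbability,
    LinkCategory,
    NodeId,
    NodeKind,
    PharmGraph,
    SharedCountTable,
    category_for_kinds,
)
from snslink.calibration import connection_probability
from snslink.graph_store import CROSS_KIND_CATEGORIES


def make_node(kind: NodeKind, value: str) -> NodeId:
    return NodeId(value, kind=kind)


def injected_bank(prob_by_n: dict) -> CalibrationBank:
    """CalibrationBank whose empirical P(n) equals the given exact ratios.

    prob_by_n maps shared count -> probability; probabilities are encoded
    as count rows (total=1000, connected=round(p*1000)) so the empirical
    ratio is exact for 3-decimal probabilities.
    """
    rows = {n: (1000, round(p * 1000)) for n, p in prob_by_n.items() if n >= 1}
    bank = CalibrationBank()
    for cat in CROSS_KIND_CATEGORIES:
        bank.tables[cat] = ConnectionProbability(
            SharedCountTable(cat, dict(rows)), None, policy="empirical"
        )
    return bank


@pytest.fixture
def triangle_graph():
    """D1-P1, P1-X1, D1-X1 plus an isolated drug D2."""
    g = PharmGraph()
    d1, d2 = make_node(NodeKind.DRUG, "D1"), make_node(NodeKind.DRUG, "D2")
    p1 = make_node(NodeKind.PROTEIN, "P1")
    x1 = make_node(NodeKind.DISEASE, "X1")
    g.add_edge(d1, p1)
    g.add_edge(p1, x1)
    g.add_edge(d1, x1)
    g.add_node(d2)
    return g, {"D1": d1, "D2": d2, "P1": p1, "X1": x1}


@pytest.fixture
def worked_example():
    """The five-node configuration of the scoring walkthrough.

    Pair (i, j) with bridges m (real-real), k (virtual i-k with shared
    count 2, real k-j) and l (virtual-virtual, shared counts 3 and 1).
    Helper nodes realize the inner shared counts without touching s_ij(0).
    """
    g = PharmGraph()
    i = make_node(NodeKind.DRUG, "i")
    j = make_node(NodeKind.DISEASE, "j")
    m = make_node(NodeKind.PROTEIN, "m")
    k = make_node(NodeKind.PROTEIN, "k")
    l = make_node(NodeKind.PROTEIN, "l")
    h = [make_node(NodeKind.DISEASE, f"h{t}") for t in range(1, 6)]
    g1 = make_node(NodeKind.DRUG, "g1")
    g.add_edge(i, m)
    g.add_edge(m, j)           # m: shared neighbor, s_ij(0) = 1
    g.add_edge(k, j)           # k-j real
    for hx in h[:2]:           # s_ik(0) = 2
        g.add_edge(i, hx)
        g.add_edge(k, hx)
    for hx in h[2:]:           # s_il(0) = 3
        g.add_edge(i, hx)
        g.add_edge(l, hx)
    g.add_edge(g1, l)          # s_lj(0) = 1 via drug g1
    g.add_edge(g1, j)
    return g, i, j


def random_tripartite(
    rng: np.random.Generator,
    n_drugs=8,
    n_proteins=14,
    n_diseases=8,
    density=0.15,
) -> PharmGraph:
    """Small random graph over all four categories (no planted structure)."""
    g = PharmGraph()
    drugs = [make_node(NodeKind.DRUG, f"D{i:02d}") for i in range(n_drugs)]
    prots = [make_node(NodeKind.PROTEIN, f"P{i:02d}") for i in range(n_proteins)]
    dis = [make_node(NodeKind.DISEASE, f"X{i:02d}") for i in range(n_diseases)]
    for node in itertools.chain(drugs, prots, dis):
        g.add_node(node)
    layers = [
        (drugs, prots),
        (prots, dis),
        (drugs, dis),
        (prots, prots),
    ]
    for left, right in layers:
        same = left is right
        for ai, a in enumerate(left):
            for b in right[ai + 1:] if same else right:
                if rng.random() < density:
                    g.add_edge(a, b)
    return g


# -- brute-force oracles ---------------------------------------------------


def brute_shared_count(g: PharmGraph, i: NodeId, j: NodeId) -> int:
    """Linear scan over every node: count those adjacent to both."""
    return sum(
        1 for k in g.nodes() if k not in (i, j) and g.has_edge(i, k) and g.has_edge(k, j)
    )


def brute_weight_matrix(g: PharmGraph, bank: CalibrationBank) -> dict:
    """Materialize W for every unordered node pair (the extended weights)."""
    nodes = g.nodes()
    w = {}
    for a, b in itertools.combinations(nodes, 2):
        if g.has_edge(a, b):
            w[(a, b)] = w[(b, a)] = 1.0
            continue
        cat = category_for_kinds(a.kind, b.kind)
        if cat is None:
            w[(a, b)] = w[(b, a)] = 0.0
            continue
        cp = bank.get(cat)
        val = connection_probability(cp, brute_shared_count(g, a, b))
        w[(a, b)] = w[(b, a)] = val
    return w


def brute_decomposition(g: PharmGraph, bank: CalibrationBank, i, j, loo=False, w=None):
    """(s0, s1, s2) by explicit sum over EVERY node k using the full
    weight matrix; independent of the production bridge-set pruning.
    Pass a precomputed ``w`` (from brute_weight_matrix) to amortize the
    matrix across many pairs of the same graph."""
    if loo and g.has_edge(i, j):
        g2 = g.copy()
        g2.remove_edge(i, j)
        return brute_decomposition(g2, bank, i, j, loo=False)
    if w is None:
        w = brute_weight_matrix(g, bank)
    s0, s1, s2 = 0, 0.0, 0.0
    for k in g.nodes():
        if k in (i, j):
            continue
        real_ik = g.has_edge(i, k)
        real_kj = g.has_edge(k, j)
        if real_ik and real_kj:
            s0 += 1
        elif real_ik or real_kj:
            s1 += w[(i, k)] * w[(k, j)]
        else:
            s2 += w[(i, k)] * w[(k, j)]
    return s0, s1, s2
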