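"""Shared-neighborhood scoring (simple and extended forms).

For a node pair (i, j) the score is S_ij = sum_k W_ik * W_kj over bridge
nodes k, where a real link has weight 1 and a virtual (absent) link between
x and y has weight P(s_xy(0)): the calibrated connection probability at the
pair's shared-neighbor count.  Expanding the product splits the score into

    s0 = sum_k a_ik a_kj                       (Shared Nodes Count)
    s1 = sum_k [a_ik P(s_kj) (1-a_kj) + a_kj P(s_ik) (1-a_ik)]
    s2 = sum_k P(s_ik) (1-a_ik) P(s_kj) (1-a_kj)

The simple algorithm scores by s0 alone; the extended algorithm by
s0 + s1 + s2.  For an existing link the score is computed leave-one-out:
the edge (i, j) is removed before any term (including the inner shared
counts) is evaluated, so the score never depends on the link's own
presence.

Although the total is a sum over individual bridges k, only bridges that
can carry nonzero weight on both sides matter: a bridge with no real link
to an endpoint needs a nonzero shared count with it (P(0) = 0).  The
implementation therefore restricts the sum to the 2-hop shared-neighbor
closure of both endpoints, which is exactly equivalent to summing over
every node in the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .calibration import CalibrationBank, connection_probability
from .errors import CalibrationMissingError, GraphValidationError
from .graph_store import (
    CATEGORY_KINDS,
    LinkCategory,
    NodeId,
    NodeKind,
    PharmGraph,
    category_for_kinds,
)

__all__ = [
    "ScoringOptions",
    "ScoreDecomposition",
    "shared_count",
    "link_weight",
    "sn_score",
    "score_all_pairs",
]


@dataclass(frozen=True)
class ScoringOptions:
    """Switches the scoring contract leaves open.

    bridge_kinds:
        Kinds allowed as shared neighbors (None = any kind, the default:
        the full heterogeneous neighborhood is what motivates working on
        the tripartite graph instead of a projection).
    loo_all_terms:
        Leave-one-out removes the scored edge before every term, including
        the inner shared counts (default).  False restricts the removal to
        nothing but the direct a_ij contribution paths, the narrower
        reading in which inner counts still see the edge.
    """

    bridge_kinds: Optional[frozenset] = None
    loo_all_terms: bool = True

    def allows(self, kind: NodeKind) -> bool:
        return self.bridge_kinds is None or kind in self.bridge_kinds


@dataclass
class ScoreDecomposition:
    """SN score of one pair split into 0th/1st/2nd-order terms."""

    pair: Tuple[NodeId, NodeId]
    s0: int
    s1: float
    s2: float
    mode: str
    leave_one_out: bool = False
    normalized: Optional[float] = None
    paths: list = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.s0 + self.s1 + self.s2


def shared_count(
    g: PharmGraph,
    i: NodeId,
    j: NodeId,
    options: ScoringOptions = ScoringOptions(),
) -> int:
    """Shared Nodes Count s_ij(0) = |N(i) ∩ N(j)| under the bridge policy.

    A direct i-j edge never contributes (a node is not its own neighbor).
    """
    if i == j:
        raise GraphValidationError("shared_count needs two distinct nodes")
    common = g.adjacency(i) & g.adjacency(j)
    if options.bridge_kinds is None:
        return len(common)
    return sum(1 for k in common if options.allows(k.kind))


def _virtual_weight(
    g: PharmGraph,
    bank: CalibrationBank,
    x: NodeId,
    y: NodeId,
    options: ScoringOptions,
) -> float:
    """P(s_xy(0)) for an absent link, 0 when no category exists for the pair."""
    category = category_for_kinds(x.kind, y.kind)
    if category is None:
        return 0.0
    cp = bank.get(category)
    return connection_probability(cp, shared_count(g, x, y, options))


def link_weight(
    g: PharmGraph,
    bank: CalibrationBank,
    i: NodeId,
    k: NodeId,
    options: ScoringOptions = ScoringOptions(),
) -> float:
    """W_ik: 1 for a real link, P(s_ik(0)) for a virtual one.

    Kind pairs with no link category (drug-drug, disease-disease) can never
    be connected and weigh 0.
    """
    if i == k:
        raise GraphValidationError("link_weight needs two distinct nodes")
    if g.has_edge(i, k):
        return 1.0
    return _virtual_weight(g, bank, i, k, options)


def _two_hop(g: PharmGraph, x: NodeId) -> set:
    """Nodes sharing at least one neighbor with x (candidates for s_xk >= 1)."""
    out = set()
    for u in g.adjacency(x):
        out |= g.adjacency(u)
    out.discard(x)
    return out


def sn_score(
    g: PharmGraph,
    bank: CalibrationBank,
    i: NodeId,
    j: NodeId,
    mode: str = "extended",
    leave_one_out: bool = False,
    options: ScoringOptions = ScoringOptions(),
    keep_paths: bool = False,
) -> ScoreDecomposition:
    """Score one pair; returns the s0/s1/s2 decomposition.

    mode "simple" returns the Shared Nodes Count only; "extended" adds the
    1st- and 2nd-order weighted terms and requires a calibration bank.
    With ``leave_one_out`` an existing edge (i, j) is removed for the whole
    computation and restored afterwards.
    """
    if mode not in ("simple", "extended"):
        raise ValueError(f"unknown mode {mode!r}")
    if i == j:
        raise GraphValidationError("cannot score a node against itself")
    g._require(i)
    g._require(j)

    if leave_one_out and g.has_edge(i, j):
        if options.loo_all_terms:
            g.remove_edge(i, j)
            try:
                return _score_pair(
                    g, bank, i, j, mode, leave_one_out, options, keep_paths
                )
            finally:
                g.add_edge(i, j)
        # narrow reading: only the 2nd-order term sees the edge removed
        intact = _score_pair(g, bank, i, j, mode, leave_one_out, options, keep_paths)
        if mode == "simple":
            return intact
        g.remove_edge(i, j)
        try:
            removed = _score_pair(
                g, bank, i, j, mode, leave_one_out, options, keep_paths
            )
        finally:
            g.add_edge(i, j)
        intact.s2 = removed.s2
        return intact
    return _score_pair(g, bank, i, j, mode, leave_one_out, options, keep_paths)


def _score_pair(g, bank, i, j, mode, leave_one_out, options, keep_paths):
    s0 = shared_count(g, i, j, options)
    if mode == "simple":
        dec = ScoreDecomposition((i, j), s0, 0.0, 0.0, "simple", leave_one_out)
        if keep_paths:
            dec.paths = [
                (k, 1.0, 1.0, "real-real")
                for k in sorted(g.adjacency(i) & g.adjacency(j))
                if options.allows(k.kind)
            ]
        return dec

    if not bank.tables:
        raise CalibrationMissingError("extended scoring requires a calibration bank")

    # Bridges with possibly-nonzero weight on both sides: a real link to the
    # endpoint, or >= 1 shared neighbor with it (otherwise P(0) = 0).
    near_i = g.adjacency(i) | _two_hop(g, i)
    near_j = g.adjacency(j) | _two_hop(g, j)
    candidates = (near_i & near_j) - {i, j}

    s0_check = 0
    s1 = 0.0
    s2 = 0.0
    paths = []
    for k in sorted(candidates):
        if not options.allows(k.kind):
            continue
        real_ik = g.has_edge(i, k)
        real_kj = g.has_edge(k, j)
        if real_ik and real_kj:
            s0_check += 1
            if keep_paths:
                paths.append((k, 1.0, 1.0, "real-real"))
            continue
        w_ik = 1.0 if real_ik else _virtual_weight(g, bank, i, k, options)
        w_kj = 1.0 if real_kj else _virtual_weight(g, bank, k, j, options)
        prod = w_ik * w_kj
        if prod == 0.0:
            continue
        if real_ik or real_kj:
            s1 += prod
            tag = "real-virtual" if real_ik else "virtual-real"
        else:
            s2 += prod
            tag = "virtual-virtual"
        if keep_paths:
            paths.append((k, w_ik, w_kj, tag))
    assert s0_check == s0
    dec = ScoreDecomposition((i, j), s0, s1, s2, "extended", leave_one_out)
    if keep_paths:
        dec.paths = paths
    return dec


def score_all_pairs(
    g: PharmGraph,
    bank: CalibrationBank,
    category: LinkCategory,
    mode: str = "extended",
    leave_one_out_for_connected: bool = False,
    options: ScoringOptions = ScoringOptions(),
) -> Dict[Tuple[NodeId, NodeId], ScoreDecomposition]:
    """Score every pair of the category that can have a nonzero score.

    Covers all connected pairs plus every unconnected pair reachable within
    three hops (the furthest a pair with a nonzero bridge product can be).
    Iteration order is deterministic (sorted node ids).
    """
    kind_a, kind_b = CATEGORY_KINDS[category]
    out: Dict[Tuple[NodeId, NodeId], ScoreDecomposition] = {}
    nodes_a = g.nodes(kind_a)
    for i in nodes_a:
        # A usable bridge k satisfies k in M(i) & M(j) where M(x) is the
        # real-or-shared-neighbor set N(x) | twohop(x); M is symmetric, so
        # candidate partners are the union of M(k) over k in M(i).
        frontier = g.adjacency(i) | _two_hop(g, i)
        frontier.discard(i)
        reach = set()
        for k in frontier:
            reach |= g.adjacency(k) | _two_hop(g, k)
        reach.discard(i)
        for j in sorted(n for n in reach if n.kind == kind_b):
            if category == LinkCategory.PROTEIN_PROTEIN and not (i < j):
                continue  # same-kind pairs: visit each unordered pair once
            key = (i, j) if i <= j else (j, i)
            if key in out:
                continue
            connected = g.has_edge(i, j)
            dec = sn_score(
                g, bank, i, j, mode,
                leave_one_out=leave_one_out_for_connected and connected,
                options=options,
            )
            if dec.total > 0.0 or connected:
                out[key] = dec
    return out
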