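"""Synthetic tripartite networks with planted shared-neighbor structure.

The generator is a latent-community (affiliation / stochastic-block-style)
model: every drug, protein and disease is assigned uniformly to one of
``n_modules`` communities, and each admissible pair is linked independently
with probability ``p_within`` inside a community and ``p_between`` across
communities.  Because co-membership simultaneously raises the chance of a
direct link and of common neighbors, connected pairs share more neighbors
than unconnected ones — the transitivity premise behind the ABC-style
shared-neighborhood prediction model.  An Erdős–Rényi null is obtained by
setting ``p_within == p_between``.

Drug–disease links are generated sparser than the other layers (the
``dd_scale`` factor, default 0.5) mirroring the relative scarcity of known
indication links compared to drug–target links in real pharmacological
databases; this is a shape choice, not a numeric target.

All randomness comes from one ``numpy.random.default_rng(seed)`` stream
consumed in a fixed documented order (module assignments by kind, then
edges by category in the order drug_protein, protein_disease, drug_disease,
protein_protein, pairs in sorted node order), so output is byte-identical
across runs and platforms for the same parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .errors import GraphValidationError, InsufficientDataError
from .graph_store import LinkCategory, NodeId, NodeKind, PharmGraph

__all__ = ["SynthParams", "HoldoutSplit", "generate", "split_links"]


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the planted-community tripartite generator."""

    n_drugs: int = 60
    n_proteins: int = 120
    n_diseases: int = 60
    n_modules: int = 6
    p_within: float = 0.25
    p_between: float = 0.01
    pp_within: float = 0.25
    pp_between: float = 0.01
    dd_scale: float = 0.5
    seed: int = 1

    def __post_init__(self):
        if min(self.n_drugs, self.n_proteins, self.n_diseases, self.n_modules) < 1:
            raise GraphValidationError("all node and module counts must be >= 1")
        if self.n_modules > min(self.n_drugs, self.n_proteins, self.n_diseases):
            raise GraphValidationError(
                "n_modules cannot exceed the smallest node-kind count"
            )
        for lo, hi in (
            (self.p_between, self.p_within),
            (self.pp_between, self.pp_within),
        ):
            if not (0.0 <= lo < hi <= 1.0) and not (lo == hi):
                raise GraphValidationError(
                    f"need 0 <= p_between <= p_within <= 1, got ({lo}, {hi})"
                )
        if not 0.0 < self.dd_scale <= 1.0:
            raise GraphValidationError("dd_scale must be in (0, 1]")

    def category_probs(self) -> Dict[LinkCategory, Tuple[float, float]]:
        """(p_within, p_between) effectively used per link category."""
        return {
            LinkCategory.DRUG_PROTEIN: (self.p_within, self.p_between),
            LinkCategory.PROTEIN_DISEASE: (self.p_within, self.p_between),
            LinkCategory.DRUG_DISEASE: (
                self.p_within * self.dd_scale,
                self.p_between * self.dd_scale,
            ),
            LinkCategory.PROTEIN_PROTEIN: (self.pp_within, self.pp_between),
        }


@dataclass
class HoldoutSplit:
    """Train graph plus held-out positives and sampled negative pairs."""

    train: PharmGraph
    positives: List[Tuple[NodeId, NodeId]]
    negatives: List[Tuple[NodeId, NodeId]]
    category: LinkCategory
    fraction: float
    seed: int


def _node_batch(kind: NodeKind, prefix: str, count: int) -> List[NodeId]:
    width = max(3, len(str(count)))
    return [NodeId(f"{prefix}{i:0{width}d}", kind=kind) for i in range(1, count + 1)]


def generate(params: SynthParams) -> Tuple[PharmGraph, Dict[NodeId, int]]:
    """Draw one network; returns (graph, ground-truth module assignment).

    Every node appears in the graph even when isolated, so pair totals in
    downstream calibration reflect the full node sets.
    """
    rng = np.random.default_rng(params.seed)
    drugs = _node_batch(NodeKind.DRUG, "D", params.n_drugs)
    proteins = _node_batch(NodeKind.PROTEIN, "P", params.n_proteins)
    diseases = _node_batch(NodeKind.DISEASE, "X", params.n_diseases)

    modules: Dict[NodeId, int] = {}
    for batch in (drugs, proteins, diseases):
        assignment = rng.integers(0, params.n_modules, size=len(batch))
        modules.update(zip(batch, (int(m) for m in assignment)))

    g = PharmGraph()
    for batch in (drugs, proteins, diseases):
        for node in batch:
            g.add_node(node)

    probs = params.category_probs()
    layers = [
        (LinkCategory.DRUG_PROTEIN, drugs, proteins),
        (LinkCategory.PROTEIN_DISEASE, proteins, diseases),
        (LinkCategory.DRUG_DISEASE, drugs, diseases),
        (LinkCategory.PROTEIN_PROTEIN, proteins, proteins),
    ]
    for category, left, right in layers:
        p_in, p_out = probs[category]
        same_kind = left is right
        draws = rng.random(
            (len(left) * (len(left) - 1)) // 2 if same_kind else len(left) * len(right)
        )
        pos = 0
        for ai, a in enumerate(left):
            partners = right[ai + 1:] if same_kind else right
            for b in partners:
                p = p_in if modules[a] == modules[b] else p_out
                if draws[pos] < p:
                    g.add_edge(a, b, source_tag="synth")
                pos += 1
    return g, modules


def split_links(
    g: PharmGraph,
    category: LinkCategory,
    fraction: float,
    negatives_per_positive: int = 1,
    seed: int = 0,
) -> HoldoutSplit:
    """Hold out ceil(fraction * E) random edges of one category.

    Positives are removed from a copy of ``g``; negatives are sampled from
    pairs unconnected in the ORIGINAL graph.  Deterministic by seed.
    """
    if not 0.0 < fraction < 1.0:
        raise GraphValidationError("fraction must be in (0, 1)")
    edges = [(e.u, e.v) for e in g.edges(category)]
    if len(edges) < 10:
        raise InsufficientDataError(
            f"category {category.value} has {len(edges)} edges, need >= 10"
        )
    rng = np.random.default_rng(seed)
    n_hold = math.ceil(fraction * len(edges))
    idx = rng.choice(len(edges), size=n_hold, replace=False)
    positives = sorted(edges[k] for k in idx)

    train = g.copy()
    for u, v in positives:
        train.remove_edge(u, v)

    from .evaluation import sample_negatives  # local import avoids a cycle

    negatives = sample_negatives(
        g, category, size=negatives_per_positive * n_hold, seed=seed
    )
    return HoldoutSplit(train, positives, negatives, category, fraction, seed)
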