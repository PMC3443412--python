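"""Typed tripartite-network data model with edge-list I/O.

The pharmacological network is an undirected simple graph over three node
kinds (drug, protein, disease) and four link categories (drug-protein,
protein-disease, drug-disease, protein-protein).  Node identity is the pair
(namespace, value): PubChem CIDs for drugs, Entrez GeneIDs for proteins and
MeSH descriptor IDs for diseases, plus a ``synthetic`` namespace for
generated networks so simulated nodes never masquerade as real ontology IDs.

The canonical on-disk format is a TSV edge list with header columns
``source_id, source_kind, target_id, target_kind`` and an optional
``source_tag`` provenance column.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx

from .errors import (
    EdgeListParseError,
    GraphValidationError,
    NodeLookupError,
)

__all__ = [
    "NodeKind",
    "Namespace",
    "LinkCategory",
    "NodeId",
    "Edge",
    "PharmGraph",
    "category_for_kinds",
    "load_edge_list",
    "write_edge_list",
    "write_sif",
    "load_id_list",
]


class NodeKind(str, Enum):
    DRUG = "drug"
    PROTEIN = "protein"
    DISEASE = "disease"


class Namespace(str, Enum):
    PUBCHEM_CID = "pubchem_cid"
    ENTREZ_GENE = "entrez_gene"
    MESH_DESCRIPTOR = "mesh_descriptor"
    SYNTHETIC = "synthetic"


#: namespaces whose node kind is implied
_NAMESPACE_KIND = {
    Namespace.PUBCHEM_CID: NodeKind.DRUG,
    Namespace.ENTREZ_GENE: NodeKind.PROTEIN,
    Namespace.MESH_DESCRIPTOR: NodeKind.DISEASE,
}


class LinkCategory(str, Enum):
    DRUG_PROTEIN = "drug_protein"
    PROTEIN_DISEASE = "protein_disease"
    DRUG_DISEASE = "drug_disease"
    PROTEIN_PROTEIN = "protein_protein"


#: unordered kind pair -> category; drug-drug and disease-disease do not exist
_KIND_PAIR_CATEGORY = {
    frozenset({NodeKind.DRUG, NodeKind.PROTEIN}): LinkCategory.DRUG_PROTEIN,
    frozenset({NodeKind.PROTEIN, NodeKind.DISEASE}): LinkCategory.PROTEIN_DISEASE,
    frozenset({NodeKind.DRUG, NodeKind.DISEASE}): LinkCategory.DRUG_DISEASE,
    frozenset({NodeKind.PROTEIN}): LinkCategory.PROTEIN_PROTEIN,
}

#: the two kinds of every category's endpoints (protein_protein repeats)
CATEGORY_KINDS = {
    LinkCategory.DRUG_PROTEIN: (NodeKind.DRUG, NodeKind.PROTEIN),
    LinkCategory.PROTEIN_DISEASE: (NodeKind.PROTEIN, NodeKind.DISEASE),
    LinkCategory.DRUG_DISEASE: (NodeKind.DRUG, NodeKind.DISEASE),
    LinkCategory.PROTEIN_PROTEIN: (NodeKind.PROTEIN, NodeKind.PROTEIN),
}

#: the three cross-kind categories that get their own calibration
CROSS_KIND_CATEGORIES = (
    LinkCategory.DRUG_PROTEIN,
    LinkCategory.DRUG_DISEASE,
    LinkCategory.PROTEIN_DISEASE,
)


def category_for_kinds(a: NodeKind, b: NodeKind) -> Optional[LinkCategory]:
    """Category of an (unordered) kind pair, or None for forbidden pairs.

    Drug-drug and disease-disease pairs have no category: such links cannot
    exist in the network and virtual links between them carry weight zero.
    """
    return _KIND_PAIR_CATEGORY.get(frozenset({a, b}))


@dataclass(frozen=True, order=True)
class NodeId:
    """Typed node identifier; identity is (namespace, value).

    Ordering is by (value, namespace, kind) so that "lexicographic node
    value" tie-breaks are well defined.
    """

    value: str
    namespace: Namespace = Namespace.SYNTHETIC
    kind: NodeKind = field(default=None, compare=True)  # type: ignore[assignment]

    def __post_init__(self):
        if not self.value or any(c.isspace() for c in self.value):
            raise GraphValidationError(
                f"node value must be non-empty without whitespace: {self.value!r}"
            )
        implied = _NAMESPACE_KIND.get(self.namespace)
        if implied is not None:
            if self.kind is not None and self.kind != implied:
                raise GraphValidationError(
                    f"namespace {self.namespace.value} implies kind {implied.value}, "
                    f"got {self.kind}"
                )
            object.__setattr__(self, "kind", implied)
        elif self.kind is None:
            raise GraphValidationError(
                "synthetic nodes must declare their kind explicitly"
            )
        elif not isinstance(self.kind, NodeKind):
            object.__setattr__(self, "kind", NodeKind(self.kind))

    @classmethod
    def drug(cls, value: str) -> "NodeId":
        return cls(value, Namespace.SYNTHETIC, NodeKind.DRUG)

    @classmethod
    def protein(cls, value: str) -> "NodeId":
        return cls(value, Namespace.SYNTHETIC, NodeKind.PROTEIN)

    @classmethod
    def disease(cls, value: str) -> "NodeId":
        return cls(value, Namespace.SYNTHETIC, NodeKind.DISEASE)

    def __repr__(self):
        return f"{self.kind.value}:{self.value}"


@dataclass(frozen=True)
class Edge:
    u: NodeId
    v: NodeId
    category: LinkCategory
    source_tags: frozenset = frozenset()

    def __post_init__(self):
        if self.u == self.v:
            raise GraphValidationError(f"self-loop on {self.u}")
        expected = category_for_kinds(self.u.kind, self.v.kind)
        if expected is None:
            raise GraphValidationError(
                f"no link category exists between kinds "
                f"{self.u.kind.value} and {self.v.kind.value}"
            )
        if expected != self.category:
            raise GraphValidationError(
                f"category {self.category.value} does not match endpoint kinds "
                f"({self.u.kind.value}, {self.v.kind.value})"
            )


class PharmGraph:
    """Undirected simple heterogeneous graph over drugs, proteins, diseases.

    Thin typed wrapper around :class:`networkx.Graph`; at most one edge per
    unordered pair, category derived from endpoint kinds, multi-source edges
    collapsed with a union of provenance tags.
    """

    def __init__(self):
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node: NodeId) -> None:
        self._g.add_node(node)

    def add_edge(
        self,
        u: NodeId,
        v: NodeId,
        source_tag: Optional[str] = None,
    ) -> LinkCategory:
        """Add (or merge into) the undirected edge u-v.

        The category is derived from the endpoint kinds; a kind pair with no
        category (drug-drug, disease-disease) raises GraphValidationError.
        """
        if u == v:
            raise GraphValidationError(f"self-loop on {u}")
        category = category_for_kinds(u.kind, v.kind)
        if category is None:
            raise GraphValidationError(
                f"no link category exists between kinds "
                f"{u.kind.value} and {v.kind.value} ({u!r}, {v!r})"
            )
        if self._g.has_edge(u, v):
            if source_tag:
                self._g.edges[u, v]["tags"] = self._g.edges[u, v]["tags"] | {source_tag}
        else:
            tags = frozenset({source_tag}) if source_tag else frozenset()
            self._g.add_edge(u, v, category=category, tags=tags)
        return category

    def remove_edge(self, u: NodeId, v: NodeId) -> None:
        if not self._g.has_edge(u, v):
            raise NodeLookupError(f"no edge {u!r}-{v!r}")
        self._g.remove_edge(u, v)

    def copy(self) -> "PharmGraph":
        out = PharmGraph()
        out._g = self._g.copy()
        return out

    # -- queries ----------------------------------------------------------

    def __contains__(self, node: NodeId) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes(self, kind: Optional[NodeKind] = None) -> list:
        """Sorted node list, optionally restricted to one kind."""
        if kind is None:
            return sorted(self._g.nodes)
        return sorted(n for n in self._g.nodes if n.kind == kind)

    def edges(self, category: Optional[LinkCategory] = None) -> list:
        """Sorted Edge records, optionally restricted to one category."""
        out = []
        for u, v, data in self._g.edges(data=True):
            if category is not None and data["category"] != category:
                continue
            a, b = sorted((u, v))
            out.append(Edge(a, b, data["category"], data["tags"]))
        out.sort(key=lambda e: (e.u, e.v))
        return out

    def edge_counts(self) -> dict:
        """Number of edges per link category."""
        counts = {c: 0 for c in LinkCategory}
        for _, _, data in self._g.edges(data=True):
            counts[data["category"]] += 1
        return counts

    def has_edge(self, u: NodeId, v: NodeId) -> bool:
        return self._g.has_edge(u, v)

    def degree(self, node: NodeId) -> int:
        self._require(node)
        return self._g.degree[node]

    def neighbors(
        self, node: NodeId, kinds: Optional[Iterable[NodeKind]] = None
    ) -> set:
        """Set of nodes adjacent to ``node``, optionally filtered by kind."""
        self._require(node)
        if kinds is None:
            return set(self._g.adj[node])
        kindset = set(kinds)
        return {n for n in self._g.adj[node] if n.kind in kindset}

    def adjacency(self, node: NodeId):
        """Set-like view of the neighbors of ``node`` (no copy)."""
        return self._g.adj[node].keys()

    def shortest_path(self, i: NodeId, j: NodeId) -> Optional[list]:
        """Minimum-hop path from i to j, or None if disconnected.

        Among equally short paths the lexicographically smallest node-value
        sequence is returned, so the result is deterministic.
        """
        self._require(i)
        self._require(j)
        if i == j:
            return [i]
        # BFS distances from j, then walk greedily from i picking the
        # smallest neighbor that moves strictly closer to j.
        dist = {j: 0}
        queue = deque([j])
        while queue:
            cur = queue.popleft()
            for nbr in self._g.adj[cur]:
                if nbr not in dist:
                    dist[nbr] = dist[cur] + 1
                    queue.append(nbr)
        if i not in dist:
            return None
        path = [i]
        cur = i
        while cur != j:
            cur = min(n for n in self._g.adj[cur] if dist.get(n, -1) == dist[cur] - 1)
            path.append(cur)
        return path

    def to_networkx(self) -> nx.Graph:
        """A copy of the underlying networkx graph (for interop/plots)."""
        return self._g.copy()

    def _require(self, node: NodeId) -> None:
        if node not in self._g:
            raise NodeLookupError(f"unknown node {node!r}")

    def __eq__(self, other):
        if not isinstance(other, PharmGraph):
            return NotImplemented
        return set(self._g.nodes) == set(other._g.nodes) and {
            (min(u, v), max(u, v), d["category"]) for u, v, d in self._g.edges(data=True)
        } == {
            (min(u, v), max(u, v), d["category"])
            for u, v, d in other._g.edges(data=True)
        }


# -- edge-list I/O ---------------------------------------------------------

_HEADER = ["source_id", "source_kind", "target_id", "target_kind", "source_tag"]


def _parse_node(
    value: str, kind: str, namespace_policy: str, line_number: int
) -> NodeId:
    try:
        node_kind = NodeKind(kind)
    except ValueError:
        raise EdgeListParseError(line_number, f"unknown node kind {kind!r}") from None
    if namespace_policy == "ontology":
        ns = {
            NodeKind.DRUG: Namespace.PUBCHEM_CID,
            NodeKind.PROTEIN: Namespace.ENTREZ_GENE,
            NodeKind.DISEASE: Namespace.MESH_DESCRIPTOR,
        }[node_kind]
    else:
        ns = Namespace.SYNTHETIC
    try:
        return NodeId(value, ns, node_kind)
    except GraphValidationError as exc:
        raise EdgeListParseError(line_number, str(exc)) from None


def load_edge_list(
    path: Union[str, Path], namespace_policy: str = "synthetic"
) -> PharmGraph:
    """Read a TSV edge list into a PharmGraph.

    Parameters
    ----------
    path:
        TSV file with header ``source_id source_kind target_id target_kind``
        and optional ``source_tag``.
    namespace_policy:
        ``"synthetic"`` (default) puts every node in the synthetic namespace;
        ``"ontology"`` assigns pubchem_cid / entrez_gene / mesh_descriptor by
        kind.

    Duplicate rows collapse to one edge (tags merged); row order never
    affects the result.  Malformed rows raise EdgeListParseError with the
    line number; forbidden kind pairs raise GraphValidationError.
    """
    g = PharmGraph()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise EdgeListParseError(1, "empty file, expected header") from None
        if [h.strip() for h in header[:4]] != _HEADER[:4]:
            raise EdgeListParseError(
                1, f"bad header {header!r}, expected {_HEADER[:4]} [+ source_tag]"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 4:
                raise EdgeListParseError(lineno, f"expected >=4 columns, got {len(row)}")
            u = _parse_node(row[0].strip(), row[1].strip(), namespace_policy, lineno)
            if not row[2].strip() and not row[3].strip():
                g.add_node(u)  # node-only row (isolated node)
                continue
            v = _parse_node(row[2].strip(), row[3].strip(), namespace_policy, lineno)
            tag = row[4].strip() if len(row) > 4 and row[4].strip() else None
            g.add_edge(u, v, source_tag=tag)
    return g


def write_edge_list(g: PharmGraph, path: Union[str, Path]) -> None:
    """Write the canonical TSV edge list (stable sort order, round-trips).

    Isolated nodes are preserved as node-only rows with empty target
    columns so that write-then-load reproduces the node set exactly.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for e in g.edges():
            writer.writerow(
                [
                    e.u.value,
                    e.u.kind.value,
                    e.v.value,
                    e.v.kind.value,
                    ";".join(sorted(e.source_tags)),
                ]
            )
        for node in g.nodes():
            if g.degree(node) == 0:
                writer.writerow([node.value, node.kind.value, "", "", ""])


def write_sif(g: PharmGraph, path: Union[str, Path]) -> None:
    """SIF-style export (node <TAB> category <TAB> node) for visualization."""
    with open(path, "w", newline="") as fh:
        for e in g.edges():
            fh.write(f"{e.u.value}\t{e.category.value}\t{e.v.value}\n")


def load_id_list(
    path: Union[str, Path],
    kind: NodeKind = NodeKind.DRUG,
    namespace: Namespace = Namespace.SYNTHETIC,
) -> set:
    """Plain-text identifier list (one per line) -> set of NodeId.

    Used for the approved-drug filter list; blank lines and ``#`` comments
    are ignored.
    """
    out = set()
    with open(path) as fh:
        for line in fh:
            value = line.strip()
            if not value or value.startswith("#"):
                continue
            out.add(NodeId(value, namespace, kind))
    return out
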