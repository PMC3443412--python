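"""Drug-repositioning candidate selection on a scored tripartite network.

Given a query disease (and the broader disease class it belongs to), drugs
are ranked by their extended shared-neighborhood score against the query
and kept only when all four selection criteria hold:

1. the score exceeds a threshold while the Shared Nodes Count satisfies a
   constraint (default: exactly zero — the pair must be supported purely by
   indirect 1st/2nd-order evidence, so the proposed indication is genuinely
   novel);
2. the drug is on the approved-drug list;
3. the drug has no existing indication link to ANY disease of the class
   (it is not already a drug for this disease family);
4. the drug is directly linked to at least one protein associated with the
   disease class (a plausible target connects them).

Each surviving candidate carries its supporting bridge paths so the
prediction can be explained and audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

from .calibration import CalibrationBank, LogisticParams
from .errors import GraphValidationError, NodeLookupError
from .graph_store import NodeId, NodeKind, PharmGraph
from .sns_core import ScoringOptions, sn_score

__all__ = [
    "DiseaseQuery",
    "FilterConfig",
    "CandidateRecord",
    "class_proteins",
    "find_candidates",
    "explain_candidate",
    "audit_record",
]


@dataclass(frozen=True)
class DiseaseQuery:
    """Query disease node(s) plus the broader disease class around them."""

    diseases: Tuple[NodeId, ...]
    disease_class: Tuple[NodeId, ...]

    def __init__(self, diseases: Iterable[NodeId], disease_class: Iterable[NodeId]):
        diseases = tuple(diseases)
        disease_class = tuple(disease_class)
        for node in (*diseases, *disease_class):
            if node.kind != NodeKind.DISEASE:
                raise GraphValidationError(f"{node!r} is not a disease node")
        if not diseases:
            raise GraphValidationError("query needs at least one disease node")
        object.__setattr__(self, "diseases", diseases)
        object.__setattr__(self, "disease_class", disease_class)


@dataclass(frozen=True)
class FilterConfig:
    """Candidate-filter parameters.

    threshold:
        Minimum score (strict) for criterion 1; default 0.004.
    score_space:
        ``"normalized"`` applies the threshold to the logistic-normalized
        score (requires a normalizer); ``"raw"`` to the raw SN score.
    shared_count_max:
        Criterion 1's Shared Nodes Count constraint, ``s0 <= k`` with the
        default k = 0 (exact "count zero" novelty requirement).
    """

    threshold: float = 0.004
    score_space: str = "normalized"
    shared_count_max: int = 0

    def __post_init__(self):
        if self.score_space not in ("normalized", "raw"):
            raise ValueError(f"unknown score space {self.score_space!r}")


@dataclass
class CandidateRecord:
    drug: NodeId
    disease: NodeId
    score: float
    normalized: Optional[float]
    shared_count: int
    approved: bool
    novel_indication: bool
    target_linked: bool
    supporting_paths: List[Tuple[NodeId, float, float, str]]
    targets_in_class: List[NodeId] = field(default_factory=list)


def class_proteins(g: PharmGraph, query: DiseaseQuery) -> set:
    """Proteins with a direct protein-disease link to any class disease."""
    out = set()
    for disease in query.disease_class:
        if disease not in g:
            raise NodeLookupError(f"unknown disease node {disease!r}")
        out |= g.neighbors(disease, kinds=[NodeKind.PROTEIN])
    return out


def find_candidates(
    g: PharmGraph,
    bank: CalibrationBank,
    query: DiseaseQuery,
    approved: Iterable[NodeId],
    cfg: FilterConfig = FilterConfig(),
    normalizer: Optional[LogisticParams] = None,
    options: ScoringOptions = ScoringOptions(),
) -> List[CandidateRecord]:
    """Rank drugs against the query disease(s) and apply the four filters.

    Only drugs with no existing link to the query disease are considered
    (the pair must be a prediction, not a lookup).  Records are ranked by
    the thresholded score, descending, ties broken by drug id.
    """
    approved = set(approved)
    if not approved:
        import warnings

        warnings.warn("empty approved-drug list: no candidate can pass criterion 2")
    if cfg.score_space == "normalized" and normalizer is None:
        raise GraphValidationError(
            "score_space='normalized' requires a fitted score normalizer"
        )
    targets = class_proteins(g, query)
    class_set = set(query.disease_class)

    records: List[CandidateRecord] = []
    for disease in query.diseases:
        if disease not in g:
            raise NodeLookupError(f"unknown disease node {disease!r}")
        for drug in g.nodes(NodeKind.DRUG):
            if g.has_edge(drug, disease):
                continue
            dec = sn_score(
                g, bank, drug, disease, "extended",
                leave_one_out=False, options=options, keep_paths=True,
            )
            normalized = normalizer(dec.total) if normalizer is not None else None
            gate = normalized if cfg.score_space == "normalized" else dec.total
            drug_targets = sorted(g.neighbors(drug, kinds=[NodeKind.PROTEIN]) & targets)
            record = CandidateRecord(
                drug=drug,
                disease=disease,
                score=dec.total,
                normalized=normalized,
                shared_count=dec.s0,
                approved=drug in approved,
                novel_indication=not any(
                    g.has_edge(drug, d) for d in class_set
                ),
                target_linked=bool(drug_targets),
                supporting_paths=dec.paths,
                targets_in_class=drug_targets,
            )
            passes_score = gate > cfg.threshold and dec.s0 <= cfg.shared_count_max
            if (
                passes_score
                and record.approved
                and record.novel_indication
                and record.target_linked
            ):
                records.append(record)
    key_score = (lambda r: r.normalized) if cfg.score_space == "normalized" else (
        lambda r: r.score
    )
    records.sort(key=lambda r: (-key_score(r), r.drug, r.disease))
    return records


def audit_record(
    g: PharmGraph,
    record: CandidateRecord,
    query: DiseaseQuery,
    approved: Iterable[NodeId],
    cfg: FilterConfig = FilterConfig(),
) -> bool:
    """Independent re-check that a record passes all four criteria."""
    gate = record.normalized if cfg.score_space == "normalized" else record.score
    crit1 = gate > cfg.threshold and record.shared_count <= cfg.shared_count_max
    crit2 = record.drug in set(approved)
    crit3 = not any(g.has_edge(record.drug, d) for d in query.disease_class)
    crit4 = any(
        g.has_edge(record.drug, p) for p in class_proteins(g, query)
    )
    return bool(crit1 and crit2 and crit3 and crit4)


def explain_candidate(record: CandidateRecord) -> str:
    """Human-readable bridge-path table; products sum to the total score."""
    lines = [
        f"candidate {record.drug!r} -> {record.disease!r}  "
        f"score={record.score:.6g}  shared_count={record.shared_count}",
        f"{'bridge':<20}{'w(drug,k)':>12}{'w(k,disease)':>14}{'product':>12}  kind",
    ]
    order = {"real-real": 0, "real-virtual": 1, "virtual-real": 1, "virtual-virtual": 2}
    total = 0.0
    for k, w1, w2, tag in sorted(
        record.supporting_paths, key=lambda p: (order[p[3]], p[0])
    ):
        product = w1 * w2
        total += product
        lines.append(f"{k!r:<20}{w1:>12.4g}{w2:>14.4g}{product:>12.4g}  {tag}")
    lines.append(f"{'sum of path products':<46}{total:>12.6g}")
    return "\n".join(lines)


def path_product_total(record: CandidateRecord) -> float:
    """Sum of per-path weight products (equals the score total)."""
    return sum(w1 * w2 for _, w1, w2, _ in record.supporting_paths)
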