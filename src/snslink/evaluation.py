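"""Evaluation protocol: shared-count distribution comparison and ROC.

Two checks mirror the standard validation of shared-neighborhood scoring:

* a two-sample Kolmogorov–Smirnov comparison of the shared-neighbor-count
  distributions of connected versus unconnected pairs (connected pairs
  should share more neighbors), and
* leave-one-out ROC analysis comparing the simple algorithm (Shared Nodes
  Count only) with the extended algorithm (count plus weighted indirect
  terms), with AUC computed by the Mann–Whitney rank statistic using
  midranks for ties — ties are abundant in simple mode, where scores are
  small integers, so the tie convention is observable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .calibration import CalibrationBank
from .errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    SampleSizeError,
)
from .graph_store import CATEGORY_KINDS, LinkCategory, NodeId, PharmGraph
from .sns_core import ScoringOptions, shared_count, sn_score

__all__ = [
    "KsResult",
    "RocResult",
    "ks_compare",
    "sample_negatives",
    "roc_auc",
    "compare_simple_extended",
]


@dataclass
class KsResult:
    category: LinkCategory
    statistic: float
    p_value: float           # two-sided
    p_value_one_sided: float  # H1: connected counts stochastically larger
    n_connected: int
    n_unconnected: int


@dataclass
class RocResult:
    category: Optional[LinkCategory]
    mode: str
    auc: float
    curve: List[Tuple[float, float]]  # (fpr, tpr), from (0,0) to (1,1)
    n_pos: int
    n_neg: int
    seed: Optional[int] = None


def sample_negatives(
    g: PharmGraph,
    category: LinkCategory,
    size: int,
    seed: int = 0,
    exclude: Optional[Iterable[Tuple[NodeId, NodeId]]] = None,
) -> List[Tuple[NodeId, NodeId]]:
    """Uniform sample without replacement of unconnected cross-kind pairs.

    ``exclude`` removes extra pairs (e.g. held-out positives) from the
    population.  Raises SampleSizeError when the population is too small.
    """
    kind_a, kind_b = CATEGORY_KINDS[category]
    nodes_a = g.nodes(kind_a)
    nodes_b = g.nodes(kind_b)
    excluded = set()
    if exclude is not None:
        for u, v in exclude:
            excluded.add((u, v) if u <= v else (v, u))

    def norm(i, j):
        return (i, j) if i <= j else (j, i)

    same_kind = kind_a == kind_b
    if same_kind:
        population = len(nodes_a) * (len(nodes_a) - 1) // 2
    else:
        population = len(nodes_a) * len(nodes_b)
    n_connected = g.edge_counts()[category]
    available = population - n_connected - len(excluded)
    if size > available:
        raise SampleSizeError(
            f"requested {size} negatives, only {available} unconnected "
            f"{category.value} pairs available"
        )

    rng = np.random.default_rng(seed)
    # Rejection sampling is fast while the population is mostly unconnected;
    # fall back to full enumeration when it is not.
    if size <= 0.5 * available and n_connected + len(excluded) < 0.9 * population:
        chosen: Dict[Tuple[NodeId, NodeId], None] = {}
        na, nb = len(nodes_a), len(nodes_b)
        while len(chosen) < size:
            want = size - len(chosen)
            ii = rng.integers(0, na, size=2 * want + 8)
            jj = rng.integers(0, nb, size=2 * want + 8)
            for ai, bj in zip(ii, jj):
                i, j = nodes_a[ai], nodes_b[bj]
                if i == j:
                    continue
                key = norm(i, j)
                if key in chosen or key in excluded or g.has_edge(i, j):
                    continue
                chosen[key] = None
                if len(chosen) == size:
                    break
        return list(chosen)

    pool = []
    for ai, i in enumerate(nodes_a):
        partners = nodes_b[ai + 1:] if same_kind else nodes_b
        for j in partners:
            key = norm(i, j)
            if key not in excluded and not g.has_edge(i, j):
                pool.append(key)
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[k] for k in idx]


def ks_compare(
    g: PharmGraph,
    category: LinkCategory,
    negative_sample_size: int = 1000,
    seed: int = 0,
    options: ScoringOptions = ScoringOptions(),
) -> KsResult:
    """KS test of shared-count distributions, connected vs unconnected pairs.

    All connected pairs of the category are used; unconnected pairs are a
    seeded uniform sample.  Reports the two-sided p-value alongside the
    one-sided test in the direction "connected counts stochastically
    larger".
    """
    edges = [(e.u, e.v) for e in g.edges(category)]
    if not edges:
        raise InsufficientDataError(f"no connected {category.value} pairs")
    negatives = sample_negatives(g, category, negative_sample_size, seed=seed)
    conn = np.array([shared_count(g, u, v, options) for u, v in edges], dtype=float)
    unconn = np.array(
        [shared_count(g, u, v, options) for u, v in negatives], dtype=float
    )
    method = "asymp" if min(len(conn), len(unconn)) > 100 else "auto"
    two = stats.ks_2samp(conn, unconn, alternative="two-sided", method=method)
    # alternative="less": CDF of the first sample lies below the second's,
    # i.e. connected counts are stochastically larger.
    one = stats.ks_2samp(conn, unconn, alternative="less", method=method)
    return KsResult(
        category,
        float(two.statistic),
        float(two.pvalue),
        float(one.pvalue),
        len(conn),
        len(unconn),
    )


def roc_auc(
    scored: Sequence[Tuple[float, bool]],
    category: Optional[LinkCategory] = None,
    mode: str = "",
    seed: Optional[int] = None,
) -> RocResult:
    """ROC from (score, label) pairs.

    AUC is the Mann–Whitney rank statistic with midranks for ties; the
    curve is a threshold sweep over distinct score values and its
    trapezoidal area equals the rank AUC exactly.
    """
    scores = np.array([s for s, _ in scored], dtype=float)
    labels = np.array([bool(l) for _, l in scored])
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"need both classes, got {n_pos} positives / {n_neg} negatives"
        )
    ranks = stats.rankdata(scores)  # midranks for ties
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # threshold sweep, descending distinct scores; ties move diagonally
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(scores) - 1]
    curve = [(0.0, 0.0)] + [
        (fps[k] / n_neg, tps[k] / n_pos) for k in distinct
    ]
    return RocResult(category, mode, float(auc), curve, n_pos, n_neg, seed)


def compare_simple_extended(
    g: PharmGraph,
    bank: CalibrationBank,
    category: LinkCategory,
    seed: int = 0,
    max_positives: int = 50000,
    options: ScoringOptions = ScoringOptions(),
) -> Tuple[RocResult, RocResult, float]:
    """Leave-one-out ROC of the simple vs extended algorithm.

    Positives are the category's existing links, scored leave-one-out;
    negatives an equal-size seeded sample of unconnected pairs scored on
    the intact graph.  Both modes score the identical pair sets.  Returns
    (simple, extended, improvement %) where improvement is the relative
    AUC gain of the extended algorithm.
    """
    edges = [(e.u, e.v) for e in g.edges(category)]
    if not edges:
        raise InsufficientDataError(f"no {category.value} links to evaluate")
    if len(edges) > max_positives:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(edges), size=max_positives, replace=False)
        edges = [edges[k] for k in sorted(idx)]
    negatives = sample_negatives(g, category, len(edges), seed=seed)

    scored = {"simple": [], "extended": []}
    for mode in ("simple", "extended"):
        for u, v in edges:
            dec = sn_score(g, bank, u, v, mode, leave_one_out=True, options=options)
            scored[mode].append((dec.total, True))
        for u, v in negatives:
            dec = sn_score(g, bank, u, v, mode, leave_one_out=False, options=options)
            scored[mode].append((dec.total, False))

    simple = roc_auc(scored["simple"], category, "simple", seed)
    extended = roc_auc(scored["extended"], category, "extended", seed)
    improvement = (extended.auc - simple.auc) / simple.auc * 100.0
    return simple, extended, improvement
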