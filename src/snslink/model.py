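"""Model-style front end for shared-neighborhood link prediction.

``SharedNeighborhoodModel`` is constructed from a network (or an edge-list
DataFrame), and ``fit()`` performs the calibration step — estimating the
per-category empirical connection probabilities P(n) and their logistic
connecting-probability functions — returning an ``SNSResults`` object that
carries the fitted parameters with diagnostics and exposes scoring,
evaluation and candidate search.

    >>> model = SharedNeighborhoodModel(graph)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.score(drug, disease).total
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .calibration import CalibrationBank, calibrate, calibrate_score_normalizer
from .errors import CalibrationFitError
from .graph_store import (
    LinkCategory,
    NodeId,
    NodeKind,
    PharmGraph,
)
from .sns_core import ScoringOptions, score_all_pairs, sn_score
from .evaluation import compare_simple_extended, ks_compare

__all__ = ["SharedNeighborhoodModel", "SNSResults"]


class SharedNeighborhoodModel:
    """Shared-neighborhood scoring model over a tripartite network.

    Parameters
    ----------
    graph:
        The drug-protein-disease network.
    policy:
        How P(n) is evaluated after fitting: "hybrid" (empirical where
        observed, fitted elsewhere — default), "empirical", or "fitted".
    bridge_kinds:
        Optional restriction of which node kinds count as shared neighbors.
    """

    def __init__(
        self,
        graph: PharmGraph,
        policy: str = "hybrid",
        bridge_kinds: Optional[Iterable[NodeKind]] = None,
        pp_proxy: LinkCategory = LinkCategory.PROTEIN_DISEASE,
    ):
        self.graph = graph
        self.policy = policy
        self.options = ScoringOptions(
            bridge_kinds=frozenset(bridge_kinds) if bridge_kinds else None
        )
        self.pp_proxy = pp_proxy

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "SharedNeighborhoodModel":
        """Build from an edge-list DataFrame with columns
        source_id, source_kind, target_id, target_kind [, source_tag]."""
        g = PharmGraph()
        has_tag = "source_tag" in frame.columns
        for row in frame.itertuples(index=False):
            u = NodeId(str(row.source_id), kind=NodeKind(row.source_kind))
            v = NodeId(str(row.target_id), kind=NodeKind(row.target_kind))
            tag = getattr(row, "source_tag", None) if has_tag else None
            g.add_edge(u, v, source_tag=tag if tag else None)
        return cls(g, **kwargs)

    def fit(self) -> "SNSResults":
        """Calibrate P(n) per category and return the results object."""
        bank = calibrate(
            self.graph,
            policy=self.policy,
            bridge_kinds=self.options.bridge_kinds,
            pp_proxy=self.pp_proxy,
        )
        return SNSResults(self, bank)


class SNSResults:
    """Fitted calibration plus scoring/evaluation entry points."""

    def __init__(self, model: SharedNeighborhoodModel, bank: CalibrationBank):
        self.model = model
        self.bank = bank

    @property
    def params(self) -> pd.DataFrame:
        """Logistic (a, b) per category with fit diagnostics."""
        rows = []
        for cat, cp in self.bank.tables.items():
            fitted = cp.fitted
            rows.append(
                {
                    "category": cat.value,
                    "policy": cp.policy,
                    "a": fitted.a if fitted else float("nan"),
                    "b": fitted.b if fitted else float("nan"),
                    "residual_deviance": fitted.residual_deviance
                    if fitted
                    else float("nan"),
                    "n_points": fitted.n_points if fitted else 0,
                    "n_pairs": cp.empirical.n_pairs,
                }
            )
        return pd.DataFrame(rows).set_index("category")

    def summary(self) -> str:
        g = self.model.graph
        counts = g.edge_counts()
        lines = [
            "Shared Neighborhood Scoring model",
            "=" * 70,
            f"nodes: {len(g.nodes(NodeKind.DRUG))} drugs, "
            f"{len(g.nodes(NodeKind.PROTEIN))} proteins, "
            f"{len(g.nodes(NodeKind.DISEASE))} diseases",
            "links: "
            + ", ".join(f"{c.value}={counts[c]}" for c in LinkCategory),
            "",
            "connecting-probability function f(n) = 1/(1+exp(a+b*n)), P(0)=0",
            "-" * 70,
            f"{'category':<18}{'policy':<11}{'a':>10}{'b':>10}"
            f"{'deviance':>12}{'points':>8}",
        ]
        for cat, row in self.params.iterrows():
            lines.append(
                f"{cat:<18}{row['policy']:<11}{row['a']:>10.4f}{row['b']:>10.4f}"
                f"{row['residual_deviance']:>12.4g}{int(row['n_points']):>8}"
            )
        lines.append("-" * 70)
        return "\n".join(lines)

    # -- scoring ----------------------------------------------------------

    def score(
        self,
        i: NodeId,
        j: NodeId,
        mode: str = "extended",
        leave_one_out: bool = False,
        keep_paths: bool = False,
    ):
        return sn_score(
            self.model.graph, self.bank, i, j, mode,
            leave_one_out=leave_one_out, options=self.model.options,
            keep_paths=keep_paths,
        )

    def score_pairs(
        self,
        category: LinkCategory,
        mode: str = "extended",
        leave_one_out_for_connected: bool = False,
    ) -> pd.DataFrame:
        """Batch scores as a tidy DataFrame (one row per pair)."""
        scored = score_all_pairs(
            self.model.graph, self.bank, category, mode,
            leave_one_out_for_connected, self.model.options,
        )
        g = self.model.graph
        norm = self.bank.normalizers.get(category)
        rows = []
        for (u, v), dec in scored.items():
            rows.append(
                {
                    "source_id": u.value, "source_kind": u.kind.value,
                    "target_id": v.value, "target_kind": v.kind.value,
                    "category": category.value,
                    "s0": dec.s0, "s1": dec.s1, "s2": dec.s2,
                    "total": dec.total,
                    "normalized": norm(dec.total) if norm else float("nan"),
                    "connected": g.has_edge(u, v),
                    "mode": mode,
                }
            )
        return pd.DataFrame(rows)

    def fit_normalizer(
        self, category: LinkCategory, bins: int = 20
    ) -> "SNSResults":
        """Fit the raw-score -> (0,1) normalizing logistic for a category."""
        scored = score_all_pairs(
            self.model.graph, self.bank, category, "extended",
            leave_one_out_for_connected=True, options=self.model.options,
        )
        if not scored:
            raise CalibrationFitError(f"no scoreable {category.value} pairs")
        g = self.model.graph
        scores = {pair: dec.total for pair, dec in scored.items()}
        connected = {pair: g.has_edge(*pair) for pair in scored}
        self.bank.normalizers[category] = calibrate_score_normalizer(
            scores, connected, category, bins=bins
        )
        return self

    # -- evaluation -------------------------------------------------------

    def ks_compare(self, category: LinkCategory, negative_sample_size=1000, seed=0):
        return ks_compare(
            self.model.graph, category, negative_sample_size, seed,
            self.model.options,
        )

    def compare_simple_extended(self, category: LinkCategory, seed=0, **kwargs):
        return compare_simple_extended(
            self.model.graph, self.bank, category, seed,
            options=self.model.options, **kwargs,
        )
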