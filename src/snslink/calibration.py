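"""Connection-probability calibration for shared-neighborhood scoring.

For every cross-kind link category the connection probability P(n) is the
fraction of directly connected node pairs among all pairs of that category
that share exactly n neighbors; P(0) = 0 by definition.  A logistic
connecting-probability function

    f(x) = 1 / (1 + exp(a + b*x)),   b < 0

is fitted to the empirical points (n, P(n)) so that P can be evaluated at
shared counts never observed in the calibration graph, and the same family
is reused to map raw shared-neighborhood scores onto a normalized (0, 1)
scale per category.

Calibration is done separately per category because link density differs
strongly between the drug-protein, drug-disease and protein-disease layers,
so identical raw counts carry different evidence in each.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Tuple, Union

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import (
    CalibrationFitError,
    CalibrationMissingError,
    MonotonicityError,
    UnsupportedCategoryError,
)
from .graph_store import (
    CATEGORY_KINDS,
    CROSS_KIND_CATEGORIES,
    LinkCategory,
    NodeKind,
    PharmGraph,
)

__all__ = [
    "SharedCountTable",
    "LogisticParams",
    "ConnectionProbability",
    "CalibrationBank",
    "count_shared_distribution",
    "empirical_probability",
    "fit_connection_probability",
    "connection_probability",
    "calibrate_score_normalizer",
    "calibrate",
]


def logistic(x, a: float, b: float):
    """The connecting-probability family f(x) = 1/(1+exp(a+b*x))."""
    return 1.0 / (1.0 + np.exp(a + b * np.asarray(x, dtype=float)))


@dataclass
class SharedCountTable:
    """Per-category tally of node pairs by shared-neighbor count.

    ``rows[n] = (pairs_total, pairs_connected)`` over all unordered pairs of
    the category's endpoint kinds.
    """

    category: LinkCategory
    rows: Dict[int, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        for n, (total, connected) in self.rows.items():
            if n < 0 or connected > total:
                raise ValueError(f"bad row n={n}: ({total}, {connected})")

    @property
    def n_pairs(self) -> int:
        return sum(t for t, _ in self.rows.values())

    def usable_points(self) -> list:
        """(n, P(n), weight) for n >= 1 rows with nonzero totals."""
        return [
            (n, c / t, t)
            for n, (t, c) in sorted(self.rows.items())
            if n >= 1 and t > 0
        ]


@dataclass(frozen=True)
class LogisticParams:
    """Fitted parameters of f(x) = 1/(1+exp(a+b*x)) with b < 0."""

    a: float
    b: float
    category: LinkCategory
    residual_deviance: float = float("nan")
    n_points: int = 0

    def __post_init__(self):
        if not self.b < 0:
            raise MonotonicityError(
                f"logistic slope must be negative, got b={self.b}"
            )

    def __call__(self, x) -> float:
        return float(logistic(x, self.a, self.b))


@dataclass
class ConnectionProbability:
    """Evaluable per-category connection probability P(n).

    policy:
        ``hybrid`` (default) — empirical value where n was observed, fitted
        logistic elsewhere; ``empirical`` — observed values only (0 when
        unobserved); ``fitted`` — always the logistic.  Under every policy
        P(0) = 0 exactly.
    """

    empirical: SharedCountTable
    fitted: Optional[LogisticParams] = None
    policy: str = "hybrid"

    def __post_init__(self):
        if self.policy not in ("hybrid", "empirical", "fitted"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.policy in ("hybrid", "fitted") and self.fitted is None:
            raise CalibrationMissingError(
                f"policy {self.policy!r} requires fitted logistic parameters"
            )

    @property
    def category(self) -> LinkCategory:
        return self.empirical.category

    def __call__(self, n: int) -> float:
        return connection_probability(self, n)

    @classmethod
    def zero(cls, category: LinkCategory) -> "ConnectionProbability":
        """P identically zero — reduces extended scoring to the simple form."""
        return cls(SharedCountTable(category, {}), None, policy="empirical")


def count_shared_distribution(
    g: PharmGraph,
    category: LinkCategory,
    bridge_kinds: Optional[Iterable[NodeKind]] = None,
) -> SharedCountTable:
    """Tally shared-neighbor counts over every unordered cross-kind pair.

    Pairs with n = 0 are obtained by complement arithmetic (total cross-kind
    pairs minus the pairs that share at least one neighbor), never by
    enumeration, so calibration scales to all-pairs workloads.
    """
    if category not in CROSS_KIND_CATEGORIES:
        raise UnsupportedCategoryError(
            f"calibration is defined for cross-kind categories only, got {category}"
        )
    kind_a, kind_b = CATEGORY_KINDS[category]
    nodes_a = g.nodes(kind_a)
    nodes_b = g.nodes(kind_b)
    kindset = set(bridge_kinds) if bridge_kinds is not None else None

    # Enumerate pairs with n >= 1 by walking each potential bridge node once.
    shared: Dict[Tuple, int] = {}
    for k in g.nodes():
        if kindset is not None and k.kind not in kindset:
            continue
        adj = g.adjacency(k)
        left = sorted(n for n in adj if n.kind == kind_a)
        right = sorted(n for n in adj if n.kind == kind_b)
        for i in left:
            for j in right:
                if i == j:
                    continue
                shared[(i, j)] = shared.get((i, j), 0) + 1

    rows: Dict[int, list] = {}
    connected_seen = 0
    for (i, j), n in shared.items():
        row = rows.setdefault(n, [0, 0])
        row[0] += 1
        if g.has_edge(i, j):
            row[1] += 1
            connected_seen += 1

    total_pairs = len(nodes_a) * len(nodes_b)
    total_connected = g.edge_counts()[category]
    pairs_nonzero = len(shared)
    zero_row = [total_pairs - pairs_nonzero, total_connected - connected_seen]
    rows[0] = zero_row
    return SharedCountTable(category, {n: (t, c) for n, (t, c) in rows.items()})


def empirical_probability(table: SharedCountTable, n: int) -> Optional[float]:
    """Observed P(n); 0 for n = 0; None for unobserved n >= 1."""
    if n < 0:
        raise ValueError(f"shared count must be non-negative, got {n}")
    if n == 0:
        return 0.0
    row = table.rows.get(n)
    if row is None or row[0] == 0:
        return None
    return row[1] / row[0]


def _fit_logistic_points(
    x: np.ndarray, p: np.ndarray, w: np.ndarray, category: LinkCategory
) -> LogisticParams:
    """Weighted least-squares logistic fit shared by calibration and
    normalization; deterministic initialization, b < 0 enforced."""
    if len(x) < 3:
        raise CalibrationFitError(
            f"need >= 3 points for the logistic fit, got {len(x)}"
        )
    if np.allclose(p, p[0]):
        raise MonotonicityError("flat connection probabilities, slope would be 0")
    rate = float(np.average(p, weights=w))
    rate = min(max(rate, 1e-6), 1 - 1e-6)
    a0 = -math.log(rate / (1 - rate))
    try:
        with warnings.catch_warnings():
            # the parameter covariance is not used anywhere
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                logistic,
                x,
                p,
                p0=(a0, -1.0),
                sigma=1.0 / np.sqrt(w),
                absolute_sigma=False,
                maxfev=20000,
            )
    except RuntimeError as exc:  # no convergence
        raise CalibrationFitError(f"logistic fit failed: {exc}") from None
    a_hat, b_hat = float(popt[0]), float(popt[1])
    if b_hat >= -1e-8:
        raise MonotonicityError(
            f"fitted connecting-probability slope is non-negative (b={b_hat:.4g})"
        )
    resid = p - logistic(x, a_hat, b_hat)
    deviance = float(np.sum(w * resid**2))
    return LogisticParams(a_hat, b_hat, category, deviance, len(x))


def fit_connection_probability(table: SharedCountTable) -> LogisticParams:
    """Fit f(n) = 1/(1+exp(a+b*n)) to the empirical P(n) points (n >= 1).

    Each point is weighted by its pair count; the fit is deterministic given
    the table.  Raises CalibrationFitError with < 3 usable points and
    MonotonicityError when the data do not support an increasing curve.
    """
    pts = table.usable_points()
    if len(pts) < 3:
        raise CalibrationFitError(
            f"need >= 3 distinct shared-count values, got {len(pts)}"
        )
    x = np.array([n for n, _, _ in pts], dtype=float)
    p = np.array([pn for _, pn, _ in pts], dtype=float)
    w = np.array([t for _, _, t in pts], dtype=float)
    return _fit_logistic_points(x, p, w, table.category)


def connection_probability(cp: ConnectionProbability, n: int) -> float:
    """Evaluate P(n) under the table's policy; P(0) = 0 always."""
    if n < 0:
        raise ValueError(f"shared count must be non-negative, got {n}")
    if n == 0:
        return 0.0
    if cp.policy == "fitted":
        return cp.fitted(n)
    emp = empirical_probability(cp.empirical, n)
    if cp.policy == "empirical":
        return emp if emp is not None else 0.0
    # hybrid
    if emp is not None:
        return emp
    return cp.fitted(n)


def calibrate_score_normalizer(
    scores: Mapping,
    connected: Mapping,
    category: LinkCategory,
    bins: int = 20,
) -> LogisticParams:
    """Fit the normalizing logistic mapping raw SN score -> (0, 1).

    Raw scores are binned, the fraction of connected pairs per bin computed,
    and the same logistic family fitted against bin midpoints weighted by
    bin occupancy.  The result is a monotone increasing map because b < 0.

    Parameters
    ----------
    scores : mapping pair -> raw score
    connected : mapping pair -> bool (connection status of each scored pair)
    """
    pairs = list(scores)
    if not pairs:
        raise CalibrationFitError("no scored pairs to normalize")
    y = np.array([bool(connected[p]) for p in pairs])
    if not y.any():
        raise CalibrationFitError("no connected pairs in the normalization sample")
    s = np.array([scores[p] for p in pairs], dtype=float)
    edges = np.linspace(s.min(), s.max(), bins + 1)
    if edges[0] == edges[-1]:
        raise CalibrationFitError("all raw scores identical, cannot bin")
    idx = np.clip(np.digitize(s, edges[1:-1]), 0, bins - 1)
    mids, fracs, weights = [], [], []
    for k in range(bins):
        mask = idx == k
        if not mask.any():
            continue
        mids.append((edges[k] + edges[k + 1]) / 2.0)
        fracs.append(float(y[mask].mean()))
        weights.append(int(mask.sum()))
    return _fit_logistic_points(
        np.array(mids), np.array(fracs), np.array(weights, dtype=float), category
    )


@dataclass
class CalibrationBank:
    """Per-category connection probabilities plus optional score normalizers."""

    tables: Dict[LinkCategory, ConnectionProbability] = field(default_factory=dict)
    normalizers: Dict[LinkCategory, LogisticParams] = field(default_factory=dict)
    pp_proxy: LinkCategory = LinkCategory.PROTEIN_DISEASE

    def get(self, category: LinkCategory) -> ConnectionProbability:
        """Connection probability for a category; protein-protein virtual
        links fall back to the configured proxy category."""
        if category in self.tables:
            return self.tables[category]
        if category == LinkCategory.PROTEIN_PROTEIN and self.pp_proxy in self.tables:
            return self.tables[self.pp_proxy]
        raise CalibrationMissingError(f"no calibration for category {category}")

    @classmethod
    def zero(cls) -> "CalibrationBank":
        """P identically 0 in every category (extended == simple scoring)."""
        return cls(
            tables={c: ConnectionProbability.zero(c) for c in CROSS_KIND_CATEGORIES}
        )

    # -- serialization ----------------------------------------------------

    def to_json(self, path: Union[str, Path]) -> None:
        doc = {"pp_proxy": self.pp_proxy.value, "categories": {}, "normalizers": {}}
        for cat, cp in self.tables.items():
            doc["categories"][cat.value] = {
                "policy": cp.policy,
                "rows": {str(n): list(tc) for n, tc in sorted(cp.empirical.rows.items())},
                "fitted": None
                if cp.fitted is None
                else {"a": cp.fitted.a, "b": cp.fitted.b,
                      "residual_deviance": cp.fitted.residual_deviance,
                      "n_points": cp.fitted.n_points},
            }
        for cat, params in self.normalizers.items():
            doc["normalizers"][cat.value] = {"a": params.a, "b": params.b}
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CalibrationBank":
        doc = json.loads(Path(path).read_text())
        bank = cls(pp_proxy=LinkCategory(doc.get("pp_proxy", "protein_disease")))
        for cat_name, block in doc["categories"].items():
            cat = LinkCategory(cat_name)
            table = SharedCountTable(
                cat, {int(n): tuple(tc) for n, tc in block["rows"].items()}
            )
            fitted = None
            if block["fitted"] is not None:
                f = block["fitted"]
                fitted = LogisticParams(
                    f["a"], f["b"], cat, f.get("residual_deviance", float("nan")),
                    f.get("n_points", 0),
                )
            bank.tables[cat] = ConnectionProbability(table, fitted, block["policy"])
        for cat_name, f in doc.get("normalizers", {}).items():
            cat = LinkCategory(cat_name)
            bank.normalizers[cat] = LogisticParams(f["a"], f["b"], cat)
        return bank


def calibrate(
    g: PharmGraph,
    policy: str = "hybrid",
    bridge_kinds: Optional[Iterable[NodeKind]] = None,
    pp_proxy: LinkCategory = LinkCategory.PROTEIN_DISEASE,
) -> CalibrationBank:
    """Calibrate P(n) for the three cross-kind categories of a graph.

    Categories whose logistic fit fails (too few points, flat or
    non-monotone data) silently fall back to the empirical policy, which is
    always available.
    """
    bank = CalibrationBank(pp_proxy=pp_proxy)
    for cat in CROSS_KIND_CATEGORIES:
        table = count_shared_distribution(g, cat, bridge_kinds=bridge_kinds)
        fitted = None
        cat_policy = policy
        if policy in ("hybrid", "fitted"):
            try:
                fitted = fit_connection_probability(table)
            except CalibrationFitError:
                cat_policy = "empirical"
        bank.tables[cat] = ConnectionProbability(table, fitted, cat_policy)
    return bank
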