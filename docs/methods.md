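# Methods

## Model

`snslink` treats a pharmacological knowledge base as an undirected simple
graph with three node kinds (drug, protein, disease) and four typed link
categories (drug–protein, protein–disease, drug–disease,
protein–protein); drug–drug and disease–disease links do not exist in the
data model, and a virtual link between such a kind pair carries weight 0.
The underlying premise is transitivity: the probability that two nodes
are connected increases monotonically with the number of neighbors they
share. The shared-neighborhood score operationalises this as

    S_ij = Σ_k W_ik W_kj,
    W_xy = a_xy + P(s_xy(0)) δ(a_xy, 0),

with `a_xy` the adjacency indicator, `s_xy(0)` the pair's shared-neighbor
count and `P(n)` the per-category connection probability (`P(0) = 0`).
Expanding the product decomposes the score into the Shared Nodes Count
`s0` (the "simple" algorithm), the half-virtual term `s1` and the fully
virtual term `s2`; the "extended" algorithm uses the sum.

The printed definition of the second-order term is ambiguous about the
sum over bridge nodes; the defining expression `S_ij = Σ_k W_ik W_kj`
implies it, and this package sums `s2` over bridges like the other two
terms.

### Bridge set

The sum formally runs over every node `k`, but a bridge contributes only
if both of its weights can be nonzero: it must either have a real link to
the endpoint or share at least one neighbor with it (otherwise
`P(0) = 0`). The implementation therefore iterates over
`(N(i) ∪ N²(i)) ∩ (N(j) ∪ N²(j))`, where `N²(x)` is the set of nodes
sharing a neighbor with `x`. This is an exact computational bound, not an
approximation — the test suite verifies equality with a brute-force sum
over all nodes using a fully materialised weight matrix — and it keeps
per-pair cost proportional to neighborhood size rather than graph size.
In particular a fully virtual bridge (no real link to either endpoint)
**does** contribute whenever it shares neighbors with both, as in the
canonical five-node walkthrough where the total is
`1 + P(2) + P(3)·P(1)`.

### Shared neighbors across kinds

Shared neighbors are counted over all node kinds adjacent to both
endpoints by default — working on the full heterogeneous graph rather
than a one-kind projection is the method's point, and protein–protein
links thereby contribute bridging proteins. A `bridge_kinds` option
restricts counting to chosen kinds; the restriction applies uniformly to
`s0`, to the bridge set and to the inner shared counts.

## Calibration

`P(n)` is estimated separately for each of the three cross-kind
categories, because link density differs strongly between layers and the
same raw count carries different evidence in each. For every unordered
cross-kind pair the shared count is tallied; pairs with `n = 0` are
obtained by complement arithmetic (total pairs minus pairs with
`n ≥ 1`), never enumerated, which is what makes all-pairs calibration
affordable beyond toy graphs.

The logistic connecting-probability function
`f(x) = 1/(1+exp(a+b·x))` is fitted to the points `(n, P(n))`, `n ≥ 1`,
by weighted least squares with weight `pairs_total[n]`
(`scipy.optimize.curve_fit`; deterministic initialisation
`a₀ = −logit(mean rate)`, `b₀ = −1`). A fit needs at least three usable
points and must produce `b < −10⁻⁸`; flat or decreasing data raise a
monotonicity error and the category falls back to the purely empirical
policy. Three evaluation policies exist:

* `hybrid` (default): empirical value where `n` was observed, fitted
  `f(n)` elsewhere — the sources are ambiguous about whether raw or
  fitted probabilities feed the weights, so both are kept and the hybrid
  uses each where it is most defensible;
* `empirical`: observed values only, 0 elsewhere;
* `fitted`: always the logistic.

`P(0) = 0` exactly under every policy. Protein–protein virtual links have
no calibration of their own (only the three cross-kind categories are
calibrated); they reuse the protein–disease table as a proxy,
configurable via `CalibrationBank.pp_proxy`.

Score normalization fits the same logistic family to binned raw scores
against the fraction of connected pairs per bin (default 20 bins,
weighted by occupancy), giving a monotone map from raw score to (0, 1)
per category, so thresholds are comparable across categories.

Calibration is computed once on the full graph and frozen; leave-one-out
scoring does not recalibrate per pair (per-pair recalibration would be
quadratically expensive and changes nothing about the ranking question
being asked).

## Leave-one-out

When an existing link is scored, the edge is removed before **all**
terms — including the inner shared counts `s_ik(0)` — are computed, and
restored afterwards; the tests assert exact equality with scoring on a
copy of the graph with the edge physically deleted. The narrower reading,
in which only the second-order term sees the edge removed, is available
via `ScoringOptions(loo_all_terms=False)`; the default is the full
removal because the purpose of leave-one-out is that the score must not
depend on the link's own presence in any term.

## Evaluation protocol

* **Distribution comparison.** Two-sample Kolmogorov–Smirnov test of
  shared-count distributions, all connected pairs versus a seeded uniform
  sample of unconnected pairs (default 1000; the choice of sample size is
  exposed because exhaustive enumeration of negatives is rarely wanted).
  Both the two-sided and the one-sided ("connected stochastically
  larger") p-values are reported. Asymptotic p-values are used for large
  samples; p-values far below machine precision are reported as computed
  and should be read as "vanishingly small", not as exact quantities.
* **ROC.** Positives are the category's existing links scored
  leave-one-out; negatives an equal-size seeded sample scored on the
  intact graph; both modes score identical pair sets. AUC is the
  Mann–Whitney rank statistic with midranks for ties — ties dominate in
  simple mode, where scores are small integers, so the tie convention is
  observable; the reported curve's trapezoidal area equals the rank AUC
  to 1e-9 by construction. Improvement is the relative AUC gain of the
  extended algorithm in percent.

Scoring positives leave-one-out while negatives keep the intact graph
introduces a small downward bias for positives on unstructured (null)
graphs, visible in the null tests as mean AUC slightly below 0.5; it is
conservative with respect to the method's claim.

## Synthetic data

The generator plants latent communities: each node is assigned uniformly
to one of `n_modules` communities and each admissible pair links
independently with `p_within` inside a community, `p_between` across.
Co-membership raises both the chance of a direct link and the number of
common neighbors, producing exactly the structure the score exploits —
connected pairs share more neighbors than unconnected pairs. Defaults: 60
drugs, 120 proteins, 60 diseases, 6 modules, `p_within = 0.25`,
`p_between = 0.01`, protein–protein the same, and drug–disease
probabilities scaled by 0.5 to mirror the relative scarcity of indication
links in real pharmacological databases (a shape choice, not a numeric
target). Setting `p_within == p_between` yields the Erdős–Rényi null used
to check false-positive behaviour.

What the generator does **not** emulate: heavy-tailed degree
distributions, hub drugs/targets, correlated multi-database provenance,
and curation biases of real knowledge bases. Passing tests on planted
networks therefore demonstrate that the implementation detects
shared-neighbor structure where it exists and stays at chance where it
does not — they do not certify performance numbers on any real database,
whose absolute AUCs depend on its size and density.

All randomness flows from a single `numpy.random.default_rng(seed)`
stream consumed in documented order, so edge lists are byte-identical for
identical parameters and seed. Holdout splits remove
`ceil(fraction · E)` uniformly chosen edges of one category from a copy
of the graph and sample negatives from pairs unconnected in the original
graph.

## Numerical choices and degenerate inputs

* Bridge iteration and batch scoring follow sorted node order, so
  floating-point summation order is deterministic.
* Score comparisons in tests use 1e-9 absolute tolerance; decomposition
  identities (`total = s0+s1+s2`, path products summing to the total) are
  exact by construction.
* Shortest paths are breadth-first; among equally short paths the
  lexicographically smallest node-value sequence is returned for
  determinism.
* Degenerate inputs raise typed errors: fewer than three calibration
  points, flat or decreasing probability data, single-class ROC labels,
  negative-sample requests exceeding the unconnected population, unknown
  nodes, forbidden kind pairs.
* Duplicate edge rows collapse to a single link with merged provenance
  tags; isolated nodes round-trip through the TSV format as node-only
  rows.

## Problem sizes

The test suite and the acceptance script run on planted networks of
240 nodes (the default parameters above) with 5–10 generator seeds,
brute-force oracle graphs of ≤ 40 nodes, and 20,000-pair simulated
calibration experiments — sizes chosen so every check is exact or
well-powered while the whole suite stays interactive on a laptop.

## Known limitations

* Only the three cross-kind categories are calibrated; protein–protein
  virtual weights lean on a proxy category.
* No approximate scoring for very large graphs; all-pairs drivers are
  exact and meant for desk-scale networks (10⁴–10⁵ pairs per category).
* The repositioning threshold default (0.004) is applied to the
  normalized score by default; whether a published threshold refers to
  raw or normalized scores is ambiguous in general, so the score space is
  an explicit configuration switch.
* Disease-class membership is supplied as explicit node lists; resolving
  ontology terms ("Carcinoma", "Neoplasm", ...) to identifiers is
  curation work outside this package's scope.
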