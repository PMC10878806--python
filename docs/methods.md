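# Methods

This note records the models implemented in `bowtienet`, the choices
made where the design was genuinely open, and what the synthetic data
does and does not establish.

## Data model

A snapshot is a simple directed graph (self-loops allowed, no parallel
edges) whose nodes are pages with a stance (`r` anti, `b` pro, `g`
neutral) and a non-negative integer fan count.  Edge *presence* is the
stored datum; the edge *weight* is derived as the product of the two
endpoint fan counts ("product kernel": a recommendation between two
large pages moves more people than one between two small pages).
Because zero-fan pages exist, a present edge may have weight 0 —
presence and weight are therefore kept separate, and reachability
semantics always use presence.  Algorithms that need strictly positive
flow (community detection, inverse-weight shortest paths) substitute a
floor of 1e-9 on a copy; stored data is never modified.

Snapshots are cumulative: every early edge must appear in the late
snapshot (`validate_temporal` rejects violations and lists offenders).
Reciprocity is reported as the percentage of all edges whose reverse is
also present; self-loops count in the denominator but can never be
mutual.

## Bow-tie decomposition

`decompose` computes the largest strongly connected component with
Tarjan-type SCC enumeration (via networkx), then classifies the
remaining nodes by multi-source reachability: OUT is what the core
reaches, IN is what reaches the core, TUBES are on IN-to-OUT paths that
bypass the core, INTENDRILS hang off IN, OUTTENDRILS feed OUT, OTHERS
is the remainder.  "Reachable from a set" includes the trivial
self-path, so IN itself belongs to the reachable-from-IN set.  The
seven roles are checked (in tests) to be a hard partition on every
graph, and to agree exactly with a brute-force reachability-matrix
oracle that applies the definitions literally.

Two degenerate situations need deterministic conventions:

* **Ties for the largest SCC.**  Real recommendation networks have a
  unique giant component, but random and adversarial graphs need not.
  The component containing the lexicographically smallest node id (as a
  string) wins.  This makes the decomposition reproducible; it also
  means a single node is a legitimate size-1 "core" on a graph with no
  multi-node component (a DAG).
* **Self-loops** make a singleton strongly connected in the
  edge-present sense, but do not enlarge any component; they matter only
  through the general size-1 rule above.

`recursive_decompose` applies `decompose` independently to each
community's node-induced subgraph; edges across communities are
disregarded.  Nodes in communities relabelled `UNASSIGNED` (below) are
excluded from decomposition, keep a sentinel role, and reduce to `NA`.
`reduce_roles` collapses the seven roles to `{SCC, IN, OUT, NA}`: the
three main components carry the information-flow interpretation
(magnifiers / creators / listeners); the marginal ones do not separate
the stance groups and are pooled.

## Community detection

The across-group partition uses the map equation (Infomap): random
walks on the weighted directed graph, minimising the Shannon-entropy
description length of the walk.  The backend is igraph's
`community_infomap` with `trials=10` attempts (best description length
kept) and the two-level map equation; both are backend defaults
documented here rather than tuned values.  The run is seeded, and the
partition from one seeded run is canonical for downstream features;
communities smaller than 5 nodes are relabelled `UNASSIGNED`.  Nodes in
`UNASSIGNED` communities never count as community-mates of any page —
including each other — in the community-share features.

## Null-model significance

Observed component sizes are compared with degree-preserving random
graphs.  The default null re-pairs out-stubs with a random permutation
of in-stubs and repairs duplicate edges and newly created self-loops by
local swap moves (bounded rounds; a non-converged repair is returned
best-effort with a warning).  A directed triple-edge-swap chain (10
accepted swaps per edge by default) is available as an alternative.
Both preserve every node's in- and out-degree exactly.

For each role the test statistic is the node count; significance is the
two-sided empirical p-value with the finite-ensemble correction,

    p = (1 + #{ |x_i − mean| ≥ |obs − mean| }) / (n_replicates + 1),

so p is never 0 and equals 1 when the observation sits at the null
mean.  Calibration is verified by drawing the "observed" graph from the
null itself: over 100 such draws the p-values pass a
Kolmogorov–Smirnov uniformity test at the 1% level.  Note that a
*planted* sparse core can be significantly **larger** than the null
(rewiring fragments it) while a dense network's core can come out
**smaller** (rewiring recruits the periphery into the core); the sign
of z is informative in both directions.

## Feature set and prediction harness

Features are computed on the early snapshot for non-neutral pages only;
neutral pages remain in every neighbour sum.  Proportional features use
weights, not edge counts.  Conventions:

* zero weighted in-degree (isolated page, or only zero-fan
  recommenders) sets the in-proportions to 0 and flags the row
  (`degenerate_in`); same for the out direction — features stay total
  and bounded, and the flag makes the convention auditable;
* the fan count enters models as `log(1 + f)` (zero-fan pages exist);
* PageRank uses edge weights as strengths; betweenness uses distance
  `1/weight` with the 1e-9 floor.  Unweighted variants are available
  (`weighted_centralities=False`); weighted is the default because the
  weight carries the recommendation strength.

The harness is cross-validated throughout (5 folds, shuffled, seeded):

* **Expansion classification** — a page expands iff its fan count
  strictly increased.  Class-weighted (`balanced`) logistic regression,
  standardized inputs, inverse-regularization grid
  C ∈ {0.01, 0.1, 1, 10, 100}, accuracy optimized; sensitivity and
  specificity (label 1 = expanding) from out-of-fold predictions.  The
  baseline assigns classes with equal probability.
* **Fan-count-change regression** — raw `Δf`, per stratum (all /
  expanding / non-expanding).  SVR (kernel ∈ {linear, rbf},
  C ∈ {1…1000}, ε ∈ {0.001, 0.01, 0.1}, inputs standardized, target
  scaled with a *robust* (median/IQR) scaler: fan-count changes are
  heavy-tailed, and scaling by the standard deviation would let a few
  mega pages compress the bulk of the target into the ε-tube) and
  random-forest regression (100 trees, depth ∈ {None, 10}, leaf
  ∈ {1, 5}).  MAE is the optimized metric (robust to outliers), with
  R² and RMSE reported; the baseline predicts the training-fold mean,
  so its out-of-fold R² is ≤ 0 in expectation.
* **Feature assessment** — Pearson correlation with `Δf` for numeric
  features per stratum (zero-variance features report 0 with a flag);
  mutual information for all features (k-NN estimator, categorical
  features as discrete, averaged over seeded runs because the estimator
  is stochastic); and sequential forward floating selection on the
  expanding stratum, selecting 10 of the 14 features by greedy forward
  additions under cross-validated MAE with conditional backward
  removals, one-hot blocks moving as units, selection frequencies
  reported over repeated runs.  SFFS is implemented in-package (greedy
  wrapper, ~100 model evaluations per run) with fixed inner models
  (SVR as above with default grid point; 50-tree forest).

## SIR information cascades

A recommendation `u -> v` is usually *triggered by* v's content
reaching u, so information travels against the edges: an infectious
page transmits to each susceptible **in-neighbour** independently with
probability β per step, then recovers with probability γ.  This
direction choice is the single most consequential interpretive decision
in the simulator; it is switchable (`direction="forward"`), and the
reverse default is the one consistent with the data model's
recommendation semantics.  Dynamics are synchronous — all transmissions
of a step resolve from the previous step's infectious set before any
recovery draw — which yields clean closed forms used as oracles:
β = 0 leaves only the seed; β = 1 infects the entire reverse-reachable
set of the seed regardless of γ (every page transmits to all contacts
in its first infectious step); a single-contact cascade with γ = 1
doubles with probability exactly β.  γ = 0 is rejected
(non-termination risk); the impacted set of a piece is the set of
ever-infected pages, all of which have recovered at termination.

Influence accounting: a piece seeded at an anti- or pro- page scores
its **within-group** influence as the summed fan counts of impacted
same-stance pages (the seed included — switchable via
`include_seed=False`) and its **across-group** influence over impacted
neutral pages.  Impacted pages of the opposite stance score in neither
tally but still transmit: the exclusion reflects that their members are
assumed not to convert, not that they stop the content.  Neutral pages
can be infected but never seed.  Per-page influence sums the piece
influences over the pieces seeded at that page, so the page totals and
the piece totals agree exactly (a conservation identity asserted in
tests).

The component experiment seeds 1000 pieces uniformly inside each main
reduced component at β = 0.5, γ = 0.3.  The initializer sweep varies
the seeding weights of two chosen roles over a grid (default 7
log-spaced weights from 0.1 to 10, all other eligible pages at weight
1), runs 3000 pieces per cell, and reports the Pearson correlation
between per-page influence and the fan-count change on a chosen
stratum.

## Synthetic data

The generator produces the study conditions end to end: 1326 pages (317
anti, 124 pro, 885 neutral); within-group bow-tie mixes that make the
anti group OUT-heavy (40%), the pro group SCC-heavy (42%) and the
neutral group OTHERS-heavy (58%); log-normal fan counts (log-location
7.0, log-scale 1.6) with three mega pages above one million fans
injected into the pro group and four zero-fan pages; inter-group edges
moderate towards the neutral group and near zero between the stances;
8.5% target reciprocity reached by mirroring inter-group edges only (so
the planted intra-group roles stay exact); self-loops at 0.15% of
edges; and a late snapshot adding 45% new edges, 6% of which arrive as
mutual pairs so reciprocity drifts up to ~10% instead of diluting.
Exact per-group proportions are configurable: the study's own numeric
breakdown per role is not published, so the defaults are declared
stand-ins chosen to reproduce the qualitative composition, not
estimates of the real values.

The fan-count-change law is `Δf = a·f·s + b·k_in + ε` with `s = +1`
with probability q = 0.73.  The two sides are asymmetric by design:
gains follow the recommendation structure (a = 0.35, b = 2e-7 so the
in-strength term is a secondary effect, additive noise of sd
0.05·(f+50)), while losses are smaller (shrink 0.35) and carry a
multiplicative log-normal jitter (log-sd 0.75) and are clamped at zero.
The asymmetry encodes the domain expectation that recommendations
correlate with audience growth while decline is largely exogenous; it
is what makes the expanding stratum systematically more predictable
than the non-expanding one, and the magnitude-scales-with-f form
produces the "snowball" correlation between initial fan count and
change magnitude.  Realized quantities (reciprocity, expanding share,
role counts) are reported in the returned ground truth rather than
assumed.

What the generator does **not** emulate: degree heterogeneity beyond
the planted structure, narrative/geography metadata, community
structure finer than the three stance groups (detected communities on
synthetic data are a property of the plant, not a planted target), and
any fitted relationship to the real dataset.  Green synthetic tests
therefore certify the pipeline's correctness and its qualitative
behaviour under the stated conditions, not quantitative agreement with
the real network.

## Problem sizes and tolerances in the test suite

Oracle equivalence uses 200 random digraphs with up to 60 nodes;
planted recovery uses 100 random size vectors; the SIR closed forms use
10⁴ runs per β with a 3-standard-error binomial band; the influence
hierarchy uses 1000 pieces per component on the default 1326-page
synthetic network; the prediction patterns are required in at least 8
of 10 generator seeds; null calibration uses 100 draws against 49-replicate
ensembles and a KS test at α = 0.01.  Realized reciprocity is required
within ±0.02 of target for networks with at least 2000 edges; the
realized expanding share within ±0.03 of q at 1000 non-neutral pages
(binomial tolerance).  These sizes keep the full suite and the
acceptance script to a few minutes on one CPU while leaving each check
statistically meaningful.

## Known limitations

* The reciprocity tuner only mirrors inter-group edges; targets beyond
  what that pool can supply (e.g. a target of 1) are met best-effort
  with the realized value reported, because mirroring intra-group edges
  would destroy the planted roles that downstream recovery tests rely
  on.
* The map-equation backend's stochasticity means across-group roles
  are defined relative to the seeded canonical run; a multi-seed
  robustness loop is a one-liner (`detect_communities` with several
  seeds) but no consensus clustering is provided.
* Pearson correlations on heavy-tailed quantities are outlier-driven;
  the reported CCs should be read accordingly (the rank-based
  alternative is deliberately not substituted, to keep the harness
  comparable with the standard protocol).
* The SIR simulator is discrete-time and synchronous; continuous-time
  dynamics, forgetting mechanisms and transmission delays are out of
  scope.
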