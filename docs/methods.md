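# Methods

This note documents the models and procedures implemented in `cytopattern`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make runs reproducible.

## Input model

The unit of analysis is a samples × features 0/1 matrix whose columns are
(cytoband, event-type) pairs under the loss/gain/fusion (LGF) model. The
canonical column-header dialect is `"<band>.<L|G|F>"` (e.g. `8q24.F`);
upstream exports with other conventions are handled by a user-supplied regex
with named groups `band` and `type`, since no single upstream naming scheme is
universal. Matrix orientation is fixed as rows = samples; a `transpose` flag
covers the other convention. Sparse-triplet files carry an explicit
`#sample` / `#feature` manifest so all-zero rows (cytogenetically normal
karyotypes) survive round trips.

## Binary distances

Every metric is a function of the 2×2 contingency counts
`(N11, N10, N01, N00)` of a vector pair. The Jaccard distance
`1 − N11/(N11+N10+N01)` is the default: in sparse aberration data the 0–0
matches dominate and carry no information, and Jaccard is the classical
metric that discards them. The other nine follow the standard binary-
similarity literature conventions:

| metric | distance |
|---|---|
| Sokal–Michener | `1 − (N11+N00)/n` |
| Hamming | `(N10+N01)/n` |
| Russell–Rao | `1 − N11/n` |
| Pearson | `(1 − φ)/2`, `φ = (N11·N00 − N10·N01)/√(Π marginals)` |
| Goodman–Kruskal | `1 − (σ−σ′)/(2n−σ′)` with the usual `σ`, `σ′` row/col maxima |
| Manhattan / Canberra | `N10 + N01` (binary vectors make them coincide) |
| Euclidean | `√(N10+N01)` |
| Binary | identical to Jaccard (the same asymmetric-binary formula) |

Degenerate denominators are resolved so identical vectors are always at
distance 0: Jaccard/Binary of two all-zero vectors is 0; Pearson with a zero
marginal is 0 for equal vectors and 1 otherwise; Goodman–Kruskal with
`2n = σ′` is 0. Russell–Rao is the one metric whose *formula* gives a
positive self-distance for vectors containing zeros; the zero diagonal is
enforced at the distance-matrix level. Pairwise matrices are computed from a
single matrix product of the 0/1 data, so results do not depend on chunking
or evaluation order, and are symmetrized exactly.

## Feature reduction and outlier filtering

Duplicate columns are collapsed to their first occurrence (original column
order), keeping a representative → members map; multiplicities appear in
reports as a `.x<k>` suffix so whole-arm events stay interpretable.
Downstream distances use the reduced, unweighted matrix; expanding the map
and recomputing distances on a pre-deduplicated input yields identical
results (tested).

The Thresher-style outlier filter computes, on the feature-standardized
matrix (zero-variance columns contribute nothing), the top-`q` eigenpairs and
drops features whose loading length `‖(√l_k v_{jk})_{k≤q}‖` falls below
`δ = 0.3`. Standardization is the default because the filter asks whether a
feature participates in the *correlation* structure; both the unstandardized
mode and `δ` are configurable, and `q` defaults to the Auer–Gervini choice on
the same spectrum.

## Dimension estimation

Eigenvalues come from the singular values of the column-mean-centered matrix
(numerically stabler than forming the covariance); values below
`1e−12 · l_1` are treated as zero.

* **Broken stick:** keep `q` while `l_k/Σl > b_k = (1/d)·Σ_{i=k..d} 1/i`.
* **Auer–Gervini:** with the isotropic-residual profile log-likelihood
  `L(q) = −(n/2)[Σ_{j≤q} ln l_j + (d−q)·ln(Σ_{j>q} l_j/(d−q))]`, the MAP
  dimension under an exponential prior with rate `θ` is
  `argmax_q [L(q) − θq]`. Because the penalty is linear in `q` this is solved
  exactly by the upper convex hull of `{(q, L(q))}`; breakpoints in `θ` are
  the slopes between adjacent hull vertices, and ties at a breakpoint resolve
  to the larger `q`. The prior rate is left unnormalized by `n`: only the
  ordering and relative lengths of steps matter for selection.

**Selection rule.** Steps (with `q ≥ 1` and finite width) longer than twice
the mean step length are the *long-step candidates*. The automatic
`twice-mean` criterion picks the candidate with the longest step (ties → the
larger `q`), falling back to the longest step when no candidate clears the
bar. The candidate list frequently contains more than one defensible
dimension — e.g. the between-cluster contrast rank and the number of
elementary events both produce long steps — which is precisely why the
analyst-facing surface exposes `manual_q` to pin any candidate, and why the
automatic rule should be read as a default, not an oracle. On data with `K`
well-separated planted clusters the automatic choice lands at the
between-cluster rank (≈ `K − 1`); recovering finer event-level structure
requires pinning the higher candidate.

## PAM clustering

The objective is the total distance of objects to their cluster medoids.
When the number of candidate medoid sets `C(n, K)` is at most `exact_limit`
(default 5000) the optimum is found by enumeration with a lexicographic
tie-break — best-improving BUILD+SWAP is a local search and can stall one
swap short of the optimum even on 7-point instances, so enumeration is what
actually guarantees exact costs on small problems. Above the bound the
classical Kaufman–Rousseeuw algorithm runs: BUILD greedily adds the medoid
that most reduces cost (ties → lowest index), SWAP repeatedly applies the
best-improving medoid↔non-medoid exchange (ties → lexicographic
(medoid index, candidate index)), and objects go to the nearest medoid
(ties → lowest medoid index). Everything is deterministic; no random
restarts. Silhouette widths (singletons scored 0) and Hungarian-assignment
label alignment (unmatched clusters get fresh ids) complete the module.

## Views

* **Down-sampling:** local density `LD_i` is the neighbor count within a
  radius (object itself included; `radius="auto"` = 5th percentile of
  off-diagonal distances); object `i` is kept with probability
  `min(1, TD/LD_i)`, with `TD` calibrated by bisection so the expected kept
  count equals the target. This under-samples dense regions so rare clusters
  survive sub-sampling.
* **Adjacency graph:** edge iff `d < τ`; `τ = 0.6` on the Jaccard scale by
  default (similarity > 0.4), exposed as a parameter since the inflection-
  point diagnostic that motivates it is data-dependent.
* **Classical MDS:** Torgerson double-centering, eigenvalues clipped at 0,
  zero-padding (with a warning) past the positive rank, and a fixed sign
  convention (largest-magnitude coordinate positive) for reproducibility.
* **Ward dendrogram:** Ward.D2 (squared-distance Lance–Williams), delegated
  to `scipy.cluster.hierarchy.linkage`. Jaccard distances are not Euclidean,
  so the dendrogram is a heuristic view, not a model.
* **Palette:** reference clusters take colors by descending size from an
  18-color base palette, cycling with lightness variation beyond 18; aligned
  partitions inherit colors through the alignment map.
* **t-SNE:** a pluggable scikit-learn backend with a fixed seed and
  perplexity default 30 (capped at `(n−1)/3`); not re-implemented and only
  smoke-tested.

## Characterization

Feature clusters are interpreted as elementary events: each group's band set
is the union over members (expanded through the duplicate map), its class
follows from its event types (`loss-only`, `gain-only`, `fusion-only`,
`fusion+loss`, `fusion+gain`; anything else is `mixed` and logged). A sample
*exhibits* a group if any member feature is 1 — union semantics matching the
expanded band lists. Frequencies are exact integer ratios; reports round to
two decimals but cutoff comparisons (default 60%) use unrounded values, with
ties broken by group id. Coverage summaries count clusters whose best event
clears each threshold in the 99/95/90/80/70/60% ladder. The two-way heatmap
orders event groups and sample clusters by Ward linkage on
`1 − Pearson correlation` (zero-variance profiles get correlation 0, logged).

## Synthetic cohorts

`default_spec()` is the fixed study condition used by the recovery tests:
600 samples in 5 equally likely clusters; 12 events of 8 bands each
(event types cycling Loss/Gain/Fusion on chromosomes 1–12); cluster `c`
carries events `e ≡ c (mod 5)` at penetrance 0.9 — disjoint signatures of
2–3 events, the simplest topology in which clusters are defined by event
combinations; 0→1 noise at 0.01 (false calls never erase a planted event,
the way a called whole-arm gain is internally consistent; a symmetric-noise
mode exists for robustness experiments); 40 iid Bernoulli(0.02) outlier
features; seed 42. Outlier rate 0.02 was chosen once as a plausibly sparse
uninformative column. The resulting matrices are ~14% dense.

What the generator does **not** emulate: clonal heterogeneity, correlated
(nested or overlapping) signatures across clusters, missing data, 1→0
dropout under the default noise model, and the long-tailed cluster-size and
event-frequency distributions of real registry data. Passing recovery tests
therefore demonstrate correctness of the machinery under clean planted
structure, not performance on real cohorts.

## Problem sizes and determinism

Recovery experiments use 25 replicate cohorts of the default spec
(600 × 136); down-sampling calibration uses 100 draws on a 1000-sample
two-cluster cohort. These sizes give stable rate estimates while keeping the
full suite fast. Every stochastic component takes an explicit seed
(generator, down-sampler, t-SNE); the pipeline manifest records parameters,
seeds, input checksum and per-stage object counts, and two runs with the same
config are bit-identical (tested).

## Known limitations

* The automatic dimension rule picks one long step; when cluster-level and
  event-level structure coexist, the analyst must choose among candidates
  (exactly the manual choice the method's step-function plot is designed to
  support).
* BUILD+SWAP above `exact_limit` is a local search without optimality
  guarantees (tested to be lower-bounded by, and usually equal to, the
  enumerated optimum on small instances).
* Ward on non-Euclidean binary distances and classical MDS truncation are
  visualization heuristics.
* Event-group classification assumes parseable feature names; unparseable
  headers (lenient mode) propagate as `Unknown` type and are excluded from
  the class rule.
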