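# cytopattern

Pattern recognition for sparse binary cytogenetic matrices.

Karyotypes from hematologic malignancies can be encoded, band by band, as a
binary **loss/gain/fusion (LGF)** vector: one 0/1 column per (cytoband, event
type) pair. A cohort then becomes a large, sparse samples × features 0/1
matrix. `cytopattern` finds structure in such matrices for cancer
cytogenomics researchers: which patients share aberration patterns, which
bands move together as single cytogenetic events, and which events
characterize which patient clusters.

## Method

Given an `n × d` 0/1 matrix `X`:

1. **Feature reduction.** Empty columns are dropped and bitwise-identical
   columns are collapsed to one representative each (whole-arm events set many
   bands identically), with a provenance map so full band lists can be
   recovered.
2. **Outlier filtering (Thresher).** From the top-`q` eigenpairs
   `(l_k, v_k)` of the feature-standardized matrix, feature `j` is kept iff
   its loading length `‖(√l_1 v_{j1}, …, √l_q v_{jq})‖ ≥ δ` (default
   `δ = 0.3`).
3. **Binary distances.** Ten metrics over the 2×2 contingency counts
   `(N11, N10, N01, N00)` of each vector pair; the flagship is the Jaccard
   distance `d_J = 1 − N11/(N11 + N10 + N01)`, which ignores the
   uninformative 0–0 matches of sparse data. Sokal–Michener, Hamming,
   Russell–Rao, Pearson, Goodman–Kruskal, Manhattan, Canberra, Binary and
   Euclidean are also available.
4. **Dimension → cluster count.** The number of clusters `K` is tied to the
   number of significant principal components, estimated by the broken-stick
   rule and by the Auer–Gervini Bayesian method: the MAP dimension
   `q*(θ) = argmax_q [L(q) − θq]` is computed exactly as a step function of
   the exponential-prior rate `θ` (upper convex hull of `(q, L(q))`), and
   "long" steps are the candidate dimensions.
5. **Clustering.** Deterministic PAM (K-medoids; exact enumeration on small
   instances, BUILD+SWAP otherwise), with Hungarian label alignment so the
   same cluster keeps the same label and color across methods.
6. **Views.** SPADE-style density-dependent down-sampling, a thresholded
   adjacency graph (edge iff `d < τ`, default `τ = 0.6`), classical MDS,
   Ward dendrograms and an optional t-SNE backend, all sharing one palette.
7. **Characterization.** Features are clustered into elementary event groups,
   each classified by event type and chromosomes; every sample cluster is
   summarized by the fraction of members exhibiting each group, down to a 60%
   reporting cutoff, together with coverage summaries and disease prevalence.

A synthetic cohort generator (`cytopattern.synthetic`) plants clusters,
block-structured events with per-cluster penetrance, background noise and
outlier features — with full ground truth — so the whole pipeline is testable
without any external database.

## Worked example

```python
from cytopattern import default_spec, simulate, PipelineConfig, run_pipeline
from cytopattern.characterize import report_to_markdown
import json

matrix, truth = simulate(default_spec())            # 600 x 136, 5 planted clusters
res = run_pipeline(PipelineConfig(seed=0, feature_q=12), matrix=matrix)
print(json.dumps(res.manifest["counts"], indent=2))
print(report_to_markdown(res.report))
```

prints (abridged):

```
{
  "n_samples": 600,
  "d_raw": 136,
  "d_informative": 96,
  "broken_stick_q": 4,
  "long_step_candidates": [12, 4],
  "K": 4,
  "cluster_sizes": {"1": 190, "2": 140, "3": 132, "4": 138},
  "mean_silhouette": 0.499855,
  "feature_K": 12,
  "clusters_characterized": 4
}

| cluster | size | events (frequency) | diseases |
|---|---|---|---|
| 1 | 190 | G5 (0.63); G10 (0.61) | C3 (0.37); C4 (0.01); C5 (0.63) |
| 2 | 140 | G1 (0.84); G6 (0.83); G11 (0.81) | C1 (0.86); C3 (0.14) |
| 3 | 132 | G9 (0.88); G4 (0.86) | C3 (0.09); C4 (0.90); C5 (0.01) |
| 4 | 138 | G2 (0.88); G12 (0.86); G7 (0.82) | C2 (0.87); C3 (0.13) |
```

Reading this: the Thresher filter removed the 40 uninformative columns
(136 → 96). The Auer–Gervini step function flags two long steps — 4
(between-cluster contrasts) and 12 (the planted event count); the automatic
rule picks `K = 4`, so two of the five planted clusters are merged (cluster 1
mixes pseudo-diseases C3 and C5 and its top events only reach ~0.6
frequency), while the other clusters are pure and carry their planted events
at ~0.85 frequency, close to the planted 0.9 penetrance. Pinning
`manual_q=5` (as one would after inspecting the step plot) recovers the five
planted clusters essentially exactly. `feature_q=12` pins the feature-side
dimension at the other long step, recovering one event group per planted
event.

The same analysis is available from the shell:

```bash
cytopattern simulate --seed 42 --out sim/
cytopattern run --config run.yaml          # input/outdir/metric/... in YAML
cytopattern dist sim/matrix.tsv d.tsv --metric jaccard
cytopattern dim sim/matrix.tsv --out dim.json
cytopattern cluster d.tsv part.tsv --k auto --dim-report dim.json
cytopattern compare-metrics sim/matrix.tsv --metrics jaccard,sokal-michener
```

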