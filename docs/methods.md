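# Methods

This note documents the models, parameter choices and numerical details of
`eetnet`, and what the synthetic benchmarks do and do not establish.

## Study design being modelled

Six proteomic steady states span the O₂ downshift that activates
extracellular electron transfer (EET) in *Shewanella oneidensis* MR-1:
S1–S3 under high O₂ (EET inactive) and S4–S6 under low O₂ (EET active).
The analysis assumes the biologically meaningful signal is the S3→S4 step
of a protein's trajectory; everything downstream (networks, centrality,
motifs, modules, enrichment) operates on the proteins selected by that
step.

## Expression clustering

* **Zero filter.** A protein is "not expressed" only if all six abundances
  are exactly zero; any detection in any sample retains the row. No other
  missing-value handling is attempted.
* **Standardisation.** Rows are transformed to mean 0, sd 1 (population
  sd). This is the canonical preprocessing of the soft-clustering family
  used here: it makes trajectories comparable by shape rather than by
  absolute copy number. Constant non-zero rows cannot be standardised and
  are dropped with a warning.
* **Fuzzy c-means.** Classic Bezdek alternating optimisation with
  Euclidean distance: memberships `u_ij ∝ (1/d_ij²)^(1/(m−1))` normalised
  per protein, centroids as `u^m`-weighted means, objective
  `J = Σ u_ij^m d_ij²`. Defaults `c = 4`, `m = 1.5` (the published
  settings for this proteome), `tol = 1e-6` on the objective change,
  `max_iter = 1000`. Initial centroids are k-means++ seeded; `n_init = 10`
  restarts are run and the lowest final objective wins, because a single
  start can merge two archetypes into one cluster on unlucky seeds. A zero
  distance pins the membership on the coincident centroid. Hard labels are
  the argmax membership; ties go to the lowest cluster index.
* **Active-cluster rule.** For each centroid the five consecutive steps
  are examined; a cluster is *sharp* iff its |S3→S4| step is the largest
  and exceeds `sharp_ratio` (default 2.0) times the largest other step.
  Exactly one sharp-decreasing and one sharp-increasing cluster are
  required; otherwise the error lists every centroid's steps so the caller
  can adjust `sharp_ratio`. The factor 2 separates the four archetype
  shapes cleanly: for the sharp templates all other steps are ≈ 0, for the
  gradual templates the S3→S4 step is comparable to its neighbours.

## Network construction

* Confidence cutoffs are inclusive (`≥ t`), swept over 0.4–0.9 in steps of
  0.1 (0.4/0.7/0.9 are the conventional medium/high/highest labels).
  Input scores in the 0–999 integer dialect are divided by 1000
  (auto-detected per file).
* The active subnetwork keeps edges with **both** endpoints active; active
  proteins left without an edge are tracked as isolates and count toward
  the with-isolates protein totals. Regulatory arcs are kept when both TF
  and target are in the active scope (connected ∪ isolated). Because
  isolates are defined relative to the active set, the regulatory layer of
  the synthetic sweep is constant across thresholds; only the PPI layer
  shrinks.
* Integration keeps the layers distinct; a PPI edge counts as two directed
  arcs and a regulation as one, so `total_arcs = 2·|PPI| + |reg|` holds by
  construction and is re-asserted in `summarize`.

## Centrality ranking

Degree and unweighted shortest-path betweenness (Brandes accumulation;
endpoints excluded, each unordered pair counted once) are computed on the
undirected active PPI layer — isolated proteins cannot be hubs or
bottlenecks and are excluded. Each centrality is converted to fractional
(average-tie) ranks with rank 1 most central; a protein's score is the mean
of its two ranks, with residual ties broken by id for determinism. The
selection size is `k = round(0.02 · N_min)`, floored at 1, where `N_min` is
the smallest with-isolates node count across the six networks — one shared
k keeps the per-network lists comparable (0.02 · 1118 → 22). Frequency
aggregation counts in how many per-network lists a protein appears; within
equal-frequency blocks the order is by mean within-list position, then id.
The published table's internal order within frequency ties is not uniquely
determined by any printed rule, so only the frequencies themselves are
asserted against it.

## Motif analysis

* **Representation.** The integrated network is viewed as a directed graph
  in which a PPI edge is a mutual arc pair and a regulation a single arc.
  A pair carrying both a PPI edge and a regulatory arc collapses to a
  mutual pair (PPI priority) with a warning and a reported hybrid
  fraction; reciprocal regulations likewise form a mutual dyad.
* **Classification.** A triad's class is the minimum of its 6-bit
  arc-pattern code over the 3! node orderings, precomputed for all 64
  patterns. There are 13 connected classes; ten carry the motif names used
  for this system (Co-regulated PPI, Protein Clique, Co-regulated
  Proteins, PPI Regulating, Bi-feedforward Loop, Regulatory Cascade with a
  Feedback, Regulated PPI, Feedback with a PPI, Bi-regulated Protein,
  Regulatory Cascade) and the remaining three get descriptive names
  (Feedforward Loop, PPI Chain, PPI Chain with Regulation).
* **Census.** Connected triples are enumerated once each via sorted
  neighbour pairs around every node with de-duplication, equivalent to the
  exhaustive all-triples count (asserted against a brute-force oracle in
  the tests).
* **Null model.** Switching randomization: single arcs swap endpoints only
  with single arcs, mutual pairs only with mutual pairs; proposals that
  would create a self-loop, a duplicate, or convert between single and
  mutual are skipped. Every node's (single-in, single-out, mutual) degree
  triple is preserved exactly. Defaults: 1000 randomizations with
  100·(|single| + |mutual|) swap attempts each, both configurable; the
  orchestrated pipeline uses 100 randomizations per network as its
  desk-scale default.
* **Significance.** `z = (real − null mean)/null sd` (sample sd over the
  randomizations; ±∞ flagged when the null is degenerate) and empirical
  `p = P(null ≥ real)`; the under-representation tail is reported but
  never drives a call. A motif is *active* when significant (z > 2,
  p < 0.05) in at least `quorum` networks (default 5 of 6, which keeps a
  motif present in most-but-not-all networks while excluding classes seen
  in a single network). Exclusive motifs are active motifs absent from the
  supplied genus-conserved list.

## Module detection

Newman–Girvan modularity `M = Σᵢ (eᵢᵢ − aᵢ²)` on the undirected unweighted
PPI graph, computed by direct summation and cross-checked in tests against
an independent implementation. The annealer starts from singleton modules
and proposes single-node moves (90% into a random neighbour's module, else
a uniformly random module) with Metropolis acceptance `exp(ΔM/T)`, plus a
few module-merge proposals per temperature to escape over-fragmented
states; cooling is geometric (factor 0.995) and the best-seen partition is
returned, with the one-module partition (M = 0) always a candidate, so the
result never has M < 0. T₀ is calibrated so the median worsening move is
accepted with probability ½; because single-move ΔM scales like
`k²/(2m)²`, the temperature floor is relative (`10⁻⁴·T₀`), not absolute.
The stop rule is the floor or 50 temperatures without improvement. Module
detection in the pipeline runs on the largest connected component of the
PPI graph induced on the motif-involved proteins, with moves per
temperature capped at min(n², 2000) for large components.

## Enrichment

One-sided hypergeometric upper tail `P[X ≥ k]` per term (k query hits, K
term members within the background, n query size, N background size),
BH step-up FDR over the tested terms. Terms with fewer than 2 members or
covering more than 80% of the background are skipped and reported. The
default background is the set of expressed proteins (post zero-filter); a
supplied genome list can replace it. The proportion comparison reports
`|query ∩ category|/|query|` against `|category|/|genome|` and their
ratio.

## Synthetic data

Pre-noise templates over S1..S6: sharp decrease (1,1,1,−1,−1,−1), sharp
increase mirrored, fast-then-slow decrease (1.5,0.5,0,−0.2,−0.4,−0.5),
late increase (0,0,0,0,0.2,1.5), flat zeros, and exact-zero rows for
never-detected proteins. Abundances are
`baseline + scale·(template + N(0, noise_sd))`, truncated at 0, with
baseline 10 and scale 2 so values stay positive at realistic noise;
`noise_sd` is on the template scale where the activation step has height
2 (default 0.2, i.e. a 10:1 step-to-noise ratio). The default study mix is
250/200/180/160 proteins over the four archetypes plus 25 all-zero rows —
a desk-scale proteome preserving the published proportions of the two
sharp clusters. Interactomes carry Beta(2,2) confidence scores (nudged so
every standard threshold retains an edge) on either an Erdős–Rényi or a
Barabási–Albert graph; the study default is scale-free with mean degree 8.
The regulon draws 12 TFs with 13 distinct targets each (the ~13 targets/TF
density of bacterial regulon databases). One annotation term is planted
with 36 of its 40 members inside the designated query so it is
over-represented by construction (hypergeometric z ≈ 4 at the default
study size); 49 decoy terms are uniform draws. Planted motif excesses are
embedded as disjoint triads on fresh nodes, making the class census
additive. All generators are deterministic given their seed.

**What the benchmarks do not show.** Gaussian-on-template noise, the
absence of partially missing values, independence of expression and
network position, and uniform decoy annotations are simplifications; real
proteomics has peptide-level noise, batch structure and correlated
annotation terms. Passing recovery tests therefore demonstrates
correctness of the algorithms under the stated generative assumptions,
not performance guarantees on laboratory data. The published headline
counts (1012/811 active proteins, the per-threshold network sizes, the
motif z-scores) depend on the original proteome and interaction databases
and are reproduced only through their arithmetic identities and printed
tables, which `scripts/acceptance.py` recomputes.

## Problem sizes

The default test and acceptance runs use a ~800-protein study, 3-node
motif censuses on networks of up to ~1200 edges, 100–1000 switching
randomizations, 20-seed annealing replicates on 12–60-node graphs, and
50–100-seed enrichment replicates — sizes chosen so the full pipeline and
all property suites execute in minutes on one CPU while keeping every
statistical check well-powered.
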