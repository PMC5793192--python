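# eetnet

Network-based identification of the key **active proteins** that switch on
extracellular electron transfer (EET) in *Shewanella oneidensis* MR-1.

When O₂ runs out, *S. oneidensis* reroutes respiration onto extracellular
insoluble electron acceptors. A six-sample proteomic time course spanning the
shift (S1–S3 high O₂, S4–S6 low O₂) captures the transition: proteins whose
abundance steps sharply between S3 and S4 are the candidates that activate
EET. `eetnet` implements the complete downstream analysis as a reusable,
tested pipeline that runs end-to-end on synthetic data with known ground
truth:

1. **Expression clustering** — drop never-detected proteins, row-standardise
   the six-sample trajectories, fuzzy c-means (c = 4, fuzzifier m = 1.5);
   the two clusters with a sharp S3→S4 centroid step (down and up) define
   the active-protein set.
2. **Network construction** — filter a scored interactome at confidence
   thresholds 0.4–0.9, induce the subnetwork on the active proteins, add
   TF→target regulatory arcs, and integrate into a mixed graph with the arc
   accounting `total_arcs = 2·|PPI| + |regulatory|`.
3. **Centrality ranking** — per network, rank proteins by the mean of their
   degree rank (hubs) and betweenness rank (bottlenecks); keep the top 2% of
   the smallest network size; aggregate key-protein frequency across the six
   networks.
4. **Motif analysis** — census of the 13 connected 3-node classes of the
   mixed graph (a PPI edge is a mutual arc pair, a regulation a single arc),
   z-scores and empirical p against degree-preserving switching nulls, motif
   calls at a quorum of networks, and *exclusive* motifs = active minus the
   genus-conserved list.
5. **Module detection** — Newman modularity `M = Σᵢ (eᵢᵢ − aᵢ²)` maximised
   by simulated annealing on the largest connected component of the
   motif-protein interaction network.
6. **Enrichment** — hypergeometric over-representation with
   Benjamini–Hochberg FDR, plus query-vs-genome proportion comparison.

The `synthetic_data` generators are first-class: they emulate the archetypal
trajectories, all-zero rows, scored interactome, sparse regulon, planted
motif excesses, planted communities and planted enriched terms, and return
the ground truth so every stage is scored for parameter recovery.

## Worked example

```python
from eetnet import synthetic as syn, clustering as cl, network as nw

study = syn.simulate_study(syn.ScenarioConfig(seed=1))
std = cl.standardize(cl.filter_unexpressed(study.expression))
fit = cl.fuzzy_cmeans(std, cl.ClusteringConfig(c=4, m=1.5, seed=1))
active = cl.identify_active_clusters(fit)
print(len(active.down_set), len(active.up_set), len(active.union))

networks = nw.build_thresholded_networks(study.edges, study.arcs,
                                         active.union)
print(nw.stats_table(networks).to_string())
```

prints

```
251 201 452
                  proteins_connected  proteins_with_isolates  ppi_interactions  reg_genes  reg_interactions  total_nodes  total_arcs
confidence_score
CS_0.4                           446                     450              1169         62                57          448        2395
CS_0.5                           436                     449               885         62                57          439        1827
CS_0.6                           411                     446               635         62                57          417        1327
CS_0.7                           341                     439               396         62                57          354         849
CS_0.8                           232                     422               190         62                57          262         437
CS_0.9                            88                     402                51         62                57          138         159
```

— 452 of the 450 truly sharp-transition proteins were called active (the
planted labels are recovered essentially perfectly at this noise level), and
every integrated network satisfies `total_arcs = 2·PPI + regulatory` while
shrinking monotonically with the confidence threshold.

The same pipeline is available from the shell:

```sh
eetnet simulate --outdir study --seed 1
eetnet cluster --expression study/expression.tsv --seed 1 --outdir clu
eetnet run-all --outdir run --seed 1
```

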