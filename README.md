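# somscreen

Cluster compounds by their quantitative high-throughput-screening
(qHTS) bioactivity profiles and find the gene targets and pathways
overrepresented in each cluster — the computational core of an
activity-based drug-repurposing workflow.

## The problem

Screening a large compound library against a panel of in-vitro assays
yields, per compound, a vector of *curve ranks*: integer-scaled scores
in [−9, 9] summarising the potency, efficacy and quality of each
concentration–response (positive = activation, negative = inhibition
of the assay target). Compounds with similar activity profiles are
likely to share targets or modes of action, so clusters in profile
space are candidate groups for repurposing: if most members of a
cluster hit a known target family, the unannotated members become
hypotheses worth following up.

`somscreen` implements that pipeline end to end:

1. **SOM clustering** — a self-organizing map trained online with
   Euclidean distance; each compound's cluster is its best-matching
   unit (BMU).
2. **Cluster merging** — clusters with fewer than 15 compounds are
   merged into their most-correlated partner by complete-linkage
   agglomeration over the Pearson distance `1 − r` between cluster
   centroids; the merged cluster keeps the label of its larger
   constituent.
3. **Annotation joining** — compounds are matched to gene-target
   tables through InChIKey block 1 (the first 14 characters, computed
   on the longest dot-separated SMILES component), a salt- and
   stereo-insensitive structure key.
4. **Gene-target enrichment** — per (cluster, gene), a 2×2 table over
   the annotated universe and a one-tailed Fisher exact test
   `P(X ≥ a)`; all p-values pooled into a beta-uniform mixture (BUM)

   ```
   f(p) = λ + (1 − λ) a p^(a−1),   0 < a < 1,  0 ≤ λ ≤ 1
   ```

   whose fit yields the null-proportion bound `π̂ = λ + (1 − λ)a` and a
   p-value cutoff τ with estimated FDR
   `π̂τ / (λτ + (1 − λ)τ^a)` equal to the requested level (default 1%).
5. **Pathway enrichment** — Fisher tests of each cluster's enriched
   genes against GMT gene sets over a gene background, Holm-adjusted
   within the cluster, plus a randomized-cluster null (annotation sets
   permuted as blocks across compounds, cluster sizes preserved).
6. **Structural validation** — intra- vs inter-cluster mean Tanimoto
   similarity of circular (Morgan) fingerprints: activity-derived
   clusters should be more structurally coherent than chance.

A synthetic-data module generates activity matrices, annotation
tables, fingerprints and gene sets with *planted* cluster and gene
structure, so every stage is testable without external databases.

## Worked example

```bash
python examples/simulate_and_cluster.py
```

```
activity matrix: 400 compounds x 20 assays, values in [-9.0, 9.0]
SOM: 4 non-empty units, quantization error 4.036
after merging: 4 clusters, smallest has 100 compounds
adjusted Rand index vs planted clusters: 1.000
```

Four hundred synthetic compounds in four latent activity clusters are
clustered perfectly (ARI 1.0) by a 3×3 map after merging. Enrichment
then recovers the planted biology (`examples/gene_enrichment.py`):

```
50 (cluster, gene) tests, adjustment=bum_fdr, 10 significant at FDR 1%
  cluster 0: enriched ['GENE0000', 'GENE0001'] = planted
  ...
```

Every planted gene — and nothing else — is called significant in its
own cluster. `examples/full_pipeline.py` runs all stages through the
orchestrator and prints the pathway null comparison (here 4
significant pathways in the actual clustering vs a median of 0 in 10
randomized clusterings) and the structural summary (intra-cluster mean
Tanimoto 0.505 vs 0.083 between clusters).

The same stages are exposed as a CLI:

```bash
somscreen simulate --out inputs --seed 1
somscreen run-all --config config.yaml
```

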