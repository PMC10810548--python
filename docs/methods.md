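# Methods

This note documents the models, defaults and design choices behind
`somscreen`, and what the synthetic benchmarks do and do not show.

## Activity data model

The pipeline consumes a dense compound × assay matrix of curve ranks:
integer-scaled activity scores in [−9, 9] that summarise potency,
efficacy and curve quality of a concentration–response (positive =
activation, negative = inhibition). Compounds with incomplete assay
coverage are dropped at load time (the count is logged); values
outside [−9, 9] are rejected as format errors. No feature scaling is
applied before clustering: curve ranks already share one bounded
scale across assays.

## Self-organizing map

Training is the classic online Kohonen scheme. The codebook (one
prototype profile per grid unit) is initialised from randomly sampled
data rows. For each presented row the best-matching unit (BMU,
minimal Euclidean distance) and its neighbours are pulled toward the
row:

    w_u ← w_u + η(t) · exp(−d(u, bmu)² / 2σ(t)²) · (x − w_u)

with grid distance `d`, learning rate `η` decaying linearly from 0.05
to 0.01 and radius `σ` decaying linearly from half the larger grid
dimension to 0.25 over all `epochs × n` steps. Defaults: 12×12
rectangular grid, Gaussian neighbourhood, 100 epochs. Updates are
convex, so codebook entries never leave the per-assay range of the
training data. Everything — initialisation and per-epoch presentation
order — derives from one seed; identical seeds give bit-identical
codebooks.

A *cluster* is a non-empty unit after BMU assignment (ties in
distance break toward the lowest unit index). A one-dimensional or
very elongated map can fold, mapping two latent archetypes onto one
unit from unlucky initialisations; the tests therefore demand exact
recovery in all seeds only for the well-posed two-blob configuration,
and in most seeds for harder ones.

## Small-cluster merging

Gene enrichment is unreliable in clusters of a handful of compounds,
so clusters below `min_size` (default 15) are consolidated. The
distance between clusters is the Pearson correlation distance
`1 − r` between centroids (member-mean profiles); group-to-group
distance is complete linkage (maximum pairwise distance over original
centroids). Iteratively, the smallest undersized cluster merges with
its nearest partner; the merged cluster keeps the label of the larger
constituent (ties → lower label) and its centroid is the
size-weighted constituent mean, identical to the pooled-member mean.
Iteration — rather than a single agglomeration pass — is the policy
that actually guarantees the size floor; it stops when no cluster is
undersized or one cluster remains. Correlation against a constant
centroid is undefined and raises rather than guessing.

## Structure keys and annotation joining

Compounds join annotation tables through InChIKey block 1: the first
14 characters of the standard InChIKey, computed on the *primary
component* of the structure — the longest dot-separated SMILES
component (ties → lexicographically smallest). Block 1 encodes the
skeleton only, so salt forms and stereoisomers of one parent share a
key. Charges on the retained component are deliberately not
neutralised: block 1 already collapses protonation variants that
share a skeleton, and a charge-normalisation pipeline is out of
scope. Unparseable structures become logged mapping-failure records,
not crashes — large libraries routinely lose a few compounds here.
Joining takes the union of (key, gene) pairs across sources,
restricted to the supplied compound list, collapsing duplicates with
`;`-joined source labels.

## Gene-target enrichment

For cluster *c* and gene *g* the 2×2 table partitions the *annotated
universe* (every assigned compound with ≥ 1 gene annotation):

|                | targets g | does not target g |
|----------------|-----------|-------------------|
| inside c       | a         | b                 |
| outside c      | c         | d                 |

"Does not target g" includes compounds annotated to other genes — a
compound may target several genes, and only this reading keeps the
four cells a partition, which the Fisher test requires. The one-tailed
p-value is the hypergeometric upper tail `P(X ≥ a)` at the table's
margins (all-zero table → 1 by convention).

All (cluster, gene) p-values — one test per gene with at least one
annotated compound in the cluster — are pooled into a single
beta-uniform mixture fit:

    f(p) = λ + (1 − λ) a p^(a−1),   0 < a < 1, 0 ≤ λ ≤ 1

maximised by seeded multi-start (10 starts) bounded L-BFGS-B, with
p-values clamped to a floor of 1e−12 (the beta term diverges at 0).
The mixture density at p = 1 bounds the null proportion from above,
π̂ = λ + (1 − λ)a, and the significance cutoff is the closed form

    τ = [ (π̂ − αλ) / (α(1 − λ)) ]^(1/(a−1))

at which the estimated FDR `π̂τ / (λτ + (1 − λ)τ^a)` equals α (default
1%). A pure-null fit (λ = 1), or no τ in (0, 1), yields no cutoff and
no significant calls. One pooled fit across all clusters (not
per-cluster fits) matches the single global cutoff the pipeline is
designed around.

Mixture-shape estimation needs a reasonable sample: below 50 pooled
p-values the fit refuses, and `cluster_gene_enrichment` falls back to
step-down Holm adjustment at the same α. Small families get
family-wise control instead of an unstable FDR estimate.

## Pathway enrichment and the randomized null

Each cluster's *enriched* genes (the significant calls above) are
tested against GMT gene sets with the same one-tailed Fisher test,
over a gene background equal to the union of all annotated genes and
all gene-set members. P-values are Holm-adjusted within the cluster;
significance is adjusted p ≤ 0.05. Testing enriched genes (rather
than all genes of cluster compounds) is the default; the alternative
is a one-line change at the call site since `pathway_enrichment`
accepts any per-cluster gene sets.

The randomized null rebuilds the entire gene-then-pathway analysis
after permuting each compound's annotation set *as a block* across
compounds: cluster sizes and the global multiset of annotation sets
are untouched; only the pairing of activity profile to annotations is
destroyed. A clustering that captures real pharmacology should yield
many more significant pathways than its permuted counterparts.

## Structural validation

Circular (Morgan) fingerprints — radius 2, 2048 bits, the community
default for Tanimoto comparisons — are computed on primary-component
SMILES. The summary statistic is the mean Tanimoto `|A∩B| / |A∪B|`
over same-cluster pairs versus different-cluster pairs (empty∩empty
→ 0: featureless molecules carry no similarity evidence). Strata
larger than 1,000,000 pairs are scored on a seeded uniform subsample,
with the subsample size reported.

## Synthetic data: what it emulates and what it does not

The generator plants known structure at every level:

* **Activity**: each latent cluster has an archetype profile drawn
  per assay from {−9, −6, −3, 0, 3, 6, 9} (mimicking curve-rank
  discreteness); members are archetype + iid Gaussian noise
  (`noise_sd`, default 1.0), hard-clipped to [−9, 9]. Archetypes are
  redrawn on collision or constancy so they are pairwise distinct and
  non-constant — constant profiles would make the Pearson merge
  distance undefined. Cluster sizes are balanced to within one.
* **Keys**: compound keys are deterministic 14-uppercase-letter
  hashes of the compound ID, shaped like InChIKey block 1, so the
  annotation join is exercised without structure generation.
* **Annotations**: each cluster's planted genes (disjoint across
  clusters) annotate members with probability `enrichment_prob`
  (default 0.6) and everyone else with `background_prob` (default
  0.05). The default of 5 genes per cluster reflects that real
  activity clusters are enriched for a handful of targets, not one.
* **Fingerprints**: per-cluster random bit patterns (density 0.1)
  with independent per-bit flips (probability 0.05) per compound.
* **Pathways**: one gene set per cluster containing its planted genes
  plus 10 random decoy genes.

Not emulated: concentration–response curve fitting, assay-specific
mechanisms, real chemical structures, inter-gene correlation, and the
heavy-tailed cluster-size distributions of real screening libraries.
Passing the synthetic benchmarks shows the machinery is correct and
well-calibrated under the planted model; it does not certify recovery
rates on real qHTS data, where signal strength and annotation
coverage are far less favourable.

## Numerical choices and degenerate inputs

* Fisher: `scipy.stats.hypergeom.sf`, verified against exhaustive
  tail enumeration for every table with N ≤ 30 to 1e−10.
* BUM: bounds a ∈ (1e−6, 1−1e−6), λ ∈ [0, 1]; density floored at
  1e−300 inside the log-likelihood; the cutoff's closed form is
  verified against a bisection root of the FDR expression to 1e−9.
* Holm: `statsmodels.stats.multitest.multipletests(method="holm")`.
* Ties: BMU assignment → lowest unit index; primary-component length
  ties → lexicographically smallest; merge-survivor ties → lower
  label.
* Determinism: one global seed fans out to per-stage seeds via a
  stable SHA-256 hash of the stage name, so adding a stage never
  perturbs another stage's randomness; manifests carry content
  checksums and no timestamps, making identical runs byte-identical.

## Problem sizes in the shipped benchmarks

The test suite and the reproduction script use simulated libraries of
200–600 compounds, 4–5 latent clusters, 12–20 assays, SOM grids up to
4×4, 20-seed replication for stochastic claims, and 20 randomized
null replicates — sizes chosen so the planted effects are comfortably
detectable while the full suite runs in well under a minute per
module. The pipeline itself is routinely run at library scale
(thousands of compounds, 12×12 grids, millions of Tanimoto pairs via
the subsampling cap).

## Known limitations

* Online (per-sample) SOM training only; no batch SOM or toroidal
  topologies.
* The BUM cutoff returns none when no τ in (0, 1) attains the
  requested FDR — including the benign case where the requested level
  exceeds the estimated FDR at every threshold; callers see "no
  significant calls" rather than "everything significant" in that
  regime.
* Complete linkage is the only tested agglomeration; the merge
  routine is not a general dendrogram-cutting tool.
* Charge states are not normalised before key generation; a salt
  whose counter-ion is the longer SMILES component would be mis-keyed
  (the longest-component rule is applied literally).
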