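"""Synthetic qHTS-style data with planted cluster structure.

Every downstream stage — SOM clustering, merging, annotation joining,
enrichment, structural validation — is testable against a known ground
truth generated here. The generator emulates:

* an activity matrix whose rows fall into latent clusters: each cluster
  has an archetype profile on the curve-rank grid {-9, -6, -3, 0, 3, 6, 9}
  and members are archetype + iid Gaussian noise, hard-clipped to [-9, 9];
* annotation tables in which each cluster's planted genes annotate
  members with probability ``enrichment_prob`` and non-members with
  probability ``background_prob``;
* binary fingerprints that are per-cluster seed patterns with
  independent per-bit flips, so intra-cluster Tanimoto similarity
  exceeds inter-cluster similarity;
* gene sets grouping each cluster's planted genes into a pathway,
  optionally padded with decoy genes.

All outputs are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

import hashlib
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import (
    CURVE_RANK_MAX,
    CURVE_RANK_MIN,
    ActivityMatrix,
    AnnotationRecord,
    AnnotationTable,
    FingerprintSet,
    GeneSetCollection,
)

ARCHETYPE_LEVELS = np.array([-9.0, -6.0, -3.0, 0.0, 3.0, 6.0, 9.0])


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator.

    labels maps compound_id -> latent cluster index in [0, n_clusters);
    archetypes is the n_clusters x n_assays matrix of cluster mean
    profiles; planted_genes maps cluster index -> its (disjoint) gene
    symbols; params records every generator parameter plus the seed.
    """

    labels: dict[str, int]
    archetypes: np.ndarray
    planted_genes: dict[int, list[str]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.archetypes.shape[0]

    def members(self, cluster: int) -> list[str]:
        return [cid for cid, lab in self.labels.items() if lab == cluster]

    def all_planted_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.planted_genes.values():
            out.update(genes)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels,
            "archetypes": self.archetypes.tolist(),
            "planted_genes": {str(k): v for k, v in self.planted_genes.items()},
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            labels={k: int(v) for k, v in payload["labels"].items()},
            archetypes=np.asarray(payload["archetypes"], dtype=float),
            planted_genes={int(k): list(v) for k, v in payload["planted_genes"].items()},
            params=payload["params"],
        )


def compound_key_for(compound_id: str) -> str:
    """Deterministic 14-uppercase-letter key in the shape of InChIKey block 1.

    Lets annotation joining be exercised without generating real
    structures: the key is a stable hash of the compound identifier.
    """
    digest = hashlib.sha256(compound_id.encode()).digest()
    letters = string.ascii_uppercase
    return "".join(letters[b % 26] for b in digest[:14])


def _draw_archetypes(rng: np.random.Generator, n_clusters: int, n_assays: int) -> np.ndarray:
    """Uniform draws from the curve-rank levels, redrawn until rows are
    pairwise distinct and non-constant (constant profiles have undefined
    Pearson correlation downstream)."""
    rows: list[tuple[float, ...]] = []
    seen: set[tuple[float, ...]] = set()
    attempts = 0
    while len(rows) < n_clusters:
        row = tuple(rng.choice(ARCHETYPE_LEVELS, size=n_assays))
        attempts += 1
        if attempts > 1000 * n_clusters:
            raise ValueError(
                f"cannot draw {n_clusters} distinct non-constant archetypes "
                f"over {n_assays} assays"
            )
        if len(set(row)) < 2 or row in seen:
            continue
        seen.add(row)
        rows.append(row)
    return np.array(rows)


def generate_activity_matrix(
    n_compounds: int,
    n_assays: int,
    n_clusters: int,
    noise_sd: float,
    seed: int,
) -> tuple[ActivityMatrix, SyntheticTruth]:
    """Activity matrix with latent cluster structure.

    Compounds are spread over clusters as evenly as possible (cluster
    sizes differ by at most one) and shuffled; each row is its cluster
    archetype plus iid N(0, noise_sd^2) noise, clipped to [-9, 9].
    """
    if n_compounds <= 0 or n_assays <= 0 or n_clusters <= 0:
        raise ValueError("n_compounds, n_assays and n_clusters must be positive")
    if n_clusters > n_compounds:
        raise ValueError("n_clusters cannot exceed n_compounds")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_assays < 2:
        raise ValueError("need at least 2 assays for non-constant archetypes")

    rng = np.random.default_rng(seed)
    archetypes = _draw_archetypes(rng, n_clusters, n_assays)
    labels_arr = rng.permutation(np.arange(n_compounds) % n_clusters)
    values = archetypes[labels_arr]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, CURVE_RANK_MIN, CURVE_RANK_MAX)

    width = max(4, len(str(n_compounds)))
    compound_ids = [f"C{i:0{width}d}" for i in range(n_compounds)]
    assay_ids = [f"assay-{j:03d}" for j in range(n_assays)]

    matrix = ActivityMatrix(tuple(compound_ids), tuple(assay_ids), values)
    truth = SyntheticTruth(
        labels=dict(zip(compound_ids, (int(x) for x in labels_arr))),
        archetypes=archetypes,
        params={
            "n_compounds": n_compounds,
            "n_assays": n_assays,
            "n_clusters": n_clusters,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    return matrix, truth


def generate_annotations(
    truth: SyntheticTruth,
    genes_per_cluster: int,
    enrichment_prob: float,
    background_prob: float,
    seed: int,
) -> AnnotationTable:
    """Annotation table with planted per-cluster gene-target signal.

    Plants ``genes_per_cluster`` disjoint gene symbols per cluster and
    annotates each to cluster members with probability
    ``enrichment_prob`` and to every other compound with probability
    ``background_prob``. Records the planted genes on ``truth``.
    """
    if genes_per_cluster <= 0:
        raise ValueError("genes_per_cluster must be positive")
    for name, p in (("enrichment_prob", enrichment_prob), ("background_prob", background_prob)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if background_prob > enrichment_prob:
        raise ValueError("background_prob cannot exceed enrichment_prob")

    rng = np.random.default_rng(seed)
    planted: dict[int, list[str]] = {
        c: [f"GENE{c:02d}{g:02d}" for g in range(genes_per_cluster)]
        for c in range(truth.n_clusters)
    }
    truth.planted_genes = planted
    truth.params.update(
        {
            "genes_per_cluster": genes_per_cluster,
            "enrichment_prob": enrichment_prob,
            "background_prob": background_prob,
            "annotation_seed": seed,
        }
    )

    compound_ids = sorted(truth.labels)
    records: list[AnnotationRecord] = []
    for cluster in range(truth.n_clusters):
        for gene in planted[cluster]:
            for cid in compound_ids:
                p = enrichment_prob if truth.labels[cid] == cluster else background_prob
                if rng.random() < p:
                    records.append(
                        AnnotationRecord(compound_key_for(cid), gene, "synthetic")
                    )
    return AnnotationTable(records)


def generate_fingerprints(
    truth: SyntheticTruth,
    n_bits: int,
    intra_flip_prob: float,
    inter_seed_density: float,
    seed: int,
) -> FingerprintSet:
    """Binary fingerprints that are structurally coherent within clusters.

    Each cluster receives a random seed pattern (each bit on with
    probability ``inter_seed_density``); each compound's fingerprint is
    its cluster's pattern with independent per-bit flips at
    ``intra_flip_prob``.
    """
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    for name, p in (("intra_flip_prob", intra_flip_prob), ("inter_seed_density", inter_seed_density)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    patterns = rng.random((truth.n_clusters, n_bits)) < inter_seed_density
    fingerprints: dict[str, frozenset[int]] = {}
    for cid in sorted(truth.labels):
        bits = patterns[truth.labels[cid]].copy()
        if intra_flip_prob > 0:
            flips = rng.random(n_bits) < intra_flip_prob
            bits ^= flips
        fingerprints[cid] = frozenset(int(i) for i in np.flatnonzero(bits))
    truth.params.update(
        {
            "n_bits": n_bits,
            "intra_flip_prob": intra_flip_prob,
            "inter_seed_density": inter_seed_density,
            "fingerprint_seed": seed,
        }
    )
    return FingerprintSet(n_bits, fingerprints)


def generate_pathways(
    truth: SyntheticTruth,
    sets_per_cluster: int,
    extra_genes_per_set: int,
    seed: int,
) -> GeneSetCollection:
    """Gene sets grouping planted genes, padded with decoys.

    Each set holds one cluster's full planted gene list plus
    ``extra_genes_per_set`` random decoy genes (symbols disjoint from all
    planted genes). Requires generate_annotations to have planted genes.
    """
    if sets_per_cluster <= 0:
        raise ValueError("sets_per_cluster must be positive")
    if extra_genes_per_set < 0:
        raise ValueError("extra_genes_per_set must be nonnegative")
    if not truth.planted_genes:
        raise ValueError("truth has no planted genes; run generate_annotations first")

    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    decoy_pool = [f"DECOY{i:04d}" for i in range(max(1000, 10 * extra_genes_per_set))]
    for cluster, genes in sorted(truth.planted_genes.items()):
        for s in range(sets_per_cluster):
            name = f"PW_C{cluster:02d}_S{s}"
            decoys = (
                [decoy_pool[i] for i in rng.choice(len(decoy_pool), extra_genes_per_set, replace=False)]
                if extra_genes_per_set
                else []
            )
            sets[name] = list(genes) + decoys
            descriptions[name] = f"planted pathway for latent cluster {cluster}"
    return GeneSetCollection(sets, descriptions)
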