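"""Structural validation of activity-based clusters.

Clusters built purely from bioassay activity should still be more
structurally coherent than chance: compounds inside a cluster share
higher Tanimoto fingerprint similarity than compounds from different
clusters. This module computes circular (Morgan-type) fingerprints and
the intra- vs inter-cluster Tanimoto summary that quantifies the
effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import STATUS_OK, CompoundRecord
from .containers import ClusterAssignment, FingerprintSet

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048
DEFAULT_MAX_PAIRS = 1_000_000


def tanimoto(fp1: frozenset[int] | set[int], fp2: frozenset[int] | set[int]) -> float:
    """|intersection| / |union| of two bit sets; empty vs empty -> 0.0."""
    union = len(fp1 | fp2)
    if union == 0:
        return 0.0
    return len(fp1 & fp2) / union


def structure_fingerprints(
    compounds: list[CompoundRecord],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> FingerprintSet:
    """Circular hashed fingerprints of each compound's primary component.

    Compounds whose SMILES cannot be parsed (or which carry no
    structure) are skipped with a log entry.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fingerprints: dict[str, frozenset[int]] = {}
    skipped = 0
    for rec in compounds:
        smiles = rec.smiles_primary or rec.smiles_raw
        if rec.status != STATUS_OK or not smiles:
            skipped += 1
            continue
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            skipped += 1
            logger.warning("skipping unparseable structure for %s", rec.compound_id)
            continue
        fp = gen.GetFingerprint(mol)
        fingerprints[rec.compound_id] = frozenset(fp.GetOnBits())
    if skipped:
        logger.info("fingerprints skipped for %d/%d compounds", skipped, len(compounds))
    return FingerprintSet(n_bits, fingerprints)


@dataclass
class SimilaritySummary:
    intra_mean: float
    inter_mean: float
    n_intra_pairs: int
    n_inter_pairs: int
    subsampled: bool
    n_missing_fingerprints: int

    def as_dict(self) -> dict:
        return {
            "intra_mean": self.intra_mean,
            "inter_mean": self.inter_mean,
            "n_intra_pairs": self.n_intra_pairs,
            "n_inter_pairs": self.n_inter_pairs,
            "subsampled": self.subsampled,
            "n_missing_fingerprints": self.n_missing_fingerprints,
        }


def intra_inter_summary(
    fps: FingerprintSet,
    assignment: ClusterAssignment,
    max_pairs_per_stratum: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> SimilaritySummary:
    """Mean Tanimoto over same-cluster and different-cluster pairs.

    Assigned compounds lacking a fingerprint are excluded (their count
    is reported). When a stratum holds more than
    ``max_pairs_per_stratum`` pairs, a seeded uniform subsample of
    pairs is scored and the subsample size reported.
    """
    ids = sorted(cid for cid in assignment.mapping if cid in fps.fingerprints)
    missing = len(assignment.mapping) - len(ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 compounds with fingerprints")
    labels = np.asarray([assignment.mapping[cid] for cid in ids])

    # dense bit matrix -> all pairwise intersection counts in one matmul
    bits = np.zeros((len(ids), fps.n_bits), dtype=np.uint8)
    for row, cid in enumerate(ids):
        idx = list(fps.fingerprints[cid])
        if idx:
            bits[row, idx] = 1
    inter_counts = (bits.astype(np.int32) @ bits.T.astype(np.int32)).astype(float)
    sizes = bits.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter_counts
    with np.errstate(divide="ignore", invalid="ignore"):
        tani = np.where(union > 0, inter_counts / union, 0.0)

    iu, ju = np.triu_indices(len(ids), k=1)
    same = labels[iu] == labels[ju]
    rng = np.random.default_rng(seed)

    def stratum_mean(mask: np.ndarray) -> tuple[float, int, bool]:
        idx = np.flatnonzero(mask)
        sub = False
        if idx.size > max_pairs_per_stratum:
            idx = rng.choice(idx, size=max_pairs_per_stratum, replace=False)
            sub = True
        if idx.size == 0:
            return float("nan"), 0, sub
        return float(tani[iu[idx], ju[idx]].mean()), int(idx.size), sub

    intra_mean, n_intra, sub_a = stratum_mean(same)
    inter_mean, n_inter, sub_b = stratum_mean(~same)
    return SimilaritySummary(
        intra_mean=intra_mean,
        inter_mean=inter_mean,
        n_intra_pairs=n_intra,
        n_inter_pairs=n_inter,
        subsampled=sub_a or sub_b,
        n_missing_fingerprints=missing,
    )
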