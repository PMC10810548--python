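"""Consolidation of undersized SOM clusters.

SOM cluster sizes are uneven, and very small clusters weaken the
downstream gene-target enrichment tests. Clusters below a size floor
(default 15 compounds) are therefore merged into the cluster they
correlate with most strongly: complete-linkage agglomeration over the
Pearson-correlation distance between cluster centroids, iterated until
every cluster reaches the floor or a single cluster remains.

The merged cluster keeps the label of its larger constituent (ties:
the lower label), so surviving labels stay stable across merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ActivityMatrix, ClusterAssignment

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 15


def pearson_distance(x, y) -> float:
    """1 - r for the Pearson correlation r of two equal-length vectors.

    Ranges over [0, 2]: 0 for perfectly correlated, 2 for perfectly
    anti-correlated profiles. Undefined (raises) for constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("pearson_distance needs two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def compute_centroids(matrix: ActivityMatrix, assignment: ClusterAssignment) -> pd.DataFrame:
    """Per-cluster arithmetic mean profile, one row per cluster label."""
    frame = matrix.to_frame()
    missing = [cid for cid in assignment.mapping if cid not in frame.index]
    if missing:
        raise ValueError(f"assigned compounds missing from matrix: {missing[:5]}")
    labels = pd.Series({cid: lab for cid, lab in assignment.mapping.items()})
    sub = frame.loc[labels.index]
    centroids = sub.groupby(labels).mean()
    centroids.index.name = "cluster_id"
    return centroids.sort_index()


@dataclass
class MergeStep:
    step: int
    absorbed_label: int
    surviving_label: int
    linkage_distance: float


@dataclass
class MergeResult:
    assignment: ClusterAssignment
    centroids: pd.DataFrame
    log: list[MergeStep]

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.step, s.absorbed_label, s.surviving_label, s.linkage_distance) for s in self.log],
            columns=["step", "absorbed_label", "surviving_label", "linkage_distance"],
        )


def merge_small_clusters(
    assignment: ClusterAssignment,
    centroids: pd.DataFrame,
    min_size: int = DEFAULT_MIN_SIZE,
) -> MergeResult:
    """Iteratively merge clusters smaller than ``min_size``.

    At each step the smallest undersized cluster (ties: lower label) is
    merged with its nearest partner under complete linkage — the
    partner minimising the maximum Pearson distance between any pair of
    original centroids across the two groups. The merge keeps the label
    of the larger constituent (ties: lower label); the reported merged
    centroid is the size-weighted constituent mean, identical to the
    centroid of the pooled members. Iteration stops when no cluster is
    undersized or one cluster remains.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    sizes = assignment.sizes
    labels = sorted(sizes)
    missing = [lab for lab in labels if lab not in centroids.index]
    if missing:
        raise ValueError(f"centroids missing for clusters: {missing[:5]}")

    base = centroids.loc[labels].to_numpy(dtype=float)
    index_of = {lab: i for i, lab in enumerate(labels)}
    # pairwise Pearson distance between original centroids
    if len(labels) > 1:
        with np.errstate(invalid="raise"):
            sd = base.std(axis=1)
            if np.any(sd == 0):
                bad = [labels[i] for i in np.flatnonzero(sd == 0)]
                raise ValueError(f"constant centroid, Pearson undefined: clusters {bad}")
            corr = np.corrcoef(base)
        dist0 = 1.0 - corr
        np.fill_diagonal(dist0, 0.0)
    else:
        dist0 = np.zeros((1, 1))

    groups: dict[int, set[int]] = {lab: {index_of[lab]} for lab in labels}
    group_sizes: dict[int, int] = dict(sizes)
    log: list[MergeStep] = []

    def complete_linkage(g1: int, g2: int) -> float:
        rows = sorted(groups[g1])
        cols = sorted(groups[g2])
        return float(dist0[np.ix_(rows, cols)].max())

    step = 0
    while len(groups) > 1:
        undersized = sorted(
            (lab for lab, n in group_sizes.items() if n < min_size),
            key=lambda lab: (group_sizes[lab], lab),
        )
        if not undersized:
            break
        small = undersized[0]
        partners = sorted(lab for lab in groups if lab != small)
        dists = [(complete_linkage(small, lab), lab) for lab in partners]
        link, partner = min(dists)
        # label retention: larger constituent wins, ties -> lower label
        if group_sizes[partner] > group_sizes[small] or (
            group_sizes[partner] == group_sizes[small] and partner < small
        ):
            survivor, absorbed = partner, small
        else:
            survivor, absorbed = small, partner
        step += 1
        log.append(MergeStep(step, absorbed, survivor, link))
        groups[survivor] |= groups.pop(absorbed)
        group_sizes[survivor] += group_sizes.pop(absorbed)

    relabel: dict[int, int] = {}
    for survivor, members in groups.items():
        for idx in members:
            relabel[labels[idx]] = survivor
    merged = ClusterAssignment(
        {cid: relabel[lab] for cid, lab in assignment.mapping.items()}
    )

    # size-weighted mean of constituent centroids == centroid of pooled members
    weights = pd.Series(sizes, dtype=float)
    rows = {}
    for survivor, members in sorted(groups.items()):
        labs = [labels[i] for i in sorted(members)]
        w = weights.loc[labs].to_numpy()
        rows[survivor] = (centroids.loc[labs].to_numpy() * w[:, None]).sum(axis=0) / w.sum()
    merged_centroids = pd.DataFrame.from_dict(rows, orient="index", columns=centroids.columns)
    merged_centroids.index.name = "cluster_id"
    merged_centroids = merged_centroids.sort_index()

    logger.info(
        "merged %d clusters into %d (min_size=%d, %d merge steps)",
        len(labels), len(groups), min_size, len(log),
    )
    return MergeResult(merged, merged_centroids, log)
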