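"""In-memory containers shared across the pipeline stages.

The pipeline moves four kinds of data between stages: a compound x assay
activity matrix of curve ranks, a compound -> cluster assignment, a
compound-key -> gene annotation table, and named gene sets (pathways).
Each container validates its invariants on construction so that file
readers, the synthetic generator and the clustering stages all hand the
same guarantees downstream.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CURVE_RANK_MIN = -9.0
CURVE_RANK_MAX = 9.0

#: InChIKey block 1 — 14 uppercase letters encoding the molecular skeleton.
KEY14_PATTERN = re.compile(r"^[A-Z]{14}$")


class FormatError(ValueError):
    """A file or table violates the expected structure."""


@dataclass(frozen=True)
class ActivityMatrix:
    """Compound x assay table of qHTS curve ranks.

    Curve ranks are integer-scaled activity scores in [-9, 9]; positive
    values indicate activation of the assay target, negative values
    inhibition. Rows with incomplete assay coverage are excluded before
    construction, so the body is dense.
    """

    compound_ids: tuple[str, ...]
    assay_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "compound_ids", tuple(self.compound_ids))
        object.__setattr__(self, "assay_ids", tuple(self.assay_ids))
        if values.ndim != 2:
            raise FormatError("activity values must be a 2-D array")
        n, m = values.shape
        if len(self.compound_ids) != n or len(self.assay_ids) != m:
            raise FormatError(
                f"shape mismatch: {n}x{m} values for "
                f"{len(self.compound_ids)} compounds / {len(self.assay_ids)} assays"
            )
        if len(set(self.compound_ids)) != n:
            dup = [k for k, c in Counter(self.compound_ids).items() if c > 1]
            raise FormatError(f"duplicate compound IDs: {dup[:5]}")
        if len(set(self.assay_ids)) != m:
            raise FormatError("duplicate assay IDs")
        if n and m:
            if not np.all(np.isfinite(values)):
                raise FormatError("activity matrix contains missing or non-finite values")
            lo, hi = values.min(), values.max()
            if lo < CURVE_RANK_MIN or hi > CURVE_RANK_MAX:
                raise FormatError(
                    f"curve ranks must lie in [{CURVE_RANK_MIN:g}, {CURVE_RANK_MAX:g}]; "
                    f"observed range [{lo:g}, {hi:g}]"
                )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_assays(self) -> int:
        return len(self.assay_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.compound_ids), columns=list(self.assay_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ActivityMatrix":
        return cls(
            compound_ids=tuple(str(i) for i in frame.index),
            assay_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def row(self, compound_id: str) -> np.ndarray:
        return self.values[self.compound_ids.index(compound_id)]


@dataclass(frozen=True)
class AnnotationRecord:
    compound_key: str
    gene: str
    source: str


@dataclass
class AnnotationTable:
    """Compound-key -> gene-target records with source provenance.

    Keys are InChIKey block 1 (14 uppercase letters), which identifies a
    molecular skeleton irrespective of salt form and stereochemistry.
    (compound_key, gene) pairs are unique; ``source`` carries the
    ``;``-joined labels of every table that contributed the pair.
    """

    records: list[AnnotationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            if not KEY14_PATTERN.match(rec.compound_key):
                raise FormatError(
                    f"compound key {rec.compound_key!r} is not 14 uppercase letters"
                )
            pair = (rec.compound_key, rec.gene)
            if pair in seen:
                raise FormatError(f"duplicate (key, gene) pair: {pair}")
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.records}

    @property
    def keys(self) -> set[str]:
        return {r.compound_key for r in self.records}

    def by_key(self) -> dict[str, set[str]]:
        """Map compound key -> set of annotated genes."""
        out: dict[str, set[str]] = {}
        for rec in self.records:
            out.setdefault(rec.compound_key, set()).add(rec.gene)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.compound_key, r.gene, r.source) for r in self.records],
            columns=["compound_key", "gene", "source"],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) in the shape of a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out


@dataclass
class ClusterAssignment:
    """Compound -> cluster-label map with size accounting.

    Labels are integers; after SOM assignment they are the retained unit
    indices, and the merging stage preserves the label of the larger
    constituent so labels stay stable across consolidation.
    """

    mapping: dict[str, int]

    @property
    def sizes(self) -> dict[int, int]:
        return dict(Counter(self.mapping.values()))

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.mapping.values()))

    @property
    def n_clusters(self) -> int:
        return len(set(self.mapping.values()))

    def members(self, label: int) -> list[str]:
        return [cid for cid, lab in self.mapping.items() if lab == label]

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class FingerprintSet:
    """Binary structural fingerprints as sets of on-bit indices."""

    n_bits: int
    fingerprints: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        for cid, bits in self.fingerprints.items():
            if bits and (min(bits) < 0 or max(bits) >= self.n_bits):
                raise ValueError(f"fingerprint for {cid!r} has bits outside [0, {self.n_bits})")

    def __len__(self) -> int:
        return len(self.fingerprints)

    def __getitem__(self, compound_id: str) -> frozenset[int]:
        return self.fingerprints[compound_id]
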