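"""Readers and writers for every on-disk artifact.

The native tabular dialect is TSV (assay names may contain commas),
UTF-8, Unix newlines; missing cells are empty strings, matching common
qHTS exports. Gene sets use the standard GMT dialect. Run provenance is
a JSON manifest with content checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ActivityMatrix,
    AnnotationRecord,
    AnnotationTable,
    ClusterAssignment,
    FormatError,
    GeneSetCollection,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- activity

def read_activity_matrix(path: str | Path, drop_incomplete: bool = True) -> ActivityMatrix:
    """Load a curve-rank matrix from TSV (first column compound IDs,
    header row assay IDs).

    Compounds with any missing assay value are excluded when
    ``drop_incomplete`` is set, mirroring the use of only compounds with
    complete activity data; otherwise an incomplete row raises.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    frame = frame.replace("", np.nan)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate compound IDs in {path.name}: {dup[:5]}")

    numeric = pd.DataFrame(index=frame.index)
    for col in frame.columns:
        try:
            numeric[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"non-numeric cell in {path.name}, row {row!r}, column {col!r}"
            ) from None

    incomplete = numeric.isna().any(axis=1)
    if incomplete.any():
        if not drop_incomplete:
            raise FormatError(
                f"{int(incomplete.sum())} rows with missing cells in {path.name} "
                "(drop_incomplete=False)"
            )
        logger.info(
            "dropped %d/%d compounds with incomplete assay coverage from %s",
            int(incomplete.sum()), len(numeric), path.name,
        )
        numeric = numeric.loc[~incomplete]
    return ActivityMatrix.from_frame(numeric)


def write_activity_matrix(matrix: ActivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    frame = matrix.to_frame()
    frame.index.name = "compound_id"
    frame.to_csv(path, sep="\t", lineterminator="\n")
    return path


# ------------------------------------------------------------- annotations

def read_annotations(path: str | Path, merge_duplicates: bool = True) -> AnnotationTable:
    """Load a 3-column (compound_key, gene, source) TSV.

    Duplicate (key, gene) pairs are collapsed with ``;``-joined distinct
    sources when ``merge_duplicates`` is set.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["compound_key", "gene", "source"]
    if list(frame.columns) != expected:
        raise FormatError(f"{path.name}: expected columns {expected}, got {list(frame.columns)}")
    records: list[AnnotationRecord] = []
    if merge_duplicates:
        seen: dict[tuple[str, str], list[str]] = {}
        order: list[tuple[str, str]] = []
        for key, gene, source in frame.itertuples(index=False):
            pair = (key, gene)
            if pair not in seen:
                seen[pair] = []
                order.append(pair)
            if source not in seen[pair]:
                seen[pair].append(source)
        records = [
            AnnotationRecord(key, gene, ";".join(seen[(key, gene)])) for key, gene in order
        ]
    else:
        records = [AnnotationRecord(k, g, s) for k, g, s in frame.itertuples(index=False)]
    return AnnotationTable(records)


def write_annotations(table: AnnotationTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


# --------------------------------------------------------------- gene sets

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB members."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path.name}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *members]) + "\n")
    return path


# ------------------------------------------------------------- assignments

def read_cluster_assignment(path: str | Path) -> ClusterAssignment:
    frame = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "cluster_id": int})
    expected = ["compound_id", "cluster_id"]
    if list(frame.columns) != expected:
        raise FormatError(f"expected columns {expected}, got {list(frame.columns)}")
    if frame["compound_id"].duplicated().any():
        raise FormatError("duplicate compound_id in cluster assignment")
    return ClusterAssignment(dict(zip(frame["compound_id"], frame["cluster_id"].astype(int))))


def write_cluster_assignment(assignment: ClusterAssignment, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        sorted(assignment.mapping.items()), columns=["compound_id", "cluster_id"]
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------- codebook

def write_codebook(codebook: np.ndarray, assay_ids, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(codebook, columns=list(assay_ids))
    frame.insert(0, "unit_id", range(len(frame)))
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def read_codebook(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t")
    if frame.columns[0] != "unit_id":
        raise FormatError("codebook TSV must start with a unit_id column")
    assay_ids = list(frame.columns[1:])
    return frame[assay_ids].to_numpy(dtype=float), assay_ids


# ------------------------------------------------------------ fingerprints

def write_fingerprints(fps, path: str | Path) -> Path:
    """Persist a FingerprintSet as TSV (compound_id, n_bits, on_bits).

    ``on_bits`` is a ``;``-joined sorted list of set-bit indices; empty
    for a fingerprint with no bits set.
    """
    path = Path(path)
    rows = [
        (cid, fps.n_bits, ";".join(str(b) for b in sorted(bits)))
        for cid, bits in sorted(fps.fingerprints.items())
    ]
    pd.DataFrame(rows, columns=["compound_id", "n_bits", "on_bits"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
    return path


def read_fingerprints(path: str | Path):
    from .containers import FingerprintSet

    frame = pd.read_csv(Path(path), sep="\t", dtype={"compound_id": str, "on_bits": str},
                        keep_default_na=False)
    expected = ["compound_id", "n_bits", "on_bits"]
    if list(frame.columns) != expected:
        raise FormatError(f"expected columns {expected}, got {list(frame.columns)}")
    n_bits_values = set(frame["n_bits"].astype(int))
    if len(n_bits_values) > 1:
        raise FormatError(f"inconsistent n_bits values: {sorted(n_bits_values)}")
    n_bits = n_bits_values.pop() if n_bits_values else 1
    fingerprints = {
        cid: frozenset(int(b) for b in bits.split(";") if b)
        for cid, bits in zip(frame["compound_id"], frame["on_bits"])
    }
    return FingerprintSet(int(n_bits), fingerprints)


# ---------------------------------------------------------------- manifest

def _checksum(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_run_manifest(
    stage_outputs: dict[str, list[str | Path]],
    config_snapshot: dict,
    seed: int,
    path: str | Path,
) -> Path:
    """JSON manifest of a run: per-stage output paths with SHA-256
    content checksums, the config snapshot, and the global seed.

    Raises if any listed output path does not exist. No timestamps are
    recorded, so identical runs produce byte-identical manifests.
    """
    path = Path(path)
    stages = []
    for stage, outputs in stage_outputs.items():
        entries = []
        for out in outputs:
            out = Path(out)
            if not out.exists():
                raise FileNotFoundError(f"stage {stage!r} output missing: {out}")
            entries.append({"path": out.name, "sha256": _checksum(out)})
        stages.append({"stage": stage, "outputs": entries})
    payload = {"stages": stages, "config": config_snapshot, "seed": seed}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def compare_manifests(path_a: str | Path, path_b: str | Path) -> dict[str, bool]:
    """Report whether two manifests agree on checksums, config and seed."""
    a = json.loads(Path(path_a).read_text())
    b = json.loads(Path(path_b).read_text())
    return {
        "checksums_equal": a["stages"] == b["stages"],
        "config_equal": a["config"] == b["config"],
        "seed_equal": a["seed"] == b["seed"],
    }
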