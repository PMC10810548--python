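"""Structure normalisation and annotation joining.

Compounds are matched to gene-annotation sources through a salt- and
stereo-insensitive structure key: the first 14 characters of the
standard InChIKey (block 1), computed on the main component of the
structure — the dot-separated SMILES component with the longest string.
Block 1 encodes only the molecular skeleton, so stereoisomers and salt
forms of one parent collapse onto one key.

Unparseable structures are recorded as mapping failures and excluded
rather than aborting a run; large screening libraries routinely lose a
handful of compounds at this step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.inchi import MolToInchiKey

from .containers import KEY14_PATTERN, AnnotationRecord, AnnotationTable

logger = logging.getLogger(__name__)

# rdkit is chatty about unparseable SMILES; failures are reported via records
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

STATUS_OK = "ok"
STATUS_FAILED = "mapping_failed"


@dataclass(frozen=True)
class CompoundRecord:
    """A compound with its normalised structure key.

    ``key14`` is InChIKey block 1 of the primary component; empty when
    ``status`` is ``mapping_failed``.
    """

    compound_id: str
    smiles_raw: str
    smiles_primary: str
    key14: str
    status: str = STATUS_OK

    @classmethod
    def synthetic(cls, compound_id: str, key14: str) -> "CompoundRecord":
        """Record carrying a pre-computed key and no structure (synthetic data)."""
        if not KEY14_PATTERN.match(key14):
            raise ValueError(f"key14 {key14!r} is not 14 uppercase letters")
        return cls(compound_id, "", "", key14)


def primary_component(smiles: str) -> str:
    """Main component of a mixture SMILES: the longest dot-separated
    component by character count, ties broken lexicographically smallest."""
    if not smiles:
        raise ValueError("empty SMILES")
    components = [c for c in smiles.split(".") if c]
    if not components:
        raise ValueError(f"no components in SMILES {smiles!r}")
    return min(components, key=lambda c: (-len(c), c))


def compound_key(smiles: str) -> str:
    """InChIKey block 1 (14 uppercase letters) of the primary component.

    Raises ValueError for unparseable SMILES; batch callers catch this
    and record a mapping failure instead.
    """
    primary = primary_component(smiles)
    mol = Chem.MolFromSmiles(primary)
    if mol is None:
        raise ValueError(f"unparseable SMILES {primary!r}")
    inchikey = MolToInchiKey(mol)
    if not inchikey:
        raise ValueError(f"InChIKey generation failed for {primary!r}")
    key14 = inchikey[:14]
    if not KEY14_PATTERN.match(key14):
        raise ValueError(f"unexpected InChIKey block 1 {key14!r} for {primary!r}")
    return key14


def map_compounds(structures: list[tuple[str, str]]) -> list[CompoundRecord]:
    """Map (compound_id, SMILES) pairs to keyed records.

    Unparseable structures yield records with status ``mapping_failed``
    (logged and counted) instead of raising.
    """
    records: list[CompoundRecord] = []
    failures = 0
    for compound_id, smiles in structures:
        try:
            primary = primary_component(smiles)
            key14 = compound_key(smiles)
            records.append(CompoundRecord(compound_id, smiles, primary, key14))
        except ValueError as exc:
            failures += 1
            logger.warning("mapping failure for %s: %s", compound_id, exc)
            records.append(CompoundRecord(compound_id, smiles, "", "", STATUS_FAILED))
    if failures:
        logger.info("%d/%d compounds failed structure mapping", failures, len(structures))
    return records


def read_structures(path: str | Path) -> list[tuple[str, str]]:
    """Load a 2-column (compound_id, SMILES) TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] != 2:
        raise ValueError(f"{Path(path).name}: expected 2 columns (compound_id, smiles)")
    return [(str(a), str(b)) for a, b in frame.itertuples(index=False)]


def write_compound_records(records: list[CompoundRecord], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [(r.compound_id, r.smiles_raw, r.smiles_primary, r.key14, r.status) for r in records],
        columns=["compound_id", "smiles_raw", "smiles_primary", "key14", "status"],
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


@dataclass
class JoinReport:
    n_compounds: int = 0
    n_matched_compounds: int = 0
    n_pairs: int = 0
    n_genes: int = 0
    n_unmatched_rows: int = 0
    per_source_pairs: dict[str, int] = field(default_factory=dict)


def join_annotations(
    compounds: list[CompoundRecord],
    tables: list[AnnotationTable],
    source_labels: list[str] | None = None,
) -> tuple[AnnotationTable, JoinReport]:
    """Union of (compound-key, gene) pairs restricted to the compound list.

    Duplicate pairs across sources collapse to one record whose source
    is the ``;``-joined list of contributing labels, in table order.
    Annotation rows whose key matches no supplied compound are counted
    as unmatched and dropped.
    """
    if source_labels is None:
        source_labels = [f"source{i}" for i in range(len(tables))]
    if len(source_labels) != len(tables):
        raise ValueError("need one source label per table")

    valid_keys = {r.key14 for r in compounds if r.status == STATUS_OK and r.key14}
    merged: dict[tuple[str, str], list[str]] = {}
    order: list[tuple[str, str]] = []
    report = JoinReport(n_compounds=len(compounds))
    for label, table in zip(source_labels, tables):
        matched_pairs = 0
        for rec in table:
            if rec.compound_key not in valid_keys:
                report.n_unmatched_rows += 1
                continue
            matched_pairs += 1
            pair = (rec.compound_key, rec.gene)
            if pair not in merged:
                merged[pair] = []
                order.append(pair)
            if label not in merged[pair]:
                merged[pair].append(label)
        report.per_source_pairs[label] = matched_pairs

    records = [AnnotationRecord(k, g, ";".join(merged[(k, g)])) for k, g in order]
    out = AnnotationTable(records)
    matched_keys = out.keys
    report.n_matched_compounds = sum(
        1 for r in compounds if r.status == STATUS_OK and r.key14 in matched_keys
    )
    report.n_pairs = len(records)
    report.n_genes = len(out.genes)
    logger.info(
        "joined %d tables: %d pairs, %d genes, %d/%d compounds matched, %d unmatched rows",
        len(tables), report.n_pairs, report.n_genes,
        report.n_matched_compounds, report.n_compounds, report.n_unmatched_rows,
    )
    return out, report


def annotations_by_compound(
    compounds: list[CompoundRecord], table: AnnotationTable
) -> dict[str, frozenset[str]]:
    """Map compound_id -> annotated gene set via the structure key.

    Compounds sharing a key (salt forms, stereoisomers) receive the same
    gene set. Compounds without annotations are omitted.
    """
    by_key = table.by_key()
    out: dict[str, frozenset[str]] = {}
    for rec in compounds:
        if rec.status != STATUS_OK:
            continue
        genes = by_key.get(rec.key14)
        if genes:
            out[rec.compound_id] = frozenset(genes)
    return out
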