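"""End-to-end orchestration: load -> SOM -> merge -> annotate ->
gene enrichment -> pathway enrichment -> similarity -> manifest.

Each stage writes its outputs before the next starts, so any stage can
be re-run from its persisted inputs; a stage failure aborts the run
with the stage name and leaves a partial manifest of completed stages.
One global seed fans out to per-stage seeds through a stable hash of
the stage name, so adding a stage never perturbs the randomness of the
others, and identical (config, seed) runs produce byte-identical run
directories.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import chem, enrichment, io, merging, similarity, som, synthetic
from .containers import ClusterAssignment, FormatError

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(stage: str, global_seed: int) -> int:
    """Per-stage seed derived from the global seed by a stable hash."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ----------------------------------------------------------------- config

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PathsConfig(_Section):
    activity_matrix: Optional[str] = None
    structures: Optional[str] = None       # 2-column TSV: compound_id, SMILES
    compound_keys: Optional[str] = None    # 2-column TSV: compound_id, key14
    fingerprints: Optional[str] = None     # pre-computed fingerprint TSV
    annotations: list[str] = Field(default_factory=list)
    gene_sets: Optional[str] = None
    output_dir: str = "run"


class SomConfig(_Section):
    grid_rows: int = Field(som.DEFAULT_GRID, ge=1)
    grid_cols: int = Field(som.DEFAULT_GRID, ge=1)
    topology: Literal["rectangular", "hexagonal"] = "rectangular"
    epochs: int = Field(som.DEFAULT_EPOCHS, ge=0)
    lr_initial: float = Field(som.DEFAULT_LR_INITIAL, gt=0)
    lr_final: float = Field(som.DEFAULT_LR_FINAL, gt=0)
    radius_initial: Optional[float] = Field(None, gt=0)
    radius_final: float = Field(som.DEFAULT_RADIUS_FINAL, gt=0)

    @model_validator(mode="after")
    def _check_rates(self):
        if self.lr_final > self.lr_initial:
            raise ValueError("lr_final cannot exceed lr_initial")
        return self


class MergeConfig(_Section):
    min_size: int = Field(merging.DEFAULT_MIN_SIZE, ge=1)


class EnrichmentConfig(_Section):
    alpha_fdr: float = Field(enrichment.DEFAULT_ALPHA_FDR, gt=0, lt=1)
    alpha_pathway: float = Field(enrichment.DEFAULT_ALPHA_PATHWAY, gt=0, lt=1)
    p_floor: float = Field(enrichment.DEFAULT_P_FLOOR, gt=0, lt=1)
    min_bum_n: int = Field(enrichment.MIN_BUM_N, ge=2)
    null_reps: int = Field(0, ge=0)


class SimilarityConfig(_Section):
    radius: int = Field(similarity.DEFAULT_RADIUS, ge=0)
    n_bits: int = Field(similarity.DEFAULT_N_BITS, ge=1)
    max_pairs_per_stratum: int = Field(similarity.DEFAULT_MAX_PAIRS, ge=1)


class SyntheticConfig(_Section):
    n_compounds: int = Field(500, ge=1)
    n_assays: int = Field(20, ge=2)
    n_clusters: int = Field(5, ge=1)
    noise_sd: float = Field(1.0, ge=0)
    genes_per_cluster: int = Field(5, ge=1)
    enrichment_prob: float = Field(0.6, ge=0, le=1)
    background_prob: float = Field(0.05, ge=0, le=1)
    n_bits: int = Field(1024, ge=1)
    intra_flip_prob: float = Field(0.05, ge=0, le=1)
    inter_seed_density: float = Field(0.1, ge=0, le=1)
    sets_per_cluster: int = Field(1, ge=1)
    extra_genes_per_set: int = Field(10, ge=0)


class PipelineConfig(_Section):
    seed: int = 0
    paths: PathsConfig = Field(default_factory=PathsConfig)
    som: SomConfig = Field(default_factory=SomConfig)
    merge: MergeConfig = Field(default_factory=MergeConfig)
    enrichment: EnrichmentConfig = Field(default_factory=EnrichmentConfig)
    similarity: SimilarityConfig = Field(default_factory=SimilarityConfig)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)

    def snapshot(self) -> dict:
        return json.loads(self.model_dump_json())


# --------------------------------------------------------------- simulate

def simulate_command(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Write a complete synthetic input bundle plus the truth sidecar.

    Produces activity.tsv, compound_keys.tsv, fingerprints.tsv,
    annotations.tsv, gene_sets.gmt and truth.json, all deterministic in
    the config seed.
    """
    syn = config.synthetic
    out = Path(out_dir) if out_dir is not None else Path(config.paths.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    matrix, truth = synthetic.generate_activity_matrix(
        syn.n_compounds, syn.n_assays, syn.n_clusters, syn.noise_sd,
        seed=stage_seed("simulate.activity", seed),
    )
    annotations = synthetic.generate_annotations(
        truth, syn.genes_per_cluster, syn.enrichment_prob, syn.background_prob,
        seed=stage_seed("simulate.annotations", seed),
    )
    fps = synthetic.generate_fingerprints(
        truth, syn.n_bits, syn.intra_flip_prob, syn.inter_seed_density,
        seed=stage_seed("simulate.fingerprints", seed),
    )
    pathways = synthetic.generate_pathways(
        truth, syn.sets_per_cluster, syn.extra_genes_per_set,
        seed=stage_seed("simulate.pathways", seed),
    )

    io.write_activity_matrix(matrix, out / "activity.tsv")
    keys = pd.DataFrame(
        [(cid, synthetic.compound_key_for(cid)) for cid in matrix.compound_ids],
        columns=["compound_id", "key14"],
    )
    keys.to_csv(out / "compound_keys.tsv", sep="\t", index=False, lineterminator="\n")
    io.write_fingerprints(fps, out / "fingerprints.tsv")
    io.write_annotations(annotations, out / "annotations.tsv")
    io.write_gene_sets(pathways, out / "gene_sets.gmt")
    truth.to_json(out / "truth.json")
    logger.info("synthetic bundle written to %s", out)
    return out


# ------------------------------------------------------------------- run

def _load_compound_records(config: PipelineConfig) -> list[chem.CompoundRecord]:
    paths = config.paths
    if paths.structures:
        return chem.map_compounds(chem.read_structures(paths.structures))
    if paths.compound_keys:
        frame = pd.read_csv(paths.compound_keys, sep="\t", dtype=str, keep_default_na=False)
        if list(frame.columns) != ["compound_id", "key14"]:
            raise FormatError("compound_keys TSV needs columns compound_id, key14")
        return [chem.CompoundRecord.synthetic(cid, key) for cid, key in frame.itertuples(index=False)]
    raise FileNotFoundError("config.paths must provide either structures or compound_keys")


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Execute every stage in order; returns the run directory.

    Outputs: codebook.tsv, som_assignment.tsv, merged_assignment.tsv,
    merge_log.tsv, compound_records.tsv, joined_annotations.tsv,
    gene_enrichment.tsv (+ bum_fit.json), pathway_enrichment.tsv,
    optional null_comparison.json, similarity.json and manifest.json.
    """
    out = Path(out_dir) if out_dir is not None else Path(config.paths.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    completed: dict[str, list[Path]] = {}

    def _abort(stage: str, exc: Exception):
        try:
            io.write_run_manifest(
                {k: [str(p) for p in v] for k, v in completed.items()},
                config.snapshot(), seed, out / "manifest_partial.json",
            )
        except Exception:  # partial manifest is best effort
            pass
        raise StageError(stage, exc) from exc

    # ---- load
    try:
        if not config.paths.activity_matrix:
            raise FileNotFoundError("config.paths.activity_matrix is not set")
        matrix = io.read_activity_matrix(config.paths.activity_matrix, drop_incomplete=True)
    except Exception as exc:
        _abort("load", exc)
    completed["load"] = []

    # ---- SOM clustering
    try:
        sconf = config.som
        model = som.train_som(
            matrix,
            grid_rows=sconf.grid_rows, grid_cols=sconf.grid_cols,
            topology=sconf.topology, epochs=sconf.epochs,
            lr_initial=sconf.lr_initial, lr_final=sconf.lr_final,
            radius_initial=sconf.radius_initial, radius_final=sconf.radius_final,
            seed=stage_seed("som", seed),
        )
        assignment = som.assign_bmu(model, matrix)
        p_codebook = io.write_codebook(model.codebook, model.assay_ids, out / "codebook.tsv")
        p_assign = io.write_cluster_assignment(assignment, out / "som_assignment.tsv")
        logger.info("SOM stage: %d clusters (non-empty units), QE=%.4f",
                    assignment.n_clusters, som.quantization_error(model, matrix))
    except Exception as exc:
        _abort("cluster", exc)
    completed["cluster"] = [p_codebook, p_assign]

    # ---- merge small clusters
    try:
        centroids = merging.compute_centroids(matrix, assignment)
        merged = merging.merge_small_clusters(assignment, centroids, config.merge.min_size)
        p_merged = io.write_cluster_assignment(merged.assignment, out / "merged_assignment.tsv")
        merged.log_frame().to_csv(out / "merge_log.tsv", sep="\t", index=False, lineterminator="\n")
        assignment = merged.assignment
    except Exception as exc:
        _abort("merge", exc)
    completed["merge"] = [p_merged, out / "merge_log.tsv"]

    # ---- map structures / join annotations
    try:
        records = _load_compound_records(config)
        if not config.paths.annotations:
            raise FileNotFoundError("config.paths.annotations lists no annotation tables")
        tables = [io.read_annotations(p) for p in config.paths.annotations]
        labels = [Path(p).stem for p in config.paths.annotations]
        joined, report = chem.join_annotations(records, tables, labels)
        p_records = chem.write_compound_records(records, out / "compound_records.tsv")
        p_joined = io.write_annotations(joined, out / "joined_annotations.tsv")
        gene_map = chem.annotations_by_compound(records, joined)
    except Exception as exc:
        _abort("annotate", exc)
    completed["annotate"] = [p_records, p_joined]

    # ---- gene-target enrichment
    try:
        ge = enrichment.cluster_gene_enrichment(
            assignment, gene_map,
            alpha=config.enrichment.alpha_fdr,
            p_floor=config.enrichment.p_floor,
            min_bum_n=config.enrichment.min_bum_n,
            seed=stage_seed("enrich", seed),
        )
        p_genes = _write_enrichment_results(ge.results, out / "gene_enrichment.tsv")
        fit_payload = {
            "adjustment": ge.adjustment,
            "alpha": ge.alpha,
            "n_tests": len(ge.results),
            "n_significant": len(ge.significant),
            "cutoff": ge.cutoff,
        }
        if ge.bum_fit is not None:
            fit_payload.update(
                a_hat=ge.bum_fit.a_hat, lambda_hat=ge.bum_fit.lambda_hat,
                pi_ub=ge.bum_fit.pi_ub, loglik=ge.bum_fit.loglik, n=ge.bum_fit.n,
            )
        (out / "bum_fit.json").write_text(json.dumps(fit_payload, indent=1, sort_keys=True) + "\n")
    except Exception as exc:
        _abort("enrich", exc)
    completed["enrich"] = [p_genes, out / "bum_fit.json"]

    # ---- pathway enrichment (+ optional randomized null)
    try:
        if not config.paths.gene_sets:
            raise FileNotFoundError("config.paths.gene_sets is not set")
        gene_sets = io.read_gene_sets(config.paths.gene_sets)
        background = set()
        for genes in gene_map.values():
            background |= genes
        background |= gene_sets.all_genes
        enriched = {lab: g & background for lab, g in ge.enriched_genes().items()}
        enriched = {lab: g for lab, g in enriched.items() if g}
        pw_results = (
            enrichment.pathway_enrichment(
                enriched, gene_sets, background, alpha=config.enrichment.alpha_pathway
            )
            if enriched else []
        )
        p_pw = _write_enrichment_results(pw_results, out / "pathway_enrichment.tsv")
        pathway_outputs = [p_pw]
        if config.enrichment.null_reps > 0:
            null = enrichment.randomized_null_comparison(
                assignment, gene_map, gene_sets,
                n_reps=config.enrichment.null_reps,
                seed=stage_seed("null", seed),
                alpha_fdr=config.enrichment.alpha_fdr,
                alpha_pathway=config.enrichment.alpha_pathway,
                min_bum_n=config.enrichment.min_bum_n,
                background=background,
            )
            (out / "null_comparison.json").write_text(
                json.dumps(null.summary(), indent=1, sort_keys=True) + "\n"
            )
            pathway_outputs.append(out / "null_comparison.json")
    except Exception as exc:
        _abort("pathways", exc)
    completed["pathways"] = pathway_outputs

    # ---- structural similarity validation
    try:
        if config.paths.fingerprints:
            fps = io.read_fingerprints(config.paths.fingerprints)
        else:
            fps = similarity.structure_fingerprints(
                records, radius=config.similarity.radius, n_bits=config.similarity.n_bits
            )
        summary = similarity.intra_inter_summary(
            fps, assignment,
            max_pairs_per_stratum=config.similarity.max_pairs_per_stratum,
            seed=stage_seed("similarity", seed),
        )
        (out / "similarity.json").write_text(
            json.dumps(summary.as_dict(), indent=1, sort_keys=True) + "\n"
        )
    except Exception as exc:
        _abort("validate-similarity", exc)
    completed["validate-similarity"] = [out / "similarity.json"]

    manifest = io.write_run_manifest(
        {k: [str(p) for p in v] for k, v in completed.items()},
        config.snapshot(), seed, out / "manifest.json",
    )
    logger.info("pipeline complete: %s", manifest)
    return out


def _write_enrichment_results(results, path: Path) -> Path:
    rows = [
        (
            r.cluster_label, r.feature,
            r.table.a, r.table.b, r.table.c, r.table.d,
            r.p_value,
            "" if r.adjusted_p is None else r.adjusted_p,
            "" if r.cutoff_used is None else r.cutoff_used,
            int(r.significant), r.adjustment,
        )
        for r in results
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "cluster_label", "feature", "a", "b", "c", "d",
            "p_value", "adjusted_p", "cutoff_used", "significant", "adjustment",
        ],
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path
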