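"""Gene-target and pathway overrepresentation within compound clusters.

Per (cluster, gene) pair, a 2x2 contingency table partitions the
annotated compound universe by cluster membership and by annotation to
the tested gene, and a one-tailed Fisher exact test scores
overrepresentation. The p-values of all tests are pooled and modelled
as a beta-uniform mixture (BUM),

    f(p) = lam + (1 - lam) * a * p**(a - 1),    0 < a < 1, 0 <= lam <= 1,

a mixture of a Uniform(0,1) null component and a Beta(a, 1) signal
component. The fitted mixture yields an upper bound on the null
proportion, pi_ub = lam + (1 - lam) * a, and a p-value threshold tau
at which the estimated false discovery rate

    FDR(tau) = pi_ub * tau / (lam * tau + (1 - lam) * tau**a)

equals the requested level (default 1%). Pathway overrepresentation of
each cluster's enriched genes uses the same Fisher test over a gene
background with Holm (step-down family-wise) adjustment within the
cluster, and a randomized-cluster null — annotation sets permuted as
whole blocks across compounds, cluster sizes unchanged — calibrates how
many enriched pathways random gene-to-cluster groupings would produce.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .containers import ClusterAssignment, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_FDR = 0.01
DEFAULT_ALPHA_PATHWAY = 0.05
DEFAULT_P_FLOOR = 1e-12
MIN_BUM_N = 50


class ContingencyTable(NamedTuple):
    """Counts over the annotated universe for one (cluster, gene) test.

    a: annotated to the gene, inside the cluster
    b: not annotated to the gene, inside the cluster
    c: annotated to the gene, outside the cluster
    d: not annotated to the gene, outside the cluster
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def build_contingency(
    assignment: ClusterAssignment,
    gene_map: Mapping[str, frozenset[str]],
    cluster_label: int,
    gene: str,
) -> ContingencyTable:
    """2x2 table for one gene in one cluster.

    The universe is every assigned compound with at least one gene
    annotation; a compound may target several genes, so "not annotated
    to the tested gene" includes compounds annotated to other genes.
    """
    a = b = c = d = 0
    for cid, genes in gene_map.items():
        if cid not in assignment.mapping or not genes:
            continue
        inside = assignment.mapping[cid] == cluster_label
        has_gene = gene in genes
        if inside and has_gene:
            a += 1
        elif inside:
            b += 1
        elif has_gene:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def fisher_one_tailed(table: ContingencyTable) -> float:
    """One-tailed (overrepresentation) Fisher exact p-value.

    P(X >= a) under the hypergeometric distribution with the table's
    margins; an all-zero table returns 1.0 by convention.
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be nonnegative")
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    # draws = cluster size (a+b); successes in population = gene total (a+c)
    p = stats.hypergeom.sf(a - 1, n_total, a + c, a + b)
    return float(min(1.0, max(0.0, p)))


# ----------------------------------------------------------------- BUM fit

@dataclass(frozen=True)
class BumFit:
    """Maximum-likelihood beta-uniform mixture fit to pooled p-values.

    pi_ub = lambda_hat + (1 - lambda_hat) * a_hat bounds the proportion
    of tests drawn from the uniform null from above (the mixture density
    at p = 1).
    """

    a_hat: float
    lambda_hat: float
    loglik: float
    n: int

    @property
    def pi_ub(self) -> float:
        return self.lambda_hat + (1.0 - self.lambda_hat) * self.a_hat

    def density(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return self.lambda_hat + (1.0 - self.lambda_hat) * self.a_hat * p ** (self.a_hat - 1.0)


def _bum_negloglik(params: np.ndarray, p: np.ndarray) -> float:
    a, lam = params
    dens = lam + (1.0 - lam) * a * p ** (a - 1.0)
    return -float(np.sum(np.log(np.maximum(dens, 1e-300))))


def fit_bum(
    p_values: Sequence[float],
    p_floor: float = DEFAULT_P_FLOOR,
    n_starts: int = 10,
    seed: int = 0,
    min_n: int = MIN_BUM_N,
) -> BumFit:
    """Fit f(p) = lam + (1-lam) * a * p**(a-1) by seeded multi-start MLE.

    p-values below ``p_floor`` are clamped before the likelihood is
    evaluated (p**(a-1) diverges at 0). Fewer than ``min_n`` p-values
    give too little information about the mixture shape; the fit
    refuses and recommends Holm adjustment instead.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size < min_n:
        raise ValueError(
            f"need at least {min_n} p-values for a stable BUM fit (got {p.size}); "
            "use Holm adjustment for small families"
        )
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, p_floor, 1.0)

    rng = np.random.default_rng(seed)
    eps = 1e-6
    bounds = [(eps, 1.0 - eps), (0.0, 1.0)]
    starts = [(0.5, 0.5)]
    starts += [(rng.uniform(0.05, 0.95), rng.uniform(0.0, 1.0)) for _ in range(n_starts - 1)]

    best = None
    for start in starts:
        res = optimize.minimize(
            _bum_negloglik, np.asarray(start), args=(p,),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    a_hat, lambda_hat = best.x
    return BumFit(float(a_hat), float(lambda_hat), -float(best.fun), int(p.size))


def bum_fdr_cutoff(fit: BumFit, alpha: float) -> float | None:
    """p-value threshold tau with estimated FDR(tau) = alpha.

    Closed form: tau = [ (pi_ub - alpha*lam) / (alpha*(1 - lam)) ]**(1/(a-1)).
    Returns None when no tau in (0, 1) achieves the level — notably for
    a pure-null fit (lambda_hat = 1), where the estimated FDR is 1 at
    every threshold.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    a, lam = fit.a_hat, fit.lambda_hat
    if lam >= 1.0 or a >= 1.0:
        return None
    bracket = (fit.pi_ub - alpha * lam) / (alpha * (1.0 - lam))
    if bracket <= 0.0:
        return None
    tau = bracket ** (1.0 / (a - 1.0))
    if not 0.0 < tau < 1.0:
        return None
    return float(tau)


def bum_fdr(fit: BumFit, tau: float) -> float:
    """Estimated FDR at threshold tau under the fitted mixture."""
    a, lam = fit.a_hat, fit.lambda_hat
    denom = lam * tau + (1.0 - lam) * tau ** a
    return float(fit.pi_ub * tau / denom) if denom > 0 else 1.0


# ----------------------------------------------------------- Holm adjust

def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment, returned in the original order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="holm")[1]
    return [float(x) for x in adjusted]


# ----------------------------------------------- cluster gene enrichment

ADJUST_BUM = "bum_fdr"
ADJUST_HOLM = "holm"


@dataclass(frozen=True)
class EnrichmentResult:
    """One overrepresentation test of a gene or pathway in a cluster."""

    cluster_label: int
    feature: str
    table: ContingencyTable
    p_value: float
    adjusted_p: float | None
    significant: bool
    cutoff_used: float | None
    adjustment: str


@dataclass
class GeneEnrichment:
    """All (cluster, gene) tests plus the pooled multiple-testing fit."""

    results: list[EnrichmentResult]
    alpha: float
    adjustment: str
    bum_fit: BumFit | None
    cutoff: float | None

    @property
    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.significant]

    def enriched_genes(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for r in self.results:
            if r.significant:
                out.setdefault(r.cluster_label, set()).add(r.feature)
        return out

    def per_cluster_counts(self) -> dict[int, int]:
        return {lab: len(genes) for lab, genes in self.enriched_genes().items()}


def cluster_gene_enrichment(
    assignment: ClusterAssignment,
    gene_map: Mapping[str, frozenset[str]],
    alpha: float = DEFAULT_ALPHA_FDR,
    p_floor: float = DEFAULT_P_FLOOR,
    min_bum_n: int = MIN_BUM_N,
    seed: int = 0,
) -> GeneEnrichment:
    """Test every (cluster, gene) pair with in-cluster annotation.

    For each cluster, each gene annotating at least one member is
    tested by one-tailed Fisher; all p-values are pooled into a single
    BUM fit whose FDR cutoff at ``alpha`` marks significance. Families
    too small for a stable mixture fit (< ``min_bum_n`` tests) fall
    back to Holm adjustment at the same ``alpha``.
    """
    if assignment.n_clusters < 2:
        raise ValueError("gene enrichment needs at least 2 clusters")
    universe = {cid: genes for cid, genes in gene_map.items()
                if cid in assignment.mapping and genes}
    if not universe:
        return GeneEnrichment([], alpha, ADJUST_HOLM, None, None)

    tests: list[tuple[int, str, ContingencyTable, float]] = []
    for label in assignment.labels:
        members = [cid for cid in universe if assignment.mapping[cid] == label]
        genes_in_cluster = sorted({g for cid in members for g in universe[cid]})
        for gene in genes_in_cluster:
            table = build_contingency(assignment, universe, label, gene)
            tests.append((label, gene, table, fisher_one_tailed(table)))

    pvals = [t[3] for t in tests]
    results: list[EnrichmentResult] = []
    if len(pvals) >= min_bum_n:
        fit = fit_bum(pvals, p_floor=p_floor, seed=seed, min_n=min_bum_n)
        tau = bum_fdr_cutoff(fit, alpha)
        for label, gene, table, p in tests:
            sig = tau is not None and p <= tau
            results.append(EnrichmentResult(
                label, gene, table, p, None, sig, tau, ADJUST_BUM))
        summary = GeneEnrichment(results, alpha, ADJUST_BUM, fit, tau)
    else:
        adjusted = holm_adjust(pvals)
        for (label, gene, table, p), adj in zip(tests, adjusted):
            results.append(EnrichmentResult(
                label, gene, table, p, adj, adj <= alpha, alpha, ADJUST_HOLM))
        summary = GeneEnrichment(results, alpha, ADJUST_HOLM, None, None)
    logger.info(
        "gene enrichment: %d tests over %d clusters, %d significant (%s, alpha=%g)",
        len(tests), assignment.n_clusters, len(summary.significant),
        summary.adjustment, alpha,
    )
    return summary


# ---------------------------------------------------- pathway enrichment

def pathway_enrichment(
    enriched_genes: Mapping[int, set[str]],
    gene_sets: GeneSetCollection,
    background: set[str],
    alpha: float = DEFAULT_ALPHA_PATHWAY,
) -> list[EnrichmentResult]:
    """Pathway overrepresentation of each cluster's enriched genes.

    Per cluster and pathway, the 2x2 table partitions the gene
    background by (enriched in the cluster) x (member of the pathway);
    one-tailed Fisher p-values are Holm-adjusted within the cluster and
    called significant at adjusted p <= alpha.
    """
    if not background:
        raise ValueError("empty gene background")
    for label, genes in enriched_genes.items():
        stray = genes - background
        if stray:
            raise ValueError(
                f"cluster {label}: enriched genes missing from background: {sorted(stray)[:5]}"
            )
    results: list[EnrichmentResult] = []
    for label in sorted(enriched_genes):
        enriched = enriched_genes[label] & background
        if not enriched:
            continue
        cluster_tests: list[tuple[str, ContingencyTable, float]] = []
        for name, members in gene_sets.items():
            pw = set(members) & background
            if not pw:
                continue
            a = len(enriched & pw)
            b = len(enriched - pw)
            c = len(pw - enriched)
            d = len(background) - a - b - c
            table = ContingencyTable(a, b, c, d)
            cluster_tests.append((name, table, fisher_one_tailed(table)))
        if not cluster_tests:
            continue
        adjusted = holm_adjust([t[2] for t in cluster_tests])
        for (name, table, p), adj in zip(cluster_tests, adjusted):
            results.append(EnrichmentResult(
                label, name, table, p, adj, adj <= alpha, alpha, ADJUST_HOLM))
    return results


# ------------------------------------------------------- randomized null

@dataclass
class NullComparison:
    """Pathway significance for the actual clustering vs a permuted null.

    The null permutes each compound's annotation set as a whole block
    across compounds: cluster sizes and the global multiset of
    annotation sets are unchanged; only the pairing of profiles to
    annotations is destroyed.
    """

    actual_pvalues: list[float]
    actual_significant: int
    null_pvalues: list[list[float]]
    null_significant_counts: list[int]
    alpha_pathway: float

    @property
    def null_median_significant(self) -> float:
        return float(np.median(self.null_significant_counts)) if self.null_significant_counts else 0.0

    def summary(self) -> dict:
        return {
            "actual_significant": self.actual_significant,
            "null_significant_counts": self.null_significant_counts,
            "null_median_significant": self.null_median_significant,
            "alpha_pathway": self.alpha_pathway,
        }


def _pathway_stage(assignment, gene_map, gene_sets, background,
                   alpha_fdr, alpha_pathway, min_bum_n, seed):
    genes = cluster_gene_enrichment(
        assignment, gene_map, alpha=alpha_fdr, min_bum_n=min_bum_n, seed=seed
    )
    enriched = {lab: g & background for lab, g in genes.enriched_genes().items()}
    enriched = {lab: g for lab, g in enriched.items() if g}
    if not enriched:
        return []
    return pathway_enrichment(enriched, gene_sets, background, alpha=alpha_pathway)


def randomized_null_comparison(
    assignment: ClusterAssignment,
    gene_map: Mapping[str, frozenset[str]],
    gene_sets: GeneSetCollection,
    n_reps: int,
    seed: int,
    alpha_fdr: float = DEFAULT_ALPHA_FDR,
    alpha_pathway: float = DEFAULT_ALPHA_PATHWAY,
    min_bum_n: int = MIN_BUM_N,
    background: set[str] | None = None,
) -> NullComparison:
    """Compare pathway enrichment on the actual clustering against
    clusters of the same sizes filled with randomly reassigned targets.

    Each replicate permutes compound -> annotation-set blocks uniformly
    at random over all assigned compounds and reruns the full gene-then-
    pathway enrichment. A real biological grouping should produce many
    more significant pathways than its permuted counterparts.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if background is None:
        background = set().union(*gene_map.values()) | gene_sets.all_genes if gene_map else gene_sets.all_genes

    actual = _pathway_stage(
        assignment, gene_map, gene_sets, background, alpha_fdr, alpha_pathway, min_bum_n, seed
    )
    actual_p = [r.p_value for r in actual]
    actual_sig = sum(r.significant for r in actual)

    rng = np.random.default_rng(seed)
    compounds = sorted(assignment.mapping)
    blocks = [gene_map.get(cid, frozenset()) for cid in compounds]
    null_p: list[list[float]] = []
    null_sig: list[int] = []
    for rep in range(n_reps):
        perm = rng.permutation(len(compounds))
        permuted = {
            compounds[i]: blocks[perm[i]] for i in range(len(compounds))
            if blocks[perm[i]]
        }
        rep_results = _pathway_stage(
            assignment, permuted, gene_sets, background,
            alpha_fdr, alpha_pathway, min_bum_n, seed,
        )
        null_p.append([r.p_value for r in rep_results])
        null_sig.append(sum(r.significant for r in rep_results))
    return NullComparison(actual_p, actual_sig, null_p, null_sig, alpha_pathway)
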