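"""Fisher tests, BUM FDR control, Holm, pathway and null-comparison logic."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import somscreen as ss
from somscreen.enrichment import ContingencyTable, bum_fdr

from conftest import gene_map_from


def fisher_oracle(a, b, c, d):
    """Brute-force upper-tail hypergeometric sum over all feasible tables."""
    n = a + b + c + d
    k = a + c          # compounds annotated to the gene
    m = a + b          # cluster size
    lo = max(0, m + k - n)
    hi = min(m, k)
    denom = math.comb(n, m)
    return sum(
        math.comb(k, x) * math.comb(n - k, m - x) for x in range(max(a, lo), hi + 1)
    ) / denom


def sample_bum(n, a, lam, rng):
    """Draw from f(p) = lam*U(0,1) + (1-lam)*Beta(a,1)."""
    null = rng.random(n) < lam
    return np.where(null, rng.random(n), rng.random(n) ** (1.0 / a))


class TestBuildContingency:
    def test_hand_counted_fixture(self):
        # universe of 10 annotated compounds, cluster of 4, gene hits 3 inside
        mapping = {f"C{i}": (0 if i < 4 else 1) for i in range(10)}
        gene_map = {f"C{i}": frozenset({"G", "other"} if i < 3 else {"other"})
                    for i in range(10)}
        assignment = ss.ClusterAssignment(mapping)
        t = ss.build_contingency(assignment, gene_map, 0, "G")
        assert t == ContingencyTable(3, 1, 0, 6)

    def test_absent_gene_gives_zero_a_and_c(self, truth_assignment, annotated_truth):
        _, truth, annotations = annotated_truth
        gene_map = gene_map_from(truth, annotations)
        t = ss.build_contingency(truth_assignment, gene_map, 0, "NOSUCHGENE")
        assert t.a == 0 and t.c == 0

    def test_cells_partition_annotated_universe(self, truth_assignment, annotated_truth):
        _, truth, annotations = annotated_truth
        gene_map = gene_map_from(truth, annotations)
        universe = sum(1 for cid, g in gene_map.items()
                       if cid in truth_assignment.mapping and g)
        for gene in list(truth.all_planted_genes()):
            for label in truth_assignment.labels:
                t = ss.build_contingency(truth_assignment, gene_map, label, gene)
                assert t.total == universe


class TestFisherOneTailed:
    def test_zero_a_with_positive_margins_is_one(self):
        assert ss.fisher_one_tailed(ContingencyTable(0, 5, 3, 7)) == pytest.approx(1.0)

    def test_hand_enumerated_point_mass(self):
        # P(X>=2) with margins (2,2)/(2,2): C(2,2)*C(2,0)/C(4,2) = 1/6
        p = ss.fisher_one_tailed(ContingencyTable(2, 0, 0, 2))
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_all_zero_table_is_one_by_convention(self):
        assert ss.fisher_one_tailed(ContingencyTable(0, 0, 0, 0)) == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            p = ss.fisher_one_tailed(ContingencyTable(a, b, c, d))
            if a + b + c + d == 0:
                assert p == 1.0
            else:
                assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ss.fisher_one_tailed(ContingencyTable(-1, 2, 3, 4))


class TestFitBum:
    def test_refuses_small_families_with_guidance(self):
        with pytest.raises(ValueError, match="Holm"):
            ss.fit_bum([0.5] * 10)

    def test_uniform_density_when_a_is_one(self):
        fit = ss.BumFit(a_hat=1.0, lambda_hat=0.3, loglik=0.0, n=100)
        p = np.linspace(0.01, 1, 50)
        np.testing.assert_allclose(fit.density(p), np.ones_like(p))

    def test_uniform_pvalues_give_high_null_proportion(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(10_000 + seed)
            fit = ss.fit_bum(rng.random(10_000), seed=seed)
            ok += fit.pi_ub >= 0.95
        assert ok >= 18

    def test_parameter_recovery_from_known_mixture(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(20_000 + seed)
            p = sample_bum(10_000, 0.3, 0.6, rng)
            fit = ss.fit_bum(p, seed=seed)
            ok += abs(fit.a_hat - 0.3) < 0.05 and abs(fit.lambda_hat - 0.6) < 0.08
        assert ok >= 18

    def test_density_nonnegative_and_integrates_to_one(self):
        # the beta component has an algebraic singularity at 0, so the
        # quadrature carries the x**(a-1) factor as an explicit weight
        from scipy.integrate import quad

        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.uniform(0.05, 0.95)
            lam = rng.uniform(0.0, 1.0)
            fit = ss.BumFit(a, lam, 0.0, 1)
            grid = np.linspace(1e-12, 1, 1000)
            assert np.all(fit.density(grid) >= 0)
            uniform_part, _ = quad(lambda x: lam, 0, 1)
            beta_part, _ = quad(lambda x: (1 - lam) * a, 0, 1,
                                weight="alg", wvar=(a - 1, 0))
            assert uniform_part + beta_part == pytest.approx(1.0, abs=1e-6)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        p = sample_bum(500, 0.4, 0.5, rng)
        f1 = ss.fit_bum(p, seed=11)
        f2 = ss.fit_bum(p, seed=11)
        assert f1 == f2


class TestBumFdrCutoff:
    def test_pure_null_returns_none(self):
        fit = ss.BumFit(a_hat=0.5, lambda_hat=1.0, loglik=0.0, n=100)
        assert ss.bum_fdr_cutoff(fit, 0.01) is None

    def test_closed_form_agrees_with_bisection(self):
        fit = ss.BumFit(a_hat=0.5, lambda_hat=0.5, loglik=0.0, n=100)
        tau = ss.bum_fdr_cutoff(fit, 0.01)
        root = brentq(lambda t: bum_fdr(fit, t) - 0.01, 1e-300, 1 - 1e-12, xtol=1e-15)
        assert tau == pytest.approx(root, abs=1e-9)

    def test_fdr_at_cutoff_equals_alpha_over_random_fits(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(100):
            fit = ss.BumFit(rng.uniform(0.05, 0.95), rng.uniform(0.0, 0.99), 0.0, 1)
            alpha = rng.uniform(0.005, 0.2)
            tau = ss.bum_fdr_cutoff(fit, alpha)
            if tau is None:
                continue
            checked += 1
            assert bum_fdr(fit, tau) == pytest.approx(alpha, abs=1e-9)
        assert checked >= 50

    def test_cutoff_monotone_in_alpha(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            fit = ss.BumFit(rng.uniform(0.05, 0.95), rng.uniform(0.0, 0.99), 0.0, 1)
            taus = [ss.bum_fdr_cutoff(fit, alpha) for alpha in (0.01, 0.05, 0.1, 0.2)]
            present = [t for t in taus if t is not None]
            assert present == sorted(present)


class TestHolmAdjust:
    def test_single_p_unchanged(self):
        assert ss.holm_adjust([0.03]) == [pytest.approx(0.03)]

    def test_hand_step_down(self):
        assert ss.holm_adjust([0.01, 0.04]) == [pytest.approx(0.02), pytest.approx(0.04)]

    def test_hand_step_down_with_monotone_enforcement(self):
        out = ss.holm_adjust([0.05, 0.05, 0.05])
        assert out == [pytest.approx(0.15)] * 3

    def test_original_order_preserved(self):
        out = ss.holm_adjust([0.04, 0.01])
        assert out == [pytest.approx(0.04), pytest.approx(0.02)]

    def test_capped_at_one(self):
        assert max(ss.holm_adjust([0.9, 0.8, 0.7])) <= 1.0


class TestClusterGeneEnrichment:
    def test_planted_genes_recovered(self, annotated_truth, truth_assignment):
        _, truth, annotations = annotated_truth
        gene_map = gene_map_from(truth, annotations)
        result = ss.cluster_gene_enrichment(truth_assignment, gene_map, alpha=0.01)
        enriched = result.enriched_genes()
        for cluster, genes in truth.planted_genes.items():
            assert set(genes) <= enriched.get(cluster, set())

    def test_permuted_annotations_rarely_significant(self, annotated_truth, truth_assignment):
        _, truth, annotations = annotated_truth
        gene_map = gene_map_from(truth, annotations)
        compounds = sorted(truth_assignment.mapping)
        blocks = [gene_map.get(cid, frozenset()) for cid in compounds]
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            perm = rng.permutation(len(compounds))
            permuted = {compounds[i]: blocks[perm[i]]
                        for i in range(len(compounds)) if blocks[perm[i]]}
            result = ss.cluster_gene_enrichment(truth_assignment, permuted, alpha=0.01,
                                                seed=seed)
            frac = len(result.significant) / max(len(result.results), 1)
            hits += frac <= 0.01
        assert hits >= 18

    def test_empty_annotations_give_empty_results(self, truth_assignment):
        result = ss.cluster_gene_enrichment(truth_assignment, {}, alpha=0.01)
        assert result.results == []

    def test_single_cluster_rejected(self):
        assignment = ss.ClusterAssignment({"C1": 0, "C2": 0})
        with pytest.raises(ValueError, match="clusters"):
            ss.cluster_gene_enrichment(assignment, {"C1": frozenset({"G"})})

    def test_pooled_test_count(self, annotated_truth, truth_assignment):
        """One test per (cluster, gene with >=1 annotated member)."""
        _, truth, annotations = annotated_truth
        gene_map = gene_map_from(truth, annotations)
        expected = 0
        for label in truth_assignment.labels:
            genes = set()
            for cid in truth_assignment.members(label):
                genes |= gene_map.get(cid, frozenset())
            expected += len(genes)
        result = ss.cluster_gene_enrichment(truth_assignment, gene_map)
        assert len(result.results) == expected


class TestPathwayEnrichment:
    def test_exact_pathway_match_point_mass(self):
        background = {f"G{i}" for i in range(100)}
        pathway = ["G0", "G1", "G2", "G3", "G4"]
        sets = ss.GeneSetCollection({"PW": pathway})
        results = ss.pathway_enrichment({0: set(pathway)}, sets, background)
        assert len(results) == 1
        expected = 1 / math.comb(100, 5)
        assert results[0].p_value == pytest.approx(expected, rel=1e-9)
        assert results[0].significant

    def test_no_overlap_nothing_significant(self):
        background = {f"G{i}" for i in range(30)} | {"X1", "X2"}
        sets = ss.GeneSetCollection({"PW": ["X1", "X2"]})
        results = ss.pathway_enrichment({0: {"G0", "G1"}}, sets, background)
        assert not any(r.significant for r in results)

    def test_holm_monotone_within_cluster(self, annotated_truth, truth_assignment):
        _, truth, annotations = annotated_truth
        gene_map = gene_map_from(truth, annotations)
        gene_sets = ss.generate_pathways(truth, 2, 6, seed=9)
        result = ss.cluster_gene_enrichment(truth_assignment, gene_map)
        background = set().union(*gene_map.values()) | gene_sets.all_genes
        enriched = {lab: g & background for lab, g in result.enriched_genes().items()}
        pw = ss.pathway_enrichment(enriched, gene_sets, background)
        by_cluster: dict[int, list] = {}
        for r in pw:
            by_cluster.setdefault(r.cluster_label, []).append(r)
        for rows in by_cluster.values():
            rows.sort(key=lambda r: r.p_value)
            adj = [r.adjusted_p for r in rows]
            assert adj == sorted(adj)

    def test_empty_background_rejected(self):
        sets = ss.GeneSetCollection({"PW": ["G1"]})
        with pytest.raises(ValueError, match="background"):
            ss.pathway_enrichment({0: {"G1"}}, sets, set())


class TestRandomizedNull:
    @pytest.fixture()
    def planted_world(self):
        matrix, truth = ss.generate_activity_matrix(400, 12, 4, 1.0, seed=31)
        annotations = ss.generate_annotations(truth, 5, 0.6, 0.05, seed=32)
        gene_sets = ss.generate_pathways(truth, 1, 10, seed=33)
        assignment = ss.ClusterAssignment(dict(truth.labels))
        gene_map = gene_map_from(truth, annotations)
        return assignment, gene_map, gene_sets

    def test_randomization_preserves_cluster_sizes_and_blocks(self, planted_world):
        assignment, gene_map, gene_sets = planted_world
        null = ss.randomized_null_comparison(
            assignment, gene_map, gene_sets, n_reps=2, seed=7
        )
        # cluster sizes unchanged by construction (assignment never touched);
        # block permutation preserves the multiset of annotation sets, so the
        # total number of (compound, gene) annotations is invariant
        total = sum(len(g) for g in gene_map.values())
        assert null.actual_significant >= 0
        compounds = sorted(assignment.mapping)
        rng = np.random.default_rng(7)
        blocks = [gene_map.get(cid, frozenset()) for cid in compounds]
        perm = rng.permutation(len(compounds))
        permuted = [blocks[perm[i]] for i in range(len(compounds))]
        assert sorted(map(sorted, permuted)) == sorted(map(sorted, blocks))
        assert sum(len(b) for b in permuted) == total

    def test_actual_beats_null_median(self, planted_world):
        assignment, gene_map, gene_sets = planted_world
        null = ss.randomized_null_comparison(
            assignment, gene_map, gene_sets, n_reps=10, seed=5
        )
        assert null.actual_significant > null.null_median_significant

    def test_rep_count_validated(self, planted_world):
        assignment, gene_map, gene_sets = planted_world
        with pytest.raises(ValueError):
            ss.randomized_null_comparison(assignment, gene_map, gene_sets,
                                          n_reps=0, seed=1)
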