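"""Synthetic-data generator: contracts, determinism, planted signal."""

import numpy as np
import pytest

import somscreen as ss


class TestActivityMatrix:
    def test_shape_and_label_contract(self):
        matrix, truth = ss.generate_activity_matrix(100, 10, 4, 1.0, seed=1)
        assert matrix.values.shape == (100, 10)
        assert set(truth.labels.values()) == {0, 1, 2, 3}
        assert set(truth.labels) == set(matrix.compound_ids)

    def test_zero_noise_rows_equal_archetypes(self):
        matrix, truth = ss.generate_activity_matrix(50, 8, 2, 0.0, seed=7)
        for i, cid in enumerate(matrix.compound_ids):
            np.testing.assert_array_equal(
                matrix.values[i], truth.archetypes[truth.labels[cid]]
            )

    def test_values_clipped_to_curve_rank_range(self):
        matrix, _ = ss.generate_activity_matrix(200, 20, 5, 2.0, seed=3)
        assert matrix.values.min() >= -9.0
        assert matrix.values.max() <= 9.0

    @pytest.mark.parametrize("noise_sd", [0.0, 1.0, 5.0, 50.0])
    def test_clipping_holds_for_any_noise(self, noise_sd):
        matrix, _ = ss.generate_activity_matrix(60, 6, 3, noise_sd, seed=9)
        assert matrix.values.min() >= -9.0 and matrix.values.max() <= 9.0

    def test_determinism(self):
        a, ta = ss.generate_activity_matrix(80, 12, 3, 1.5, seed=42)
        b, tb = ss.generate_activity_matrix(80, 12, 3, 1.5, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        assert ta.labels == tb.labels
        np.testing.assert_array_equal(ta.archetypes, tb.archetypes)

    def test_archetypes_distinct_and_non_constant(self):
        _, truth = ss.generate_activity_matrix(50, 4, 6, 1.0, seed=5)
        rows = [tuple(r) for r in truth.archetypes]
        assert len(set(rows)) == 6
        assert all(len(set(r)) >= 2 for r in rows)

    @pytest.mark.parametrize(
        "args", [(0, 5, 2), (10, 0, 2), (10, 5, 0), (3, 5, 4)]
    )
    def test_invalid_dimensions_rejected(self, args):
        n, m, k = args
        with pytest.raises(ValueError):
            ss.generate_activity_matrix(n, m, k, 1.0, seed=0)


class TestAnnotations:
    def test_degenerate_probabilities(self, small_truth):
        _, truth = small_truth
        table = ss.generate_annotations(truth, 1, 1.0, 0.0, seed=0)
        by_key = table.by_key()
        for cluster, genes in truth.planted_genes.items():
            for cid in sorted(truth.labels):
                key = ss.compound_key_for(cid)
                annotated = by_key.get(key, set())
                if truth.labels[cid] == cluster:
                    assert set(genes) <= annotated
                else:
                    assert not (set(genes) & annotated)

    def test_planted_genes_disjoint_and_counted(self):
        _, truth = ss.generate_activity_matrix(100, 8, 5, 1.0, seed=2)
        ss.generate_annotations(truth, 2, 0.6, 0.05, seed=3)
        all_genes = [g for genes in truth.planted_genes.values() for g in genes]
        assert len(all_genes) == 10
        assert len(set(all_genes)) == 10

    def test_equal_probabilities_show_no_cluster_signal(self):
        """With enrichment == background the within/outside annotation
        rates agree to within 3 binomial standard errors in >=95% of seeds."""
        _, truth = ss.generate_activity_matrix(300, 6, 3, 0.5, seed=4)
        members = {c: set(truth.members(c)) for c in range(3)}
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            table = ss.generate_annotations(truth, 1, 0.1, 0.1, seed=seed)
            by_key = table.by_key()
            fine = True
            for cluster, genes in truth.planted_genes.items():
                gene = genes[0]
                inside = members[cluster]
                outside = set(truth.labels) - inside
                k_in = sum(gene in by_key.get(ss.compound_key_for(c), ()) for c in inside)
                k_out = sum(gene in by_key.get(ss.compound_key_for(c), ()) for c in outside)
                p_in, p_out = k_in / len(inside), k_out / len(outside)
                se = np.sqrt(0.1 * 0.9 * (1 / len(inside) + 1 / len(outside)))
                if abs(p_in - p_out) >= 3 * se:
                    fine = False
            ok += fine
        assert ok >= 0.95 * n_seeds

    def test_enrichment_prob_monotone_in_expected_within_count(self):
        """Raising enrichment_prob (background fixed) does not decrease
        the mean within-cluster annotation count over 50 seeds."""
        _, truth = ss.generate_activity_matrix(120, 6, 3, 0.5, seed=8)
        members = {c: set(truth.members(c)) for c in range(3)}

        def mean_within(prob):
            counts = []
            for seed in range(50):
                table = ss.generate_annotations(truth, 1, prob, 0.05, seed=seed)
                by_key = table.by_key()
                total = 0
                for cluster, genes in truth.planted_genes.items():
                    gene = genes[0]
                    total += sum(
                        gene in by_key.get(ss.compound_key_for(c), ())
                        for c in members[cluster]
                    )
                counts.append(total)
            return np.mean(counts)

        means = [mean_within(p) for p in (0.1, 0.3, 0.6, 0.9)]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_invalid_probabilities_rejected(self, small_truth):
        _, truth = small_truth
        with pytest.raises(ValueError):
            ss.generate_annotations(truth, 1, 1.2, 0.0, seed=0)
        with pytest.raises(ValueError):
            ss.generate_annotations(truth, 1, 0.5, 0.9, seed=0)


class TestFingerprints:
    def test_no_flip_gives_identical_cluster_fingerprints(self, small_truth):
        _, truth = small_truth
        fps = ss.generate_fingerprints(truth, 128, 0.0, 0.2, seed=1)
        for cluster in range(truth.n_clusters):
            members = truth.members(cluster)
            first = fps[members[0]]
            assert all(fps[cid] == first for cid in members[1:])
            if first:
                assert ss.tanimoto(first, fps[members[1]]) == 1.0

    def test_intra_similarity_exceeds_inter_over_seeds(self, small_truth):
        _, truth = small_truth
        assignment = ss.ClusterAssignment(dict(truth.labels))
        for seed in range(10):
            fps = ss.generate_fingerprints(truth, 1024, 0.05, 0.1, seed=seed)
            summary = ss.intra_inter_summary(fps, assignment, seed=seed)
            assert summary.intra_mean > summary.inter_mean

    def test_determinism(self, small_truth):
        _, truth = small_truth
        a = ss.generate_fingerprints(truth, 64, 0.1, 0.2, seed=5)
        b = ss.generate_fingerprints(truth, 64, 0.1, 0.2, seed=5)
        assert a.fingerprints == b.fingerprints


class TestPathways:
    def test_no_decoys_sets_equal_planted_lists(self, annotated_truth):
        _, truth, _ = annotated_truth
        collection = ss.generate_pathways(truth, 1, 0, seed=1)
        planted = {tuple(v) for v in truth.planted_genes.values()}
        emitted = {tuple(members) for members in collection.sets.values()}
        assert emitted == planted

    def test_set_count_contract(self):
        _, truth = ss.generate_activity_matrix(100, 8, 5, 1.0, seed=6)
        ss.generate_annotations(truth, 1, 0.6, 0.05, seed=6)
        collection = ss.generate_pathways(truth, 1, 3, seed=2)
        assert len(collection) == 5

    def test_gmt_round_trip(self, annotated_truth, tmp_path):
        _, truth, _ = annotated_truth
        collection = ss.generate_pathways(truth, 2, 4, seed=3)
        path = tmp_path / "sets.gmt"
        ss.io.write_gene_sets(collection, path)
        back = ss.io.read_gene_sets(path)
        assert back.sets == collection.sets

    def test_requires_planted_genes(self):
        _, truth = ss.generate_activity_matrix(20, 5, 2, 1.0, seed=1)
        with pytest.raises(ValueError, match="planted"):
            ss.generate_pathways(truth, 1, 2, seed=0)


def test_truth_json_round_trip(annotated_truth, tmp_path):
    _, truth, _ = annotated_truth
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = ss.SyntheticTruth.from_json(path)
    assert back.labels == truth.labels
    assert back.planted_genes == truth.planted_genes
    np.testing.assert_array_equal(back.archetypes, truth.archetypes)


def test_compound_key_shape():
    key = ss.compound_key_for("C0001")
    assert len(key) == 14 and key.isupper() and key.isalpha()
    assert ss.compound_key_for("C0001") == key
    assert ss.compound_key_for("C0002") != key
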