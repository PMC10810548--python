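import numpy as np
import pytest

import somscreen as ss


@pytest.fixture
def small_truth():
    """200 compounds, 10 assays, 4 latent clusters, moderate noise."""
    matrix, truth = ss.generate_activity_matrix(200, 10, 4, 1.0, seed=11)
    return matrix, truth


@pytest.fixture
def annotated_truth(small_truth):
    """Small synthetic bundle with strong planted annotation signal."""
    matrix, truth = small_truth
    annotations = ss.generate_annotations(truth, 2, 0.7, 0.05, seed=12)
    return matrix, truth, annotations


@pytest.fixture
def truth_assignment(small_truth):
    _, truth = small_truth
    return ss.ClusterAssignment(dict(truth.labels))


def gene_map_from(truth, annotations):
    records = [
        ss.CompoundRecord.synthetic(cid, ss.compound_key_for(cid))
        for cid in sorted(truth.labels)
    ]
    joined, _ = ss.join_annotations(records, [annotations], ["synthetic"])
    return ss.annotations_by_compound(records, joined)


@pytest.fixture
def blob_matrix():
    """Two well-separated activity blobs (per-assay separation 10, sd 1)."""

    def _make(seed, n=200, n_assays=8, sep=10.0, noise_sd=1.0):
        rng = np.random.default_rng(seed)
        labels = np.arange(n) % 2
        arch = np.array([[-sep / 2] * n_assays, [sep / 2] * n_assays])
        values = np.clip(arch[labels] + rng.normal(0, noise_sd, (n, n_assays)), -9, 9)
        ids = tuple(f"C{i:04d}" for i in range(n))
        matrix = ss.ActivityMatrix(ids, tuple(f"a{j}" for j in range(n_assays)), values)
        return matrix, labels

    return _make
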