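"""k-means clustering of density rows, positivity calls and co-occupancy."""

import numpy as np
import pytest

from chipmeta import (
    ClusterAssignment,
    DensityMatrix,
    GenomicInterval,
    PeakRecord,
    PeakSet,
    call_positive_clusters,
    cooccupancy_fraction,
    kmeans_cluster,
)

OFFSETS = np.arange(-1000, 1025, 25)


def gaussian_row(height, rng, center=0.0, width=150.0, noise=0.3, baseline=0.0):
    shape = baseline + height * np.exp(-((OFFSETS - center) ** 2) / (2 * width**2))
    return np.clip(shape + rng.normal(0, noise, len(OFFSETS)), 0, None)


def two_population_matrix(n_high, n_low, seed=0, height=10.0):
    rng = np.random.default_rng(seed)
    rows = [gaussian_row(height, rng) for _ in range(n_high)]
    rows += [np.clip(rng.normal(0, 0.3, len(OFFSETS)), 0, None) for _ in range(n_low)]
    ids = [f"a{i}" for i in range(n_high + n_low)]
    return DensityMatrix(ids, OFFSETS, np.array(rows), track_id="sig")


class TestKmeans:
    def test_planted_two_population_recovery(self):
        m = two_population_matrix(60, 60, seed=1)
        a = kmeans_cluster([m], k=2, seed=0)
        labels = a.labels
        truth = np.array([1] * 60 + [2] * 60)
        acc = max((labels == truth).mean(), (labels == (3 - truth)).mean())
        assert acc == 1.0

    def test_deterministic_given_seed(self):
        m = two_population_matrix(40, 40, seed=2)
        a1 = kmeans_cluster([m], k=2, seed=7)
        a2 = kmeans_cluster([m], k=2, seed=7)
        np.testing.assert_array_equal(a1.labels, a2.labels)

    def test_identical_rows_deterministic(self):
        values = np.tile(np.ones(len(OFFSETS)), (10, 1))
        m = DensityMatrix([f"a{i}" for i in range(10)], OFFSETS, values, track_id="t")
        a1 = kmeans_cluster([m], k=2, seed=3)
        a2 = kmeans_cluster([m], k=2, seed=3)
        np.testing.assert_array_equal(a1.labels, a2.labels)
        assert a1.sizes.sum() == 10

    def test_mismatched_anchor_ids_rejected(self):
        m1 = two_population_matrix(5, 5)
        m2 = two_population_matrix(5, 5)
        m2.ids = [f"b{i}" for i in range(10)]
        with pytest.raises(ValueError, match="share"):
            kmeans_cluster([m1, m2], k=2)

    def test_k_larger_than_anchors_rejected(self):
        m = two_population_matrix(3, 3)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster([m], k=10)

    def test_all_zero_matrix_rejected(self):
        m = DensityMatrix(["a", "b"], OFFSETS, np.zeros((2, len(OFFSETS))))
        with pytest.raises(ValueError, match="zero"):
            kmeans_cluster([m], k=2)

    def test_cluster_semantics_from_profiles_not_labels(self):
        """The high-signal population is identified by its mean profile,
        whatever label k-means happened to give it."""
        m = two_population_matrix(30, 90, seed=4)
        a = kmeans_cluster([m], k=2, seed=0)
        positive = call_positive_clusters(a, "sig")
        members = {i for c in positive for i in a.members(c)}
        assert members == {f"a{i}" for i in range(30)}


def assignment_with_profiles(centrals, flanks, sizes):
    """Assemble a ClusterAssignment directly from per-cluster profile levels."""
    k = len(centrals)
    prof = np.zeros((k, len(OFFSETS)))
    for c in range(k):
        prof[c] = flanks[c]
        prof[c, np.abs(OFFSETS) <= 100] = centrals[c]
    labels = np.concatenate([[c + 1] * sizes[c] for c in range(k)])
    ids = [f"a{i}" for i in range(labels.size)]
    return ClusterAssignment(ids, k, labels, 0, {"q": prof}, {"q": OFFSETS})


class TestPositiveClusters:
    def test_clear_enrichment_called_positive(self):
        a = assignment_with_profiles([10.0, 1.0, 1.0], [1.0, 1.0, 1.0], [5, 5, 5])
        assert call_positive_clusters(a, "q", threshold=2.0) == {1}

    def test_background_level_cluster_negative(self):
        a = assignment_with_profiles([1.0, 1.0], [1.0, 1.0], [5, 5])
        assert call_positive_clusters(a, "q", threshold=2.0) == set()

    def test_three_cluster_design_calls_match(self):
        """Factor-A-only / A+B / background design: positivity per track."""
        rng = np.random.default_rng(6)
        n = 40

        def bg_row():
            return np.clip(rng.normal(1, 0.2, len(OFFSETS)), 0, None)

        rows_a, rows_b = [], []
        for _ in range(n):  # cluster 1: A only
            rows_a.append(gaussian_row(10, rng, baseline=1.0))
            rows_b.append(bg_row())
        for _ in range(n):  # cluster 2: A and B
            rows_a.append(gaussian_row(10, rng, baseline=1.0))
            rows_b.append(gaussian_row(10, rng, baseline=1.0))
        for _ in range(n):  # cluster 3: background
            rows_a.append(bg_row())
            rows_b.append(bg_row())
        ids = [f"a{i}" for i in range(3 * n)]
        ma = DensityMatrix(ids, OFFSETS, np.array(rows_a), track_id="A")
        mb = DensityMatrix(ids, OFFSETS, np.array(rows_b), track_id="B")
        a = kmeans_cluster([ma, mb], k=3, seed=1)
        pos_a = {i for c in call_positive_clusters(a, "A") for i in a.members(c)}
        pos_b = {i for c in call_positive_clusters(a, "B") for i in a.members(c)}
        assert pos_a == {f"a{i}" for i in range(2 * n)}
        assert pos_b == {f"a{i}" for i in range(n, 2 * n)}


def peak(chrom, start, end, pid, t=1.0):
    return PeakRecord(GenomicInterval(chrom, start, end), (start + end) // 2, t, pid)


class TestCooccupancy:
    def test_query_positive_everywhere_is_100(self):
        a = assignment_with_profiles([10.0, 8.0], [1.0, 1.0], [6, 4])
        ref = PeakSet("A", [peak("chr1", i * 1000, i * 1000 + 100, f"p{i}") for i in range(10)])
        res = cooccupancy_fraction(ref, assignment=a, query_track_id="q")
        assert res.fraction == 100.0 and res.mode == "cluster"

    def test_query_positive_nowhere_is_0(self):
        a = assignment_with_profiles([1.0, 1.0], [1.0, 1.0], [6, 4])
        ref = PeakSet("A", [peak("chr1", i * 1000, i * 1000 + 100, f"p{i}") for i in range(10)])
        assert cooccupancy_fraction(ref, assignment=a, query_track_id="q").fraction == 0.0

    def test_overlap_mode_requires_one_bp(self):
        ref = PeakSet("A", [peak("chr1", 0, 100, "a1"), peak("chr1", 200, 300, "a2")])
        query = PeakSet("B", [peak("chr1", 99, 150, "b1"), peak("chr1", 300, 400, "b2")])
        res = cooccupancy_fraction(ref, query_peaks=query)
        # a1 overlaps b1 by 1 bp; a2 abuts b2 ([200,300) vs [300,400)) — no overlap
        assert res.n_cobound == 1 and res.fraction == 50.0 and res.mode == "overlap"
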