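import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simpa.core import make_training
from simpa.evaluation import (
    consensus_profile,
    crossvalidate_bin,
    davies_bouldin,
    downsample_profile,
    jaccard,
    randomized_input,
    recall_of_removed_bins,
    run_simulation,
    specificity,
)
from simpa.genome_bins import BinSet
from simpa.reference import drop_rows

from conftest import binset, make_reference


class TestJaccard:
    def test_identities(self):
        a = binset([1, 2, 3])
        assert jaccard(a, a) == 1.0
        assert jaccard(a, binset([7, 8])) == 0.0
        assert jaccard(a, binset([2, 3, 4])) == 0.5
        assert jaccard(a, binset([])) == 0.0
        assert jaccard(binset([]), binset([])) == 1.0

    def test_bin_size_mismatch(self):
        with pytest.raises(ValueError):
            jaccard(binset([1]), binset([1], bin_size=1000))

    @settings(max_examples=50, derandomize=True)
    @given(
        st.sets(st.integers(0, 50), max_size=25),
        st.sets(st.integers(0, 50), max_size=25),
    )
    def test_symmetric_and_bounded(self, xs, ys):
        a, b = binset(xs), binset(ys)
        j = jaccard(a, b)
        assert j == jaccard(b, a)
        assert 0.0 <= j <= 1.0


class TestCrossvalidateBin:
    def test_perfectly_separable_class(self, benchmark):
        rs = benchmark.rs
        sc = rs.row_binset(0)
        tf, _ = make_training(rs, sc)
        # a class vector equal to a balanced training column is learnable
        # nearly perfectly (full 10-fold CV needs >= 10 minority rows)
        col = next(
            j for j in range(tf.s) if 10 <= tf.values[:, j].sum() <= rs.n - 10
        )
        rec = crossvalidate_bin(tf, tf.values[:, col].copy(), folds=10, seed=0)
        assert rec.auroc > 0.95

    def test_constant_class_skipped(self, tiny_reference):
        tf, _ = make_training(tiny_reference, binset([1]))
        assert crossvalidate_bin(tf, np.ones(4, dtype=np.uint8)) is None

    def test_minority_below_two_skipped(self, tiny_reference):
        tf, _ = make_training(tiny_reference, binset([1]))
        assert crossvalidate_bin(tf, np.array([1, 0, 0, 0], dtype=np.uint8)) is None

    def test_folds_reduced_to_minority(self, benchmark):
        rs = benchmark.rs
        tf, _ = make_training(rs, rs.row_binset(0))
        y = np.zeros(rs.n, dtype=np.uint8)
        y[:3] = 1
        rec = crossvalidate_bin(tf, y, folds=10, seed=1, trees=20)
        assert rec.folds == 3

    def test_auprc_matches_permutation_null_on_shuffled_labels(self, benchmark):
        """With labels shuffled independently of features, the pooled
        out-of-fold AUPRC matches its finite-sample permutation-null
        expectation (which exceeds the class balance at n=30)."""
        from sklearn.metrics import average_precision_score

        rs = benchmark.rs
        tf, _ = make_training(rs, rs.row_binset(0))
        rng = np.random.default_rng(5)
        diffs = []
        for rep in range(40):
            y = np.zeros(rs.n, dtype=np.uint8)
            y[rng.choice(rs.n, rng.integers(3, 15), replace=False)] = 1
            rec = crossvalidate_bin(tf, rng.permutation(y), folds=10, seed=rep, trees=50)
            null = np.mean(
                [
                    average_precision_score(rng.permutation(y), rng.random(rs.n))
                    for _ in range(60)
                ]
            )
            diffs.append(rec.auprc - null)
        assert abs(np.mean(diffs)) < 0.05


class TestDownsample:
    def test_size_equal_returns_origin(self):
        origin = binset(range(20))
        assert downsample_profile(origin, 20, 3) == origin

    def test_subset_and_deterministic(self):
        origin = binset(range(50))
        a = downsample_profile(origin, 10, 3)
        b = downsample_profile(origin, 10, 3)
        assert a == b and len(a) == 10 and a.keys <= origin.keys

    def test_oversized_request(self):
        with pytest.raises(ValueError):
            downsample_profile(binset([1, 2]), 3, 0)


class TestRunSimulation:
    def test_loo_and_exclusion_rules(self, small_benchmark):
        rs, truth = small_benchmark
        report = run_simulation(rs, rs.experiments[0].accession, [30], "loo", 4, trees=20)
        row = report.iloc[0]
        assert row["mode"] == "leave_out_origin" or row["mode"] == "loo"
        # candidates never include input bins and AUROC is a probability
        assert 0.0 <= row["auroc"] <= 1.0
        assert row["n_candidates"] < rs.m

    def test_loct_excludes_whole_biosample(self, small_benchmark):
        rs, truth = small_benchmark
        origin = rs.experiments[0]
        pruned = drop_rows(rs, "loct", origin)
        assert all(e.biosample != origin.biosample for e in pruned.experiments)


class TestConsensus:
    def test_majority_rule(self):
        rs = make_reference(
            {"O": [0], "P1": [1, 2], "P2": [1, 3], "P3": [1, 2]},
        )
        cons = consensus_profile(rs, "O")
        assert cons.keys == {("chrT", 1), ("chrT", 2)}  # 3/3 and 2/3 > 0.5

    def test_two_peers_need_both(self):
        rs = make_reference({"O": [0], "P1": [1, 2], "P2": [2, 3]})
        cons = consensus_profile(rs, "O")
        assert cons.keys == {("chrT", 2)}  # 1 of 2 peers is not > 0.5

    def test_single_peer_is_consensus(self):
        rs = make_reference({"O": [0], "P1": [1, 2]})
        assert consensus_profile(rs, "O").keys == {("chrT", 1), ("chrT", 2)}

    def test_no_peer_error(self):
        rs = make_reference(
            {"O": [0], "X": [1]}, biosamples={"O": "liver", "X": "brain"}
        )
        with pytest.raises(ValueError, match="no peer"):
            consensus_profile(rs, "O")


class TestSpecificity:
    def test_imputed_equals_origin(self):
        origin, cons, inp = binset([1, 2, 3, 4]), binset([3, 4, 5]), binset([1])
        rec = specificity(origin, origin, cons, inp)
        assert rec.specificity == pytest.approx(1.0 - rec.j_consensus)
        assert rec.specificity >= 0

    def test_imputed_equals_consensus_nonpositive(self):
        origin, cons, inp = binset([1, 2, 3]), binset([3, 4, 5]), binset([])
        rec = specificity(cons, origin, cons, inp)
        assert rec.specificity <= 0

    def test_all_equal_gives_zero(self):
        s = binset([1, 2, 3])
        assert specificity(s, s, s, binset([])).specificity == 0.0

    def test_antisymmetric_in_origin_consensus(self):
        imp, a, b, inp = binset([1, 2, 5]), binset([1, 2, 3]), binset([2, 6]), binset([2])
        assert specificity(imp, a, b, inp).specificity == pytest.approx(
            -specificity(imp, b, a, inp).specificity
        )

    def test_input_bins_removed_from_all_sets(self):
        imp, origin, cons = binset([1, 2]), binset([1, 3]), binset([1, 4])
        rec = specificity(imp, origin, cons, binset([1]))
        assert rec.j_origin == 0.0 and rec.j_consensus == 0.0
        assert rec.input_size == 1


class TestRandomizedInput:
    def test_subset_of_reference_columns(self, tiny_reference):
        bins = randomized_input(tiny_reference, 3, 5)
        assert len(bins) == 3
        assert all(k in tiny_reference for k in bins.keys)
        assert randomized_input(tiny_reference, 3, 5) == bins

    def test_oversized(self, tiny_reference):
        with pytest.raises(ValueError):
            randomized_input(tiny_reference, 99, 0)


class TestDaviesBouldin:
    def test_hand_computed_instance(self):
        points = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [4.0, 1.0]])
        labels = ["a", "a", "b", "b"]
        # centroids (0,.5) and (4,.5); intra = .5 each; R = 1/4
        assert davies_bouldin(points, labels) == pytest.approx(0.25)

    def test_well_separated_clusters_near_zero(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.01, (20, 2)), rng.normal(100, 0.01, (20, 2))])
        labels = [0] * 20 + [1] * 20
        assert davies_bouldin(pts, labels) < 0.01

    def test_coincident_centroids_inf(self):
        pts = np.array([[0, 0], [1, 1], [0, 0], [1, 1]], dtype=float)
        assert davies_bouldin(pts, ["a", "a", "b", "b"]) == np.inf

    def test_single_cluster_error(self):
        with pytest.raises(ValueError):
            davies_bouldin(np.zeros((3, 2)), ["a", "a", "a"])

    def test_matches_sklearn_on_generic_data(self):
        from sklearn.metrics import davies_bouldin_score

        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(i * 3, 1.0, (15, 3)) for i in range(3)])
        labels = np.repeat([0, 1, 2], 15)
        assert davies_bouldin(pts, labels) == pytest.approx(
            davies_bouldin_score(pts, labels), rel=1e-9
        )


class TestRecall:
    def test_zero_removal_is_vacuous(self, tiny_reference):
        assert recall_of_removed_bins(tiny_reference, binset([0, 1, 2]), 0.0, 1) == 1.0

    def test_recall_over_removed_reference_bins_only(self, small_benchmark):
        rs, truth = small_benchmark
        cell = rs.row_binset(0)
        extra = BinSet(set(cell.keys) | {("chrS", 10_000)}, rs.bin_size, rs.assembly)
        r = recall_of_removed_bins(rs, extra, 0.2, 3, trees=20)
        assert 0.0 <= r <= 1.0
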