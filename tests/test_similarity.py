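"""Group-mean clustering and Mahalanobis similarity with permutation nulls."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from sputumpanel.containers import MediatorMatrix
from sputumpanel.similarity import (
    MediatorSubset,
    group_means,
    hierarchical_cluster,
    mahalanobis_distance,
    pairwise_similarity,
    permutation_test,
    pooled_within_group_cov,
    scale_rows,
)

from conftest import make_participants


def _dataset(group_means_dict, n_per_group=20, sd=1.0, seed=0):
    """Gaussian groups around given mean vectors; log2-scale matrix."""
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    i = 0
    p = len(next(iter(group_means_dict.values())))
    for g, mu in group_means_dict.items():
        rows.append(np.asarray(mu) + sd * rng.standard_normal((n_per_group, p)))
        for _ in range(n_per_group):
            meta.append({"participant_id": f"P{i:03d}", "group": g, "batch": "b1"})
            i += 1
    participants = pd.DataFrame(meta).set_index("participant_id")
    values = pd.DataFrame(
        np.vstack(rows), index=participants.index, columns=[f"M{j}" for j in range(p)]
    )
    return MediatorMatrix(values, scale="log2"), participants


SUBSET3 = MediatorSubset("test", ("M0", "M1", "M2"))


class TestGroupMeans:
    def test_hand_case(self):
        matrix, participants = _dataset({"A": [0, 0], "B": [0, 0]}, n_per_group=2, sd=0)
        matrix.values.iloc[:] = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]]
        means = group_means(matrix, participants)
        np.testing.assert_allclose(means.loc["A"], [2.0, 3.0])
        np.testing.assert_allclose(means.loc["B"], [6.0, 7.0])

    def test_single_participant_group(self):
        matrix, participants = _dataset({"A": [1, 2], "B": [3, 4]}, n_per_group=1, sd=0)
        means = group_means(matrix, participants)
        np.testing.assert_allclose(means.to_numpy(), matrix.values.to_numpy())

    def test_unknown_subset_member_errors(self):
        matrix, participants = _dataset({"A": [0, 0], "B": [0, 0]}, n_per_group=3)
        with pytest.raises(ValueError, match="not in matrix"):
            group_means(matrix, participants, MediatorSubset("x", ("M0", "ZZZ")))


class TestScaleRows:
    def test_forced_values(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"], columns=list("abc"))
        np.testing.assert_allclose(scale_rows(df).to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_errors(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0]], index=["r"], columns=list("abc"))
        with pytest.raises(ValueError, match="zero-SD"):
            scale_rows(df)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(0, 3, (4, 6)))
        once = scale_rows(df)
        twice = scale_rows(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 1.5], [1.0, 2.0, 1.5], [9.0, 8.0, 9.5]],
            index=["A", "B", "C"],
            columns=["x", "y", "z"],
        )
        result = hierarchical_cluster(df)
        assert result.row_linkage[0, 2] == pytest.approx(0.0)
        assert set(result.row_linkage[0, :2].astype(int)) == {0, 1}

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (6, 5)))
        result = hierarchical_cluster(df)
        assert (np.diff(result.row_linkage[:, 2]) >= -1e-12).all()

    def test_matches_brute_force_distances(self):
        df = pd.DataFrame(
            [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0], [1.0, 1.0, 1.0], [5.0, 5.0, 5.0]],
            index=list("ABCD"),
        )
        result = hierarchical_cluster(df)
        manual = squareform(
            [np.sqrt(((df.iloc[i] - df.iloc[j]) ** 2).sum()) for i in range(4) for j in range(i + 1, 4)]
        )
        # first merge joins the closest pair at exactly their Euclidean distance
        i, j = result.row_linkage[0, :2].astype(int)
        assert result.row_linkage[0, 2] == pytest.approx(manual[i, j])

    def test_planted_partition_recovered(self):
        matrix, participants = _dataset(
            {"A": [2, 2, 0, 0], "B": [2, 2, 0, 0], "C": [0, 0, 0, 0]},
            n_per_group=200,
            seed=2,
        )
        means = group_means(matrix, participants)
        result = hierarchical_cluster(means)
        first = set(result.row_linkage[0, :2].astype(int))
        assert first == {0, 1}  # A and B join before C

    def test_newick_roundtrip_labels(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(0, 1, (4, 3)), index=list("WXYZ"))
        nwk = hierarchical_cluster(df).row_newick()
        assert nwk.endswith(";")
        for label in "WXYZ":
            assert label in nwk


class TestMahalanobis:
    def test_euclidean_reduction(self):
        d = mahalanobis_distance([0, 0], [3, 4], np.eye(2))
        assert d == pytest.approx(5.0)

    def test_zero_for_equal_means(self):
        assert mahalanobis_distance([1, 2], [1, 2], np.eye(2)) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        A = rng.normal(0, 1, (5, 3))
        S = A.T @ A + np.eye(3)
        a, b = rng.normal(0, 1, 3), rng.normal(0, 1, 3)
        assert mahalanobis_distance(a, b, S) == pytest.approx(
            mahalanobis_distance(b, a, S), abs=1e-12
        )

    def test_matches_explicit_inverse(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (50, 3))
        labels = np.repeat([0, 1], 25)
        S = pooled_within_group_cov(X, labels)
        mu_a, mu_b = X[:25].mean(axis=0), X[25:].mean(axis=0)
        d = mahalanobis_distance(mu_a, mu_b, S)
        diff = mu_a - mu_b
        expected = np.sqrt(diff @ np.linalg.inv(S) @ diff)
        assert d == pytest.approx(expected, abs=1e-10)

    def test_linear_invariance(self):
        """Invariant under a common invertible linear map applied to means
        and covariance consistently."""
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 3), rng.normal(0, 1, 3)
        M = rng.normal(0, 1, (6, 3))
        S = M.T @ M + 0.5 * np.eye(3)
        T = rng.normal(0, 1, (3, 3)) + 2 * np.eye(3)
        d1 = mahalanobis_distance(a, b, S)
        d2 = mahalanobis_distance(T @ a, T @ b, T @ S @ T.T)
        assert d1 == pytest.approx(d2, rel=1e-8)


class TestPairwiseSimilarity:
    def test_minmax_attains_zero_and_one(self):
        matrix, participants = _dataset(
            {"A": [0, 0, 0], "B": [1, 0, 0], "C": [4, 4, 4], "D": [2, 2, 0]}, seed=7
        )
        report = pairwise_similarity(matrix, participants, SUBSET3)
        scaled = report.table["scaled_similarity"]
        assert scaled.max() == 1.0
        assert scaled.min() == 0.0
        assert scaled.between(0, 1).all()

    def test_inversion_and_scaling_arithmetic(self):
        """Distances {2,4,10} force similarities {0.5,0.25,0.1} and scaled
        scores {1.0, 0.375, 0.0}."""
        d = np.array([2.0, 4.0, 10.0])
        s = 1.0 / d
        scaled = (s - s.min()) / (s.max() - s.min())
        np.testing.assert_allclose(scaled, [1.0, 0.375, 0.0])
        # and the pipeline reproduces that arithmetic on its own distances
        matrix, participants = _dataset(
            {"A": [0, 0, 0], "B": [1, 1, 1], "C": [3, 3, 3]}, n_per_group=30, seed=8
        )
        report = pairwise_similarity(matrix, participants, SUBSET3)
        t = report.table
        s2 = 1.0 / t["distance"]
        expect = (s2 - s2.min()) / (s2.max() - s2.min())
        np.testing.assert_allclose(t["scaled_similarity"], expect, atol=1e-12)

    def test_order_reversal(self):
        matrix, participants = _dataset(
            {"A": [0, 0, 0], "B": [1, 0, 0], "C": [5, 5, 5], "D": [2, 0, 2]}, seed=9
        )
        t = pairwise_similarity(matrix, participants, SUBSET3).table
        ranks_d = t["distance"].rank()
        ranks_s = t["scaled_similarity"].rank(ascending=False)
        assert (ranks_d == ranks_s).all()

    def test_planted_twin_is_most_similar(self):
        """Group X drawn from Y's distribution; every other group >= 3 SD away."""
        hits = 0
        for seed in range(20):
            matrix, participants = _dataset(
                {
                    "X": [0, 0, 0],
                    "Y": [0, 0, 0],
                    "U": [3, 3, 3],
                    "V": [-3, 3, -3],
                },
                n_per_group=25,
                seed=100 + seed,
            )
            t = pairwise_similarity(matrix, participants, SUBSET3).table
            top = t.loc[t["scaled_similarity"].idxmax()]
            hits += {top.group_a, top.group_b} == {"X", "Y"}
        assert hits >= 19

    def test_duplicate_group_means_error(self):
        # groups A and B have identical means but nonzero within-group spread
        block = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        vals = np.vstack([block, block, block + [5, 5, 5]])
        participants = make_participants({"A": 4, "B": 4, "C": 4})
        values = pd.DataFrame(
            vals, index=participants.index, columns=["M0", "M1", "M2"]
        )
        matrix = MediatorMatrix(values, scale="log2")
        with pytest.raises(ZeroDivisionError, match="duplicate group means"):
            pairwise_similarity(matrix, participants, SUBSET3)

    def test_needs_three_groups(self):
        matrix, participants = _dataset({"A": [0, 0, 0], "B": [1, 1, 1]}, seed=11)
        with pytest.raises(ValueError, match=">= 3 groups"):
            pairwise_similarity(matrix, participants, SUBSET3)


class TestPermutationTest:
    def test_zero_permutations_rejected(self):
        matrix, participants = _dataset(
            {"A": [0, 0, 0], "B": [1, 1, 1], "C": [2, 2, 2]}, seed=12
        )
        with pytest.raises(ValueError, match="n_permutations"):
            permutation_test(matrix, participants, SUBSET3, n_permutations=0)

    def test_extreme_separation_flagged_far(self):
        matrix, participants = _dataset(
            {"A": [0, 0, 0], "B": [0.5, 0, 0], "C": [0, 0.5, 0], "OUT": [10, 10, 10]},
            n_per_group=30,
            seed=13,
        )
        report = permutation_test(matrix, participants, SUBSET3, n_permutations=500, seed=1)
        t = report.table
        out_pairs = t[(t.group_a == "OUT") | (t.group_b == "OUT")]
        assert out_pairs["far"].all()
        assert not out_pairs["close"].any()

    def test_percentiles_in_range_and_flags_exclusive(self):
        matrix, participants = _dataset(
            {"A": [0, 0, 0], "B": [1, 0, 1], "C": [0, 1, 0]}, seed=14
        )
        t = permutation_test(matrix, participants, SUBSET3, n_permutations=200, seed=2).table
        assert t["percentile"].between(0, 100).all()
        assert not (t["far"] & t["close"]).any()

    def test_seeded_reproducibility(self):
        matrix, participants = _dataset(
            {"A": [0, 0, 0], "B": [1, 0, 1], "C": [0, 1, 0]}, seed=15
        )
        t1 = permutation_test(matrix, participants, SUBSET3, n_permutations=100, seed=3).table
        t2 = permutation_test(matrix, participants, SUBSET3, n_permutations=100, seed=3).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_per_pair_null_option(self):
        matrix, participants = _dataset(
            {"A": [0, 0, 0], "B": [1, 0, 1], "C": [0, 1, 0]}, seed=16
        )
        pooled = permutation_test(
            matrix, participants, SUBSET3, n_permutations=200, seed=4, pooled_null=True
        )
        per_pair = permutation_test(
            matrix, participants, SUBSET3, n_permutations=200, seed=4, pooled_null=False
        )
        assert not np.allclose(
            pooled.table["percentile"], per_pair.table["percentile"]
        )
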