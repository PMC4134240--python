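import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirddct.cluster import (
    choose_elbow,
    elbow_select,
    hierarchical_order,
    k_median,
    masked_euclidean,
    pairwise_correlation,
)


def pairs_matrix(X):
    """points x dims array (NaN = missing) -> assay x pair frame."""
    X = np.asarray(X, dtype=float)
    m = pd.DataFrame(
        X.T,
        index=[f"miR-{i}" for i in range(X.shape[1])],
        columns=[f"P{i}" for i in range(X.shape[0])],
    )
    m.index.name = "assay_id"
    return m


def brute_force_two_partition(X):
    """Minimum-cost 2-partition by enumerating every bipartition, with
    per-coordinate median centers and masked distances."""
    n, d = X.shape
    best_cost, best_labels = np.inf, None
    for bits in range(1, 2 ** (n - 1)):
        labels = np.array([(bits >> i) & 1 for i in range(n)])
        cost = 0.0
        for g in (0, 1):
            members = X[labels == g]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                center = np.nanmedian(members, axis=0)
            for x in members:
                cost += masked_euclidean(x, center, d)
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_cost, best_labels


class TestMaskedEuclidean:
    def test_identical_co_observed_parts_give_zero(self):
        assert masked_euclidean([1, 2, np.nan], [1, 2, 5]) == 0.0

    def test_rescaling_formula(self):
        assert masked_euclidean([0, np.nan], [3, 4], 2) == pytest.approx(np.sqrt(2 * 9))

    @given(st.integers(0, 2**32 - 1))
    def test_reduces_to_euclidean_when_complete(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert masked_euclidean(x, y) == pytest.approx(float(np.linalg.norm(x - y)))

    def test_incomparable_vectors_rejected(self):
        with pytest.raises(ValueError, match="incomparable"):
            masked_euclidean([np.nan, 1.0], [2.0, np.nan])


class TestKMedian:
    def test_well_separated_blobs(self):
        X = np.array([[0, 0], [0, 1], [10, 10], [10, 11]], dtype=float)
        model = k_median(pairs_matrix(X), k=2, seed=0, n_restarts=5)
        labels = model.assignments.to_numpy()
        assert labels[0] == labels[1] != labels[2] == labels[3]
        centers = {tuple(c) for _, c in model.centers.iterrows()}
        assert centers == {(0.0, 0.5), (10.0, 10.5)}

    def test_k_equals_n_zero_cost(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        model = k_median(pairs_matrix(X), k=5, seed=0, n_restarts=5)
        assert model.cost == pytest.approx(0.0)
        assert model.assignments.nunique() == 5

    def test_k1_center_is_coordinate_median(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 4))
        model = k_median(pairs_matrix(X), k=1, seed=0, n_restarts=3)
        med = np.median(X, axis=0)
        assert model.centers.iloc[0].to_numpy() == pytest.approx(med)
        expected = sum(float(np.linalg.norm(x - med)) for x in X)
        assert model.cost == pytest.approx(expected)

    def test_cost_self_consistent(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        X[rng.uniform(size=X.shape) < 0.2] = np.nan
        m = pairs_matrix(X)
        model = k_median(m, k=3, seed=0, n_restarts=10)
        recomputed = 0.0
        for pair_id, label in model.assignments.items():
            recomputed += masked_euclidean(
                m[pair_id].to_numpy(), model.centers.loc[label].to_numpy(), m.shape[0]
            )
        assert model.cost == pytest.approx(recomputed)

    def test_matches_enumeration_on_missing_data_instance(self):
        # 6 pairs x 3 assays with 4 missing cells, fixed instance
        X = np.array(
            [
                [0.1, 0.0, np.nan],
                [0.0, 0.2, 0.1],
                [np.nan, 0.1, 0.0],
                [5.0, 5.2, np.nan],
                [5.1, np.nan, 5.0],
                [4.9, 5.0, 5.1],
            ]
        )
        oracle_cost, oracle_labels = brute_force_two_partition(X)
        model = k_median(pairs_matrix(X), k=2, seed=0, n_restarts=20)
        assert model.cost == pytest.approx(oracle_cost)
        found = model.assignments.to_numpy() - 1
        assert (found == oracle_labels).all() or (found == 1 - oracle_labels).all()

    def test_relabeling_leaves_partition_and_cost(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (4, 4)), rng.normal(8, 1, (4, 4))])
        m = pairs_matrix(X)
        a = k_median(m, k=2, seed=0, n_restarts=10)
        b = k_median(m, k=2, seed=99, n_restarts=10)
        assert a.cost == pytest.approx(b.cost)
        same = (a.assignments == b.assignments).all()
        flipped = (a.assignments == 3 - b.assignments).all()
        assert same or flipped

    def test_k_beyond_pairs_rejected(self):
        with pytest.raises(ValueError):
            k_median(pairs_matrix(np.zeros((3, 2))), k=4)


class TestElbow:
    def test_second_difference_on_worked_curve(self):
        # second differences (55, 3, 1) peak at k = 2
        assert choose_elbow([1, 2, 3, 4, 5], [100, 40, 35, 33, 32]) == 2

    def test_linear_curve_tie_breaks_to_two(self):
        assert choose_elbow([1, 2, 3, 4, 5], [100, 80, 60, 40, 20]) == 2

    def test_non_monotone_curve_warns_but_selects(self, caplog):
        with caplog.at_level("WARNING"):
            k = choose_elbow([1, 2, 3, 4], [100, 40, 45, 44])
        assert "monotone" in caplog.text
        assert k in (2, 3)

    def test_k_range_must_start_at_one(self):
        with pytest.raises(ValueError):
            elbow_select(pairs_matrix(np.zeros((5, 2))), k_range=[2, 3, 4])

    def test_two_blob_data_selects_two(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.3, size=(6, 4)), rng.normal(6, 0.3, size=(5, 4))]
        )
        curve = elbow_select(pairs_matrix(X), range(1, 5), seed=0, n_restarts=10)
        assert curve.chosen_k == 2
        assert curve.costs == tuple(sorted(curve.costs, reverse=True))


def brute_force_complete_linkage(X):
    """Agglomerate by recomputing complete-linkage distances each step."""
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(
                masked_euclidean(X[i], X[j], X.shape[1])
                for i in clusters[a]
                for j in clusters[b]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((sorted((frozenset(clusters[a]), frozenset(clusters[b])), key=sorted), d))
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return merges


class TestHierarchicalOrder:
    def test_nearest_rows_merge_first(self):
        m = pairs_matrix(np.array([[0, 0, 9], [0, 0, 9], [0, 1, 9]]).T)
        # here rows of the matrix are miR-0..2 = (0,0,0),(0,0,1),(9,9,9)
        m = pd.DataFrame(
            [[0, 0, 0], [0, 0, 1], [9, 9, 9]],
            index=["miR-0", "miR-1", "miR-2"],
            columns=["P0", "P1", "P2"],
        )
        row_order, _, row_tree, _ = hierarchical_order(m)
        assert {int(row_tree[0, 0]), int(row_tree[0, 1])} == {0, 1}
        assert row_order.index("miR-2") in (0, 2)

    def test_matches_brute_force_agglomeration(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 4)).round(2)
        m = pd.DataFrame(X, index=[f"r{i}" for i in range(5)], columns=list("abcd"))
        _, _, tree, _ = hierarchical_order(m)
        oracle = brute_force_complete_linkage(X)
        assert [round(d, 6) for _, d in oracle] == [round(h, 6) for h in tree[:, 2]]

    def test_row_permutation_preserves_merge_heights(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 4))
        m = pd.DataFrame(X, index=[f"r{i}" for i in range(6)], columns=list("abcd"))
        perm = m.sample(frac=1, random_state=7)
        _, _, t1, _ = hierarchical_order(m)
        _, _, t2, _ = hierarchical_order(perm)
        assert t1[:, 2] == pytest.approx(t2[:, 2])

    def test_incomparable_rows_named(self):
        m = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 2.0]], index=["r0", "r1"], columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="r0.*r1"):
            hierarchical_order(m)


class TestPairwiseCorrelation:
    def _matrix(self, a, b):
        m = pd.DataFrame([a, b], index=["x", "y"], columns=[f"P{i}" for i in range(len(a))])
        return m

    def test_identical_rows_give_one(self):
        r, n = pairwise_correlation(self._matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), "x", "y")
        assert r == pytest.approx(1.0) and n == 3

    def test_reversed_rows_give_minus_one(self):
        r, _ = pairwise_correlation(self._matrix([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]), "x", "y")
        assert r == pytest.approx(-1.0)

    def test_complete_subset_only(self):
        m = self._matrix([1.0, 2.0, 4.0, np.nan], [2.0, 4.0, 8.0, 5.0])
        r, n = pairwise_correlation(m, "x", "y")
        assert r == pytest.approx(1.0) and n == 3

    def test_too_few_complete_pairs_rejected(self):
        m = self._matrix([1.0, np.nan, 3.0], [2.0, 4.0, np.nan])
        with pytest.raises(ValueError, match="complete pairs"):
            pairwise_correlation(m, "x", "y")

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pairwise_correlation(self._matrix([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]), "x", "y")
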