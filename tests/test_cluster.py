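import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy as sch
from sklearn.metrics import adjusted_rand_score

import dietshift as ds
from dietshift.core_io import ValidationError


def test_two_points_merge_height():
    """Single merge at the weighted Ward cost m1*m2/(m1+m2) * d^2."""
    X = np.array([[0.0, 0.0], [3.0, 4.0]])
    w = np.array([2.0, 1.0])
    tree = ds.ward_tree(X, w)
    assert tree.merges.shape == (1, 4)
    assert tree.merges[0, 2] == pytest.approx(2.0 * 1.0 / 3.0 * 25.0)


def test_three_collinear_points_first_merge():
    """Points at 0, 1, 10: the cheapest first merge is {0, 1} — verified by
    enumerating all merge orders' first-step costs."""
    X = np.array([[0.0], [1.0], [10.0]])
    costs = {(i, j): 0.5 * (X[i, 0] - X[j, 0]) ** 2
             for i in range(3) for j in range(i + 1, 3)}
    assert min(costs, key=costs.get) == (0, 1)
    tree = ds.ward_tree(X)
    assert set(tree.merges[0, :2].astype(int)) == {0, 1}


def test_weight_expansion_equivalence():
    """A point with weight 2 behaves exactly like two coincident unit-weight
    copies: same merge heights."""
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (12, 3))
    w = np.ones(12)
    w[4] = 2.0
    tree_w = ds.ward_tree(X, w)
    X_rep = np.vstack([X, X[4]])
    tree_r = ds.ward_tree(X_rep)
    # replicated tree has one extra zero-height merge (the coincident pair)
    assert tree_r.merges[0, 2] == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(np.sort(tree_w.merges[:, 2]),
                               np.sort(tree_r.merges[1:, 2]), rtol=1e-9)


def test_weight_expansion_identical_labels():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (30, 2)) + np.repeat([[0, 0], [6, 6], [12, 0]], 10, axis=0)
    w = rng.integers(1, 4, 30).astype(float)
    sol_w = ds.cut_and_consolidate(ds.ward_tree(X, w), 3, X, w)
    rep = np.repeat(np.arange(30), w.astype(int))
    sol_r = ds.cut_and_consolidate(ds.ward_tree(X[rep]), 3, X[rep])
    lab_r_first = sol_r.labels.to_numpy()[np.searchsorted(rep, np.arange(30))]
    assert adjusted_rand_score(sol_w.labels.to_numpy(), lab_r_first) == 1.0


def test_matches_scipy_ward_unit_weights():
    """With unit weights the merge heights equal scipy's Ward distances
    squared over 2, and cutting both trees gives identical partitions."""
    rng = np.random.default_rng(2)
    X = rng.normal(0, 1, (40, 4))
    tree = ds.ward_tree(X)
    Z = sch.linkage(X, method="ward")
    np.testing.assert_allclose(tree.merges[:, 2], Z[:, 2] ** 2 / 2.0, rtol=1e-8)
    for k in (2, 3, 5):
        ours = ds.cut_tree(tree, k).to_numpy()
        theirs = sch.fcluster(Z, k, criterion="maxclust")
        assert adjusted_rand_score(ours, theirs) == 1.0


def test_heights_non_decreasing(small_population):
    pop = small_population
    imp = ds.person_impacts(pop["intakes"], pop["factors"])
    tree = ds.ward_tree(np.log(imp.to_numpy()), pop["weights"])
    assert (np.diff(tree.merges[:, 2]) >= -1e-12).all()


def test_suggest_k_three_blobs():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(c, 0.3, (25, 2))
                   for c in ([0, 0], [8, 0], [0, 8])])
    sug = ds.suggest_k(ds.ward_tree(X), range(2, 8))
    assert sug.k == 3
    assert not sug.weak_elbow


def test_suggest_k_five_blobs_restricted_range():
    rng = np.random.default_rng(4)
    centers = [[0, 0], [9, 0], [0, 9], [9, 9], [4.5, 18]]
    X = np.vstack([rng.normal(c, 0.3, (20, 2)) for c in centers])
    sug = ds.suggest_k(ds.ward_tree(X), range(4, 6))
    assert sug.k == 5


def test_suggest_k_uniform_data_flags_weak_elbow():
    rng = np.random.default_rng(5)
    X = rng.uniform(0, 1, (80, 2))
    sug = ds.suggest_k(ds.ward_tree(X), range(2, 8))
    assert isinstance(sug.k, int)
    assert sug.weak_elbow


def test_suggest_k_range_validated():
    X = np.random.default_rng(6).normal(0, 1, (10, 2))
    tree = ds.ward_tree(X)
    with pytest.raises(ValidationError):
        ds.suggest_k(tree, range(2, 11))


def test_consolidation_never_increases_within_inertia():
    rng = np.random.default_rng(7)
    for trial in range(5):
        X = rng.normal(0, 1, (60, 3))
        w = rng.uniform(0.5, 2.0, 60)
        tree = ds.ward_tree(X, w)
        sol = ds.cut_and_consolidate(tree, 4, X, w)
        assert sol.within_inertia <= sol.within_inertia_initial + 1e-9
        assert sol.within_inertia + sol.between_inertia == \
            pytest.approx(sol.total_inertia, rel=1e-9)


def test_consolidation_fixed_point_on_optimal_partition():
    """Two tight, distant blobs: hierarchical cut is already k-means optimal,
    so consolidation reassigns nothing."""
    rng = np.random.default_rng(8)
    X = np.vstack([rng.normal(0, 0.1, (15, 2)), rng.normal(10, 0.1, (15, 2))])
    sol = ds.cut_and_consolidate(ds.ward_tree(X), 2, X)
    assert sol.n_reassigned == 0


def test_consolidation_reassigns_misplaced_points():
    """On overlapping data the Ward cut regularly leaves points nearer the
    other centroid; consolidation must move them and strictly lower the
    within-inertia whenever it does."""
    rng = np.random.default_rng(10)
    seen_reassignment = False
    for _ in range(20):
        X = rng.normal(0, 1.5, (50, 2))
        sol = ds.cut_and_consolidate(ds.ward_tree(X), 3, X)
        if sol.n_reassigned > 0:
            seen_reassignment = True
            assert sol.within_inertia < sol.within_inertia_initial - 1e-12
    assert seen_reassignment


def test_k_equals_n_zero_inertia():
    X = np.random.default_rng(9).normal(0, 1, (6, 2))
    sol = ds.cut_and_consolidate(ds.ward_tree(X), 6, X)
    assert sol.within_inertia == pytest.approx(0.0, abs=1e-12)
    assert sorted(sol.labels.unique()) == [1, 2, 3, 4, 5, 6]


def test_nan_scores_rejected():
    X = np.array([[0.0, np.nan], [1.0, 2.0]])
    with pytest.raises(ValidationError, match="NaN"):
        ds.ward_tree(X)


def test_labels_in_range(small_population):
    pop = small_population
    imp = ds.person_impacts(pop["intakes"], pop["factors"])
    X = np.log(imp.to_numpy())
    tree = ds.ward_tree(X, pop["weights"])
    sol = ds.cut_and_consolidate(tree, 4, X, pop["weights"])
    assert set(sol.labels.unique()) <= {1, 2, 3, 4}
    assert sol.cluster_shares.sum() == pytest.approx(1.0)
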