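"""The bagged-tree learner: split optimality, OOB machinery, importance."""

import numpy as np
import pandas as pd
import pytest

from pigscape import forest as rf

# ---------------------------------------------------------------------------
# exhaustive split oracle


def exhaustive_best_split(X, y):
    """Scan every (variable, midpoint) candidate; return the minimal
    achievable child SSE, or None when no split exists."""
    best = None
    n, p = X.shape
    for j in range(p):
        vs = np.unique(X[:, j])
        for lo, hi in zip(vs[:-1], vs[1:]):
            thr = 0.5 * (lo + hi)
            left = X[:, j] <= thr
            sse = 0.0
            for side in (left, ~left):
                ys = y[side]
                sse += float(np.sum((ys - ys.mean()) ** 2))
            if best is None or sse < best:
                best = sse
    return best


def collect_internal_nodes(node, X, y, idx, out):
    if node.is_leaf:
        return
    out.append((node, idx))
    go_left = X[idx, node.split_variable] <= node.split_threshold
    collect_internal_nodes(node.left, X, y, idx[go_left], out)
    collect_internal_nodes(node.right, X, y, idx[~go_left], out)


@pytest.mark.parametrize("n_rows, n_cols, seed", [(8, 2, 0), (12, 3, 1), (10, 4, 2), (7, 2, 3)])
def test_every_split_ties_or_beats_exhaustive_oracle(n_rows, n_cols, seed):
    """With m_try = p, each chosen split must achieve the oracle's minimal
    child SSE on that node's sample."""
    gen = np.random.default_rng(seed)
    X = gen.normal(size=(n_rows, n_cols))
    y = gen.normal(size=n_rows)
    # grow one tree on the plain sample (no bootstrap) so node membership
    # can be reconstructed exactly, then audit every internal node
    counts = np.zeros(n_cols, dtype=int)
    root = rf._grow_tree(X, y, np.arange(n_rows), n_cols, 1, np.random.default_rng(0), counts)
    nodes = []
    collect_internal_nodes(root, X, y, np.arange(n_rows), nodes)
    assert nodes, "expected at least one split"
    for node, idx in nodes:
        oracle = exhaustive_best_split(X[idx], y[idx])
        left = X[idx, node.split_variable] <= node.split_threshold
        achieved = sum(
            float(np.sum((y[idx][side] - y[idx][side].mean()) ** 2)) for side in (left, ~left)
        )
        assert achieved <= oracle + 1e-9


def test_root_split_matches_sklearn_tree(rng):
    """Independent cross-check: a depth-1 reference CART finds the same
    optimal root split quality."""
    from sklearn.tree import DecisionTreeRegressor

    X = rng.normal(size=(30, 3))
    y = X[:, 1] * 2 + rng.normal(0, 0.3, 30)
    counts = np.zeros(3, dtype=int)
    root = rf._grow_tree(X, y, np.arange(30), 3, 29, np.random.default_rng(0), counts)
    ref = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
    assert root.split_variable == ref.tree_.feature[0]
    # sklearn casts inputs to float32 internally, so thresholds agree only
    # to single precision
    assert root.split_threshold == pytest.approx(ref.tree_.threshold[0], abs=1e-6)


# ---------------------------------------------------------------------------
# fitting basics


def test_same_seed_reproduces_identical_forest(rng):
    X = rng.normal(size=(40, 4))
    y = rng.normal(size=40)
    a = rf.fit_forest(X, y, n_trees=10, m_try=2, seed=99)
    b = rf.fit_forest(X, y, n_trees=10, m_try=2, seed=99)
    assert rf.forest_to_dict(a) == rf.forest_to_dict(b)
    c = rf.fit_forest(X, y, n_trees=10, m_try=2, seed=100)
    assert rf.forest_to_dict(a) != rf.forest_to_dict(c)


def test_constant_response_gives_constant_prediction_and_zero_oob(rng):
    X = rng.normal(size=(20, 3))
    y = np.full(20, 4.2)
    model = rf.fit_forest(X, y, n_trees=20, seed=0)
    assert np.allclose(rf.predict(model, X), 4.2)
    assert rf.oob_error(model, X, y) == pytest.approx(0.0)


def test_predictions_bounded_by_training_response(rng):
    X = rng.normal(size=(50, 3))
    y = rng.normal(size=50)
    model = rf.fit_forest(X, y, n_trees=50, m_try=2, seed=1)
    new = rng.normal(size=(200, 3)) * 5  # well outside the training box
    preds = rf.predict(model, new)
    assert preds.min() >= y.min() - 1e-12
    assert preds.max() <= y.max() + 1e-12


def test_constant_predictors_degenerate_to_root_leaves(rng):
    X = np.ones((15, 2))
    y = rng.normal(size=15)
    model = rf.fit_forest(X, y, n_trees=5, seed=0)
    assert all(t.is_leaf for t in model.trees)


def test_m_try_out_of_range_rejected(rng):
    X = rng.normal(size=(10, 2))
    y = rng.normal(size=10)
    with pytest.raises(ValueError):
        rf.fit_forest(X, y, m_try=3)


def test_step_function_classified_almost_perfectly(rng):
    """A noiseless step in predictor 1 only: OOB misclassification < 5 %."""
    X = rng.uniform(size=(500, 4))
    y = (X[:, 0] > 0.5).astype(float)
    model = rf.fit_forest(X, y, task="classification", n_trees=100, m_try=2, seed=3)
    assert rf.oob_error(model, X, y) < 0.05


# ---------------------------------------------------------------------------
# out-of-bag machinery


def test_oob_exclusion_fraction_near_e_inverse(rng):
    """Each bootstrap leaves out ~ 1 - (1 - 1/n)^n ~ 36.8 % of rows."""
    n = 1000
    X = rng.normal(size=(n, 2))
    y = rng.normal(size=n)
    model = rf.fit_forest(X, y, n_trees=50, m_try=1, min_node_size=900, seed=5)
    assert 0.35 < rf.oob_fraction(model, n) < 0.39


def test_oob_error_below_response_variance_for_learnable_signal(rng):
    X = rng.normal(size=(200, 3))
    y = 3 * X[:, 0] - 2 * X[:, 1]
    model = rf.fit_forest(X, y, n_trees=100, m_try=2, seed=6)
    assert rf.oob_error(model, X, y) < np.var(y)


def test_in_bag_error_not_above_oob_error(zonal_frame):
    from pigscape.covariates import PREDICTOR_NAMES

    X = zonal_frame[list(PREDICTOR_NAMES)]
    y = np.log10(zonal_frame["native_pigs"].to_numpy() + 1.0)
    model = rf.fit_forest(X, y, n_trees=200, m_try=4, seed=7)
    inbag_mse = float(np.mean((rf.predict(model, X) - y) ** 2))
    assert inbag_mse <= rf.oob_error(model, X, y)


def test_single_tree_oob_covers_only_its_complement(rng):
    n = 200
    X = rng.normal(size=(n, 2))
    y = rng.normal(size=n)
    model = rf.fit_forest(X, y, n_trees=1, seed=8)
    preds, covered = rf.oob_predict(model, X)
    assert covered.sum() == model.oob_indices[0].size
    assert np.isnan(preds[~covered]).all()
    # complement of one bootstrap: skipped count equals the in-bag count
    assert (~covered).sum() == n - model.oob_indices[0].size


# ---------------------------------------------------------------------------
# variable importance


def test_selection_counts_partition_internal_nodes(rng):
    X = rng.normal(size=(60, 4))
    y = rng.normal(size=60)
    model = rf.fit_forest(X, y, n_trees=20, m_try=2, seed=9)

    def count_internal(node):
        return 0 if node.is_leaf else 1 + count_internal(node.left) + count_internal(node.right)

    total = sum(count_internal(t) for t in model.trees)
    assert model.selection_counts.sum() == total
    imp = rf.selection_importance(model)
    assert imp["selection_pct"].sum() == pytest.approx(100.0)


def test_unused_variable_scores_zero(rng):
    X = rng.normal(size=(40, 3))
    X[:, 2] = 7.0  # constant, can never split
    y = rng.normal(size=40)
    model = rf.fit_forest(X, y, n_trees=20, m_try=3, seed=10)
    assert model.selection_counts[2] == 0


def test_pure_leaf_forest_warns_and_scores_zero(rng, caplog):
    X = rng.normal(size=(10, 2))
    y = np.zeros(10)
    model = rf.fit_forest(X, y, n_trees=3, seed=11)
    with caplog.at_level("WARNING"):
        imp = rf.selection_importance(model)
    assert (imp["selection_count"] == 0).all()
    assert any("no internal nodes" in r.message for r in caplog.records)


def test_informative_variable_ranks_first_under_both_measures(rng):
    X = rng.normal(size=(150, 4))
    y = 4 * X[:, 0] + rng.normal(0, 0.2, 150)  # predictors 1..3 pure noise
    model = rf.fit_forest(X, y, n_trees=60, m_try=2, seed=12)
    imp = rf.selection_importance(model, X, y)
    assert imp["selection_pct"].idxmax() == "x0"
    assert imp["permutation_importance"].idxmax() == "x0"


def test_ensemble_variance_shrinks_with_more_trees(rng):
    """Predictions stabilize as the ensemble grows (10 -> 200 trees)."""
    X = rng.normal(size=(80, 3))
    y = X[:, 0] + rng.normal(0, 0.5, 80)
    probe = rng.normal(size=(20, 3))

    def spread(n_trees):
        preds = [rf.predict(rf.fit_forest(X, y, n_trees=n_trees, m_try=2, seed=s), probe)
                 for s in range(8)]
        return np.var(np.stack(preds), axis=0).mean()

    assert spread(200) < spread(10)


# ---------------------------------------------------------------------------
# serialization


def test_forest_json_round_trip(tmp_path, rng):
    X = rng.normal(size=(30, 3))
    y = rng.normal(size=30)
    model = rf.fit_forest(X, y, n_trees=10, m_try=2, seed=13)
    path = tmp_path / "forest.json"
    rf.save_forest(model, path)
    back = rf.load_forest(path)
    assert np.allclose(rf.predict(back, X), rf.predict(model, X))
    assert rf.forest_to_dict(back) == rf.forest_to_dict(model)
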