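"""Bagged ensembles of unpruned CART trees with random variable subsetting.

This is a self-contained random-forest learner implementing exactly the
algorithm the distribution models need: n bootstrap sub-samples drawn with
replacement from the training data, one unpruned tree grown per sample
with ``m_try`` candidate variables sampled without replacement at every
node, the best split chosen by maximal reduction in the sum of squared
errors (regression) or Gini impurity (binary classification), and
predictions averaged over trees.  Out-of-bag (OOB) observations — the
roughly 36.8 % of rows a bootstrap leaves out — support an internal error
estimate, and variable importance is reported by counting how often each
variable is selected for a split, with a permutation importance computed
alongside as a secondary measure.

For a 0/1 response, minimizing the children's Gini impurity weighted by
node size is algebraically identical to minimizing the squared-error sum
(n * gini = 2 * SSE), so both tasks share one split search; they differ
only in how errors are scored.

Everything is deterministic for a fixed seed: per-tree random streams are
spawned from one seed sequence, candidate variables are scanned in
ascending index order and thresholds in ascending order, so gain ties
resolve to the lowest variable index and lowest threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_GAIN_TOL = 1e-12


@dataclass
class TreeNode:
    """One node of a CART tree; a leaf iff ``split_variable`` is None."""

    leaf_value: float
    n_samples: int
    split_variable: int | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None


@dataclass
class ForestModel:
    trees: list[TreeNode]
    task: str
    m_try: int
    min_node_size: int
    feature_names: list[str]
    rng_seed: int
    oob_indices: list[np.ndarray] = field(repr=False, default_factory=list)
    selection_counts: np.ndarray | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _as_matrix(X, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            if missing:
                raise ValueError(f"predictor table lacks training columns: {missing}")
            X = X[list(feature_names)]
            return X.to_numpy(dtype=float), list(feature_names)
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    names = feature_names or [f"x{j}" for j in range(arr.shape[1])]
    if len(names) != arr.shape[1]:
        raise ValueError("predictor count does not match the training schema")
    return arr, list(names)


def _best_split_for_variable(values: np.ndarray, y: np.ndarray):
    """Lowest-SSE split of one variable; returns (sse_children, threshold).

    Thresholds are midpoints between consecutive distinct sorted values;
    among equal-SSE thresholds the lowest wins.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    ys = y[order]
    n = v.size
    cuts = np.nonzero(v[1:] > v[:-1])[0]  # split after position i
    if cuts.size == 0:
        return None
    c1 = np.cumsum(ys)
    c2 = np.cumsum(ys * ys)
    t1, t2 = c1[-1], c2[-1]
    nl = cuts + 1.0
    nr = n - nl
    sse_l = c2[cuts] - c1[cuts] ** 2 / nl
    sse_r = (t2 - c2[cuts]) - (t1 - c1[cuts]) ** 2 / nr
    total = sse_l + sse_r
    k = int(np.argmin(total))  # argmin takes the first (lowest threshold) tie
    thr = 0.5 * (v[cuts[k]] + v[cuts[k] + 1])
    return float(total[k]), float(thr)


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    m_try: int,
    min_node_size: int,
    rng: np.random.Generator,
    counts: np.ndarray,
) -> TreeNode:
    ysub = y[idx]
    node = TreeNode(leaf_value=float(ysub.mean()), n_samples=idx.size)
    if idx.size <= min_node_size or np.all(ysub == ysub[0]):
        return node
    p = X.shape[1]
    cand = np.sort(rng.choice(p, size=m_try, replace=False))
    parent_sse = float(np.sum((ysub - ysub.mean()) ** 2))
    best = None  # (gain, var, thr)
    for j in cand:
        res = _best_split_for_variable(X[idx, j], ysub)
        if res is None:
            continue
        child_sse, thr = res
        gain = parent_sse - child_sse
        if best is None or gain > best[0] + _GAIN_TOL:
            best = (gain, int(j), thr)
    if best is None or best[0] <= _GAIN_TOL:
        return node
    _, j, thr = best
    go_left = X[idx, j] <= thr
    counts[j] += 1
    node.split_variable = j
    node.split_threshold = thr
    node.left = _grow_tree(X, y, idx[go_left], m_try, min_node_size, rng, counts)
    node.right = _grow_tree(X, y, idx[~go_left], m_try, min_node_size, rng, counts)
    return node


def fit_forest(
    X,
    y,
    task: str = "regression",
    n_trees: int = 500,
    m_try: int | None = None,
    min_node_size: int | None = None,
    seed: int = 0,
) -> ForestModel:
    """Fit a bagged ensemble of unpruned trees.

    Defaults mirror the classic algorithm: 500 trees, ``m_try`` candidate
    variables per node (caller-set; the distribution models use 4 of 6),
    minimum node size 5 for regression and 1 for classification, full-size
    bootstrap samples drawn with replacement.
    """
    if task not in ("regression", "classification"):
        raise ValueError("task must be 'regression' or 'classification'")
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if yv.size != n:
        raise ValueError("X and y disagree on the number of rows")
    if n < 2:
        raise ValueError("need at least two observations")
    if task == "classification" and not np.isin(yv, (0.0, 1.0)).all():
        raise ValueError("classification expects a 0/1 response")
    if m_try is None:
        m_try = p
    if not 1 <= m_try <= p:
        raise ValueError(f"m_try must be in [1, {p}]")
    if min_node_size is None:
        min_node_size = 5 if task == "regression" else 1
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")

    counts = np.zeros(p, dtype=int)
    trees: list[TreeNode] = []
    oob: list[np.ndarray] = []
    all_idx = np.arange(n)
    for ss in np.random.SeedSequence(seed).spawn(n_trees):
        rng = np.random.default_rng(ss)
        boot = rng.integers(0, n, size=n)
        oob.append(np.setdiff1d(all_idx, boot))
        trees.append(_grow_tree(Xm, yv, boot, m_try, min_node_size, rng, counts))
    return ForestModel(
        trees=trees,
        task=task,
        m_try=m_try,
        min_node_size=min_node_size,
        feature_names=names,
        rng_seed=seed,
        oob_indices=oob,
        selection_counts=counts,
    )


def _predict_tree(root: TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(root, np.arange(X.shape[0]))]
    while stack:
        node, rows = stack.pop()
        if rows.size == 0:
            continue
        if node.is_leaf:
            out[rows] = node.leaf_value
            continue
        go_left = X[rows, node.split_variable] <= node.split_threshold
        stack.append((node.left, rows[go_left]))
        stack.append((node.right, rows[~go_left]))
    return out


def predict(model: ForestModel, X) -> np.ndarray:
    """Ensemble prediction: mean of tree predictions.

    For classification the trees' leaf values are class-1 proportions, so
    the ensemble mean is a probability in [0, 1].
    """
    Xm, _ = _as_matrix(X, model.feature_names)
    acc = np.zeros(Xm.shape[0])
    for tree in model.trees:
        acc += _predict_tree(tree, Xm)
    return acc / model.n_trees


def oob_predict(model: ForestModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-row prediction using only trees whose bootstrap excluded the row.

    Returns (predictions, covered) where rows never out-of-bag are NaN and
    flagged False in ``covered``.
    """
    Xm, _ = _as_matrix(X, model.feature_names)
    n = Xm.shape[0]
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for tree, oob_idx in zip(model.trees, model.oob_indices):
        if oob_idx.size == 0:
            continue
        acc[oob_idx] += _predict_tree(tree, Xm[oob_idx])
        cnt[oob_idx] += 1
    covered = cnt > 0
    preds = np.full(n, np.nan)
    preds[covered] = acc[covered] / cnt[covered]
    return preds, covered


def _score(task: str, y: np.ndarray, pred: np.ndarray) -> float:
    if task == "regression":
        return float(np.mean((y - pred) ** 2))
    return float(np.mean((pred >= 0.5).astype(float) != y))


def oob_error(model: ForestModel, X, y) -> float:
    """OOB mean squared error (regression) or misclassification rate.

    Rows that were in-bag for every tree are skipped (their count is
    logged); a small forest simply covers fewer rows.
    """
    yv = np.asarray(y, dtype=float).ravel()
    preds, covered = oob_predict(model, X)
    skipped = int((~covered).sum())
    if skipped:
        log.warning("OOB error: %d observation(s) never out-of-bag were skipped", skipped)
    if not covered.any():
        raise ValueError("no observation has an OOB prediction; grow more trees")
    return _score(model.task, yv[covered], preds[covered])


def oob_fraction(model: ForestModel, n_obs: int) -> float:
    """Mean fraction of observations left out of a tree's bootstrap."""
    return float(np.mean([idx.size / n_obs for idx in model.oob_indices]))


def selection_importance(model: ForestModel, X=None, y=None) -> pd.DataFrame:
    """Variable importance by split-selection count.

    Returns one row per predictor with the raw number of internal nodes
    splitting on it and the same normalized to percent of all splits.
    When training data are supplied, a permutation importance (mean OOB
    error increase after permuting one variable within each tree's OOB
    rows) is reported alongside.
    """
    counts = np.asarray(model.selection_counts, dtype=float)
    total = counts.sum()
    if total == 0:
        log.warning("forest has no internal nodes; all importance scores are zero")
        pct = np.zeros_like(counts)
    else:
        pct = 100.0 * counts / total
    out = pd.DataFrame(
        {"selection_count": counts.astype(int), "selection_pct": pct},
        index=model.feature_names,
    )
    if X is not None and y is not None:
        out["permutation_importance"] = permutation_importance(model, X, y)
    return out


def permutation_importance(model: ForestModel, X, y) -> np.ndarray:
    """Mean per-tree OOB error increase after permuting each variable."""
    Xm, _ = _as_matrix(X, model.feature_names)
    yv = np.asarray(y, dtype=float).ravel()
    p = Xm.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence((model.rng_seed, 0x5EED)))
    increases = np.zeros(p)
    used = 0
    for tree, oob_idx in zip(model.trees, model.oob_indices):
        if oob_idx.size < 2:
            continue
        used += 1
        Xo = Xm[oob_idx]
        yo = yv[oob_idx]
        base = _score(model.task, yo, _predict_tree(tree, Xo))
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            increases[j] += _score(model.task, yo, _predict_tree(tree, Xp)) - base
    return increases / max(used, 1)


# ---------------------------------------------------------------------------
# JSON serialization


def _node_to_dict(node: TreeNode) -> dict:
    d = {"value": node.leaf_value, "n": node.n_samples}
    if not node.is_leaf:
        d.update(
            var=node.split_variable,
            thr=node.split_threshold,
            left=_node_to_dict(node.left),
            right=_node_to_dict(node.right),
        )
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(leaf_value=d["value"], n_samples=d["n"])
    if "var" in d:
        node.split_variable = d["var"]
        node.split_threshold = d["thr"]
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def forest_to_dict(model: ForestModel) -> dict:
    return {
        "task": model.task,
        "m_try": model.m_try,
        "min_node_size": model.min_node_size,
        "feature_names": model.feature_names,
        "rng_seed": model.rng_seed,
        "selection_counts": [int(c) for c in model.selection_counts],
        "oob_indices": [idx.tolist() for idx in model.oob_indices],
        "trees": [_node_to_dict(t) for t in model.trees],
    }


def forest_from_dict(d: dict) -> ForestModel:
    return ForestModel(
        trees=[_node_from_dict(t) for t in d["trees"]],
        task=d["task"],
        m_try=d["m_try"],
        min_node_size=d["min_node_size"],
        feature_names=list(d["feature_names"]),
        rng_seed=d["rng_seed"],
        oob_indices=[np.asarray(i, dtype=int) for i in d["oob_indices"]],
        selection_counts=np.asarray(d["selection_counts"], dtype=int),
    )


def save_forest(model: ForestModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(forest_to_dict(model), fh)


def load_forest(path) -> ForestModel:
    with open(path) as fh:
        return forest_from_dict(json.load(fh))
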