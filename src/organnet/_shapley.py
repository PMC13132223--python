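"""Exact Shapley attributions for linear models and tree ensembles.

Linear models admit the closed form ``phi_j = w_j * (x_j - mu_j)`` for the
decision function with background mean ``mu``. For decision-tree ensembles
the path-dependent polynomial-time algorithm of Lundberg et al. (TreeSHAP,
"tree_path_dependent" value function, where the conditional expectation for
a missing split follows the training cover of each branch) is implemented
directly on sklearn tree arrays. Both satisfy the efficiency property
exactly: per-sample attributions sum to prediction minus expected
prediction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["linear_shap", "tree_shap", "forest_shap", "forest_expected_value"]


def linear_shap(coef, intercept, X, mu):
    """Closed-form attributions for f(x) = coef @ x + intercept.

    Returns (phi: n_samples x n_features, expected_value).
    """
    coef = np.asarray(coef, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    mu = np.asarray(mu, dtype=float).ravel()
    phi = (X - mu) * coef
    expected = float(coef @ mu + float(np.ravel(intercept)[0]))
    return phi, expected


class _Tree:
    """Plain-array view of one sklearn decision tree (class-1 probability)."""

    def __init__(self, sk_tree):
        t = sk_tree.tree_
        self.left = t.children_left
        self.right = t.children_right
        self.feature = t.feature
        self.threshold = t.threshold
        self.cover = t.weighted_n_node_samples.astype(float)
        value = t.value[:, 0, :].astype(float)
        totals = value.sum(axis=1)
        # class-1 fraction per node (sklearn may store counts or fractions)
        self.value = np.where(totals > 0, value[:, -1] / totals, 0.0)

    def expected_value(self) -> float:
        """Cover-weighted mean over leaves = tree prediction for an
        all-missing instance under the path-dependent expectation."""

        def rec(j):
            if self.left[j] < 0:
                return self.value[j]
            wl = self.cover[self.left[j]] / self.cover[j]
            wr = self.cover[self.right[j]] / self.cover[j]
            return wl * rec(self.left[j]) + wr * rec(self.right[j])

        return float(rec(0))


def _extend(path, pz, po, pi):
    l = len(path)
    path.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l - 1, -1, -1):
        path[i + 1][3] += po * path[i][3] * (i + 1) / (l + 1)
        path[i][3] = pz * path[i][3] * (l - i) / (l + 1)


def _unwind(path, i0):
    l = len(path)
    zi, oi = path[i0][1], path[i0][2]
    n = path[l - 1][3]
    for j0 in range(l - 2, -1, -1):
        if oi != 0.0:
            t = path[j0][3]
            path[j0][3] = n * l / ((j0 + 1) * oi)
            n = t - path[j0][3] * zi * (l - 1 - j0) / l
        else:
            path[j0][3] = path[j0][3] * l / (zi * (l - 1 - j0))
    for j0 in range(i0, l - 1):
        path[j0][0] = path[j0 + 1][0]
        path[j0][1] = path[j0 + 1][1]
        path[j0][2] = path[j0 + 1][2]
    path.pop()


def _unwound_sum(path, i0):
    tmp = [row[:] for row in path]
    _unwind(tmp, i0)
    return sum(row[3] for row in tmp)


def tree_shap(tree: _Tree, x: np.ndarray, phi: np.ndarray) -> None:
    """Add one tree's path-dependent Shapley attributions for sample x."""

    def recurse(j, path, pz, po, pi):
        path = [row[:] for row in path]
        _extend(path, pz, po, pi)
        if tree.left[j] < 0:  # leaf
            v = tree.value[j]
            for i0 in range(1, len(path)):
                w = _unwound_sum(path, i0)
                phi[path[i0][0]] += w * (path[i0][2] - path[i0][1]) * v
            return
        split = tree.feature[j]
        if x[split] <= tree.threshold[j]:
            hot, cold = tree.left[j], tree.right[j]
        else:
            hot, cold = tree.right[j], tree.left[j]
        iz = io = 1.0
        k = next(
            (i for i in range(1, len(path)) if path[i][0] == split), None
        )
        if k is not None:
            iz, io = path[k][1], path[k][2]
            _unwind(path, k)
        rj = tree.cover[j]
        recurse(hot, path, iz * tree.cover[hot] / rj, io, split)
        recurse(cold, path, iz * tree.cover[cold] / rj, 0.0, split)

    recurse(0, [], 1.0, 1.0, -1)


def forest_shap(forest, X) -> tuple[np.ndarray, float]:
    """Attributions for a fitted sklearn RandomForestClassifier.

    Explains ``predict_proba[:, 1]`` (the mean of per-tree class-1 leaf
    fractions). Returns (phi: n_samples x n_features, expected_value);
    for every sample ``phi.sum() == proba - expected_value`` exactly (up to
    float round-off).
    """
    X = np.asarray(X, dtype=float)
    trees = [_Tree(e) for e in forest.estimators_]
    phi = np.zeros_like(X)
    for tree in trees:
        for s in range(X.shape[0]):
            tree_shap(tree, X[s], phi[s])
    phi /= len(trees)
    expected = float(np.mean([t.expected_value() for t in trees]))
    return phi, expected


def forest_expected_value(forest) -> float:
    return float(np.mean([_Tree(e).expected_value() for e in forest.estimators_]))
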