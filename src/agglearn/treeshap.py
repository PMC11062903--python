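"""Exact Shapley attributions for decision-tree ensembles.

Implements the path-dependent polynomial-time tree-Shapley recursion for
sklearn decision trees and random forests.  For a tree T and input x, the
value function of a feature subset S is the tree's cover-weighted conditional
expectation E[T(x) | x_S]: descend the tree, following x at splits on
features in S and averaging both children (weighted by training cover) at
splits on features outside S.  The returned attributions phi satisfy local
accuracy exactly:

    sum_j phi[j] + base_value = T(x)

where base_value = E[T(x)] (empty subset), and a feature the tree never
splits on receives exactly zero attribution.

``brute_force_shap_tree`` enumerates all subsets of the features actually
used by a tree and evaluates the Shapley sum directly; it is exponential and
exists as an independent oracle for testing the recursion.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "tree_shap_values",
    "forest_shap_values",
    "tree_expected_value",
    "brute_force_shap_tree",
]


def tree_expected_value(tree: DecisionTreeRegressor) -> float:
    """Cover-weighted mean prediction of a fitted tree (the base value)."""
    t = tree.tree_
    leaves = t.children_left == -1
    w = t.weighted_n_node_samples[leaves]
    v = t.value[leaves, 0, 0]
    return float(np.sum(w * v) / np.sum(w))


def _extend(m: list[list[float]], pz: float, po: float, pi: int) -> None:
    # m rows are [feature, zero_fraction, one_fraction, weight]; 1-indexed
    # positions in the published recursion map to list positions i-1.
    l = len(m)
    m.append([pi, pz, po, 1.0 if l == 0 else 0.0])
    for i in range(l, 0, -1):
        m[i][3] += po * m[i - 1][3] * i / (l + 1)
        m[i - 1][3] = pz * m[i - 1][3] * (l + 1 - i) / (l + 1)


def _unwind(m: list[list[float]], idx: int) -> list[list[float]]:
    out = [row[:] for row in m]
    i = idx + 1  # to 1-indexed
    l = len(out)
    z_i, o_i = out[idx][1], out[idx][2]
    n = out[l - 1][3]
    for j in range(l - 1, 0, -1):
        if o_i != 0:
            t = out[j - 1][3]
            out[j - 1][3] = n * l / (j * o_i)
            n = t - out[j - 1][3] * z_i * (l - j) / l
        else:
            out[j - 1][3] = out[j - 1][3] * l / (z_i * (l - j))
    for j in range(i, l):
        out[j - 1][0], out[j - 1][1], out[j - 1][2] = out[j][0], out[j][1], out[j][2]
    out.pop()
    return out


def tree_shap_values(tree: DecisionTreeRegressor, X: np.ndarray) -> np.ndarray:
    """Path-dependent Shapley attributions, shape ``(len(X), n_features)``."""
    t = tree.tree_
    left, right = t.children_left, t.children_right
    feature, threshold = t.feature, t.threshold
    cover = t.weighted_n_node_samples
    value = t.value[:, 0, 0]
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    phi_all = np.zeros((n, d))

    def recurse(x, phi, node, m, pz, po, pi):
        m = [row[:] for row in m]
        _extend(m, pz, po, pi)
        if left[node] == -1:  # leaf
            for i in range(1, len(m)):
                unwound = _unwind(m, i)
                w = sum(row[3] for row in unwound)
                phi[int(m[i][0])] += w * (m[i][2] - m[i][1]) * value[node]
            return
        f = feature[node]
        hot, cold = (
            (left[node], right[node])
            if x[f] <= threshold[node]
            else (right[node], left[node])
        )
        iz = io = 1.0
        k = next((j for j in range(1, len(m)) if m[j][0] == f), None)
        if k is not None:
            iz, io = m[k][1], m[k][2]
            m = _unwind(m, k)
        recurse(x, phi, hot, m, iz * cover[hot] / cover[node], io, f)
        recurse(x, phi, cold, m, iz * cover[cold] / cover[node], 0.0, f)

    for r in range(n):
        recurse(X[r], phi_all[r], 0, [], 1.0, 1.0, -1)
    return phi_all


def forest_shap_values(
    rf: RandomForestRegressor, X: np.ndarray
) -> tuple[np.ndarray, float]:
    """(attributions, base_value) for a random forest: per-tree average.

    The forest prediction is the mean over trees, so both the attributions
    and the base value are the means of the per-tree quantities and local
    accuracy carries over exactly.
    """
    X = np.asarray(X, dtype=float)
    phis = np.zeros((len(X), X.shape[1]))
    base = 0.0
    trees = rf.estimators_
    for est in trees:
        phis += tree_shap_values(est, X)
        base += tree_expected_value(est)
    return phis / len(trees), base / len(trees)


# ---------------------------------------------------------------------------
# brute-force oracle (testing only; exponential in used features)
# ---------------------------------------------------------------------------


def _conditional_expectation(tree, x, subset: frozenset) -> float:
    t = tree.tree_

    def walk(node) -> float:
        if t.children_left[node] == -1:
            return float(t.value[node, 0, 0])
        f = t.feature[node]
        if f in subset:
            nxt = (
                t.children_left[node]
                if x[f] <= t.threshold[node]
                else t.children_right[node]
            )
            return walk(nxt)
        wl = t.weighted_n_node_samples[t.children_left[node]]
        wr = t.weighted_n_node_samples[t.children_right[node]]
        return (wl * walk(t.children_left[node]) + wr * walk(t.children_right[node])) / (
            wl + wr
        )

    return walk(0)


def brute_force_shap_tree(tree: DecisionTreeRegressor, x: np.ndarray) -> np.ndarray:
    """Exact Shapley sum over all subsets of the tree's used features.

    Features the tree never splits on are dummy players and receive zero, so
    enumeration can be restricted to the used set without changing any value.
    """
    t = tree.tree_
    used = sorted({int(f) for f in t.feature if f >= 0})
    d_total = len(x)
    phi = np.zeros(d_total)
    k = len(used)
    for i in used:
        others = [f for f in used if f != i]
        for r in range(k):
            for S in combinations(others, r):
                Sf = frozenset(S)
                weight = factorial(r) * factorial(k - r - 1) / factorial(k)
                phi[i] += weight * (
                    _conditional_expectation(tree, x, Sf | {i})
                    - _conditional_expectation(tree, x, Sf)
                )
    return phi
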