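"""Random-forest classifier for binary genomic-bin features.

One forest is trained per candidate bin: features are the reference-matrix
columns restricted to the single cell's observed bins, labels are the
candidate's reference column.  The contract follows the standard
random-forest recipe: ``T`` trees (default 100), each grown on a bootstrap
sample of the experiments, best-of-``ceil(sqrt(s))`` Gini splits at every
node, no depth limit, and per-tree class probability equal to the fraction
of (bootstrap) samples of class 1 in the reached leaf.  The forest
probability is the unweighted mean over trees; feature importances are
per-tree-normalized mean Gini impurity decreases.

The kernels are numba-compiled because the surrounding methods train tens
of thousands of small forests per run; the structure of every tree is kept
(split feature, children, leaf class counts) so that predictions can be
re-derived by explicit traversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["Forest", "fit_forest"]


@njit(cache=False)
def _build_forest(X, y, n_trees, mtry, seed, max_nodes):  # pragma: no cover - compiled
    n, s = X.shape
    feat = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    left = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    right = np.full((n_trees, max_nodes), -1, dtype=np.int32)
    c0 = np.zeros((n_trees, max_nodes), dtype=np.float64)
    c1 = np.zeros((n_trees, max_nodes), dtype=np.float64)
    importances = np.zeros(s, dtype=np.float64)
    np.random.seed(seed)
    idx = np.empty(n, dtype=np.int32)
    stack_node = np.empty(max_nodes, dtype=np.int32)
    stack_lo = np.empty(max_nodes, dtype=np.int32)
    stack_hi = np.empty(max_nodes, dtype=np.int32)
    perm = np.empty(s, dtype=np.int32)
    tree_imp = np.empty(s, dtype=np.float64)
    for t in range(n_trees):
        # bootstrap sample of the experiments
        for i in range(n):
            idx[i] = np.random.randint(0, n)
        for j in range(s):
            tree_imp[j] = 0.0
        n_nodes = 1
        stack_node[0] = 0
        stack_lo[0] = 0
        stack_hi[0] = n
        sp = 1
        while sp > 0:
            sp -= 1
            node = stack_node[sp]
            lo = stack_lo[sp]
            hi = stack_hi[sp]
            tot = hi - lo
            pos = 0
            for i in range(lo, hi):
                pos += y[idx[i]]
            c0[t, node] = tot - pos
            c1[t, node] = pos
            if pos == 0 or pos == tot or tot < 2:
                continue
            p = pos / tot
            node_gini = 1.0 - p * p - (1.0 - p) * (1.0 - p)
            # features are evaluated in random order; constant features do
            # not count against the mtry budget
            for j in range(s):
                perm[j] = j
            for j in range(s - 1, 0, -1):
                k = np.random.randint(0, j + 1)
                tmp = perm[j]
                perm[j] = perm[k]
                perm[k] = tmp
            best_gain = 1e-12
            best_f = -1
            visited = 0
            for jj in range(s):
                f = perm[jj]
                n1 = 0
                p1 = 0
                for i in range(lo, hi):
                    if X[idx[i], f] == 1:
                        n1 += 1
                        p1 += y[idx[i]]
                if n1 == 0 or n1 == tot:
                    continue
                visited += 1
                n0 = tot - n1
                p0 = pos - p1
                q0 = p0 / n0
                q1 = p1 / n1
                g0 = 1.0 - q0 * q0 - (1.0 - q0) * (1.0 - q0)
                g1 = 1.0 - q1 * q1 - (1.0 - q1) * (1.0 - q1)
                gain = node_gini - (n0 * g0 + n1 * g1) / tot
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                if visited >= mtry:
                    break
            if best_f < 0:
                continue  # all features constant in this node -> impure leaf
            mid = lo
            for i in range(lo, hi):
                if X[idx[i], best_f] == 0:
                    tmp = idx[i]
                    idx[i] = idx[mid]
                    idx[mid] = tmp
                    mid += 1
            feat[t, node] = best_f
            tree_imp[best_f] += tot * best_gain
            lnode = n_nodes
            rnode = n_nodes + 1
            n_nodes += 2
            left[t, node] = lnode
            right[t, node] = rnode
            stack_node[sp] = lnode
            stack_lo[sp] = lo
            stack_hi[sp] = mid
            sp += 1
            stack_node[sp] = rnode
            stack_lo[sp] = mid
            stack_hi[sp] = hi
            sp += 1
        ssum = 0.0
        for j in range(s):
            ssum += tree_imp[j]
        if ssum > 0.0:
            for j in range(s):
                importances[j] += tree_imp[j] / ssum
    total = 0.0
    for j in range(s):
        importances[j] /= n_trees
        total += importances[j]
    if total > 0.0:  # renormalize: single-leaf trees contribute nothing
        for j in range(s):
            importances[j] /= total
    return feat, left, right, c0, c1, importances


@njit(cache=False)
def _predict_ones(feat, left, right, c0, c1):  # pragma: no cover - compiled
    n_trees = feat.shape[0]
    acc = 0.0
    for t in range(n_trees):
        node = 0
        while feat[t, node] >= 0:
            node = right[t, node]  # the probe value 1 always exceeds the 0.5 split
        acc += c1[t, node] / (c0[t, node] + c1[t, node])
    return acc / n_trees


@njit(cache=False)
def _predict_matrix(feat, left, right, c0, c1, X):  # pragma: no cover - compiled
    n_trees = feat.shape[0]
    n = X.shape[0]
    out = np.zeros(n, dtype=np.float64)
    for i in range(n):
        acc = 0.0
        for t in range(n_trees):
            node = 0
            while feat[t, node] >= 0:
                if X[i, feat[t, node]] == 1:
                    node = right[t, node]
                else:
                    node = left[t, node]
            acc += c1[t, node] / (c0[t, node] + c1[t, node])
        out[i] = acc / n_trees
    return out


@dataclass
class Forest:
    """A trained forest with full per-tree structure.

    Arrays are indexed ``[tree, node]``; ``feature == -1`` marks a leaf,
    ``class0_counts``/``class1_counts`` hold the bootstrap class counts at
    each node (leaf class-1 fraction = c1 / (c0 + c1)).
    """

    feature: np.ndarray
    left: np.ndarray
    right: np.ndarray
    class0_counts: np.ndarray
    class1_counts: np.ndarray
    importances: np.ndarray
    n_features: int
    mtry: int
    seed: int

    @property
    def n_trees(self) -> int:
        return self.feature.shape[0]

    def predict_ones(self) -> float:
        """Forest class-1 probability for the all-ones probe vector."""
        return float(
            _predict_ones(
                self.feature, self.left, self.right,
                self.class0_counts, self.class1_counts,
            )
        )

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        """Forest class-1 probability for each row of a binary matrix."""
        X = np.ascontiguousarray(X, dtype=np.uint8)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected shape (*, {self.n_features}), got {X.shape}"
            )
        return _predict_matrix(
            self.feature, self.left, self.right,
            self.class0_counts, self.class1_counts, X,
        )

    def feature_importances(self) -> np.ndarray:
        """Gini importances, per-tree normalized and averaged (sum 1, or all 0)."""
        return self.importances.copy()


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    mtry: int | None = None,
) -> Forest:
    """Train a random forest on a binary feature matrix and binary labels.

    ``mtry`` defaults to ``ceil(sqrt(n_features))`` split candidates per
    node.  Fully deterministic for a given seed.
    """
    X = np.ascontiguousarray(X, dtype=np.uint8)
    y = np.ascontiguousarray(y, dtype=np.uint8)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, s = X.shape
    if n < 1 or s < 1:
        raise ValueError("X must have at least one row and one column")
    if y.shape != (n,):
        raise ValueError(f"y must have shape ({n},)")
    if n_trees < 1:
        raise ValueError("need at least one tree")
    if mtry is None:
        mtry = max(1, math.ceil(math.sqrt(s)))
    mtry = min(int(mtry), s)
    seed = int(seed) & 0x7FFFFFFF
    max_nodes = 2 * n + 1
    feat, left, right, c0, c1, imp = _build_forest(
        X, y, int(n_trees), mtry, seed, max_nodes
    )
    return Forest(feat, left, right, c0, c1, imp, s, mtry, seed)
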