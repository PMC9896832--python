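"""Cost-sensitive ordinal classification tree (ordinal CART).

A CART variant for ordered outcomes: each of the K ordered levels is
assigned a numeric score (the ranks 1..K here), and node impurity is
the *generalized Gini index*

    G(node) = sum_{i,j} cost(i, j) * p_i * p_j,

where the misclassification cost grows with the distance between the
ordered levels: ``|s_i - s_j|`` (absolute) or ``(s_i - s_j)^2``
(quadratic, which charges a two-level miss four times an adjacent
miss).  Splitting greedily minimizes the children's total generalized
Gini risk; a split is accepted only if its impurity improvement is at
least ``cp`` times the root impurity risk (the complexity-parameter
gate, on the relative scale R's rpart uses).

The grown tree is pruned back by weakest-link cost-complexity pruning
with an internal cross-validation choosing the subtree with the least
cross-validated overall misclassification, measured either as the
plain error rate (every miss weighted 1) or as the misclassification
cost rate (misses weighted by the cost matrix), per ``prune_rule``.

Leaf prediction is the modal level of the leaf (ties toward the lower,
healthier level); the cost matrix shapes the tree, not the per-leaf
label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OcartFit", "fit_ocart_core", "gini_risk", "cost_matrix"]


def cost_matrix(K: int, split_cost: str) -> np.ndarray:
    """Pairwise misclassification costs between the K ordered levels."""
    if split_cost not in ("absolute", "quadratic"):
        raise ValueError("split_cost must be 'absolute' or 'quadratic'")
    s = np.arange(1, K + 1, dtype=float)
    d = np.abs(s[:, None] - s[None, :])
    return d if split_cost == "absolute" else d**2


def gini_risk(counts: np.ndarray, C: np.ndarray) -> float:
    """Generalized-Gini risk n * G of a node with level ``counts``:
    ``sum_ij C_ij n_i n_j / n`` (0 for an empty or pure node)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        return 0.0
    return float(counts @ C @ counts / n)


@dataclass
class _Node:
    counts: np.ndarray
    prediction: int  # level code 0..K-1
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    # weakest-link statistic, filled during pruning
    g: float = np.inf

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _modal(counts: np.ndarray) -> int:
    return int(np.argmax(counts))  # argmax takes the first (lower) level on ties


def _best_split(X, codes, idx, counts, C, minbucket):
    """Best (feature, threshold, improvement) over midpoint candidates."""
    n = len(idx)
    K = len(counts)
    r_node = gini_risk(counts, C)
    best = (None, None, -np.inf)
    Xn = X[idx]
    onehot = np.zeros((n, K))
    for j in range(X.shape[1]):
        xv = Xn[:, j]
        order = np.argsort(xv, kind="stable")
        xs = xv[order]
        ys = codes[idx][order]
        change = np.flatnonzero(np.diff(xs) > 0)
        if len(change) == 0:
            continue
        onehot[:] = 0.0
        onehot[np.arange(n), ys] = 1.0  # rows already in sorted-feature order
        cum = np.cumsum(onehot, axis=0)
        NL = cum[change]  # (T, K) left counts per candidate cut
        nL = NL.sum(axis=1)
        ok = (nL >= minbucket) & (n - nL >= minbucket)
        if not ok.any():
            continue
        NL = NL[ok]
        nL = nL[ok]
        NR = counts[None, :] - NL
        rL = np.einsum("ti,ij,tj->t", NL, C, NL) / nL
        rR = np.einsum("ti,ij,tj->t", NR, C, NR) / (n - nL)
        delta = r_node - rL - rR
        k = int(np.argmax(delta))
        if delta[k] > best[2] + 1e-12:
            cut_pos = change[ok][k]
            thr = 0.5 * (xs[cut_pos] + xs[cut_pos + 1])
            best = (j, float(thr), float(delta[k]))
    return best


def _grow(X, codes, idx, K, C, cp_abs, minsplit, minbucket, depth, max_depth=30):
    counts = np.bincount(codes[idx], minlength=K).astype(float)
    node = _Node(counts=counts, prediction=_modal(counts))
    n = len(idx)
    if n < minsplit or depth >= max_depth or np.count_nonzero(counts) < 2:
        return node
    j, thr, delta = _best_split(X, codes, idx, counts, C, minbucket)
    if j is None or delta < cp_abs:
        return node
    mask = X[idx, j] <= thr
    node.feature, node.threshold = j, thr
    node.left = _grow(X, codes, idx[mask], K, C, cp_abs, minsplit, minbucket, depth + 1, max_depth)
    node.right = _grow(X, codes, idx[~mask], K, C, cp_abs, minsplit, minbucket, depth + 1, max_depth)
    return node


def _prune_risk(counts: np.ndarray, pred: int, Cp: np.ndarray | None) -> float:
    """Pruning risk of a node labeled ``pred``: miss count (rate rule,
    Cp None) or total misclassification cost."""
    if Cp is None:
        return float(counts.sum() - counts[pred])
    return float(Cp[pred] @ counts)


def _subtree_stats(node: _Node, Cp):
    """(subtree leaf risk, leaf count); also fills the weakest-link g on
    internal nodes."""
    if node.is_leaf:
        return _prune_risk(node.counts, node.prediction, Cp), 1
    rl, nl = _subtree_stats(node.left, Cp)
    rr, nr = _subtree_stats(node.right, Cp)
    r_sub, n_leaves = rl + rr, nl + nr
    r_collapsed = _prune_risk(node.counts, node.prediction, Cp)
    node.g = (r_collapsed - r_sub) / max(n_leaves - 1, 1)
    return r_sub, n_leaves


def _collect_g(node: _Node, out: list):
    if not node.is_leaf:
        out.append(node.g)
        _collect_g(node.left, out)
        _collect_g(node.right, out)


def _pruned_copy(node: _Node, alpha: float) -> _Node:
    """Copy of the tree with every internal node of weakest-link g <= alpha
    collapsed to a leaf."""
    if node.is_leaf or node.g <= alpha + 1e-12:
        return _Node(counts=node.counts, prediction=node.prediction)
    out = _Node(counts=node.counts, prediction=node.prediction,
                feature=node.feature, threshold=node.threshold)
    out.left = _pruned_copy(node.left, alpha)
    out.right = _pruned_copy(node.right, alpha)
    return out


def _predict_codes(node: _Node, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(len(X), dtype=int)

    def walk(nd, rows):
        if nd.is_leaf:
            out[rows] = nd.prediction
            return
        mask = X[rows, nd.feature] <= nd.threshold
        walk(nd.left, rows[mask])
        walk(nd.right, rows[~mask])

    walk(node, np.arange(len(X)))
    return out


def _n_leaves(node: _Node) -> int:
    return 1 if node.is_leaf else _n_leaves(node.left) + _n_leaves(node.right)


@dataclass
class OcartFit:
    """A grown-and-pruned ordinal classification tree."""

    root: _Node
    level_labels: np.ndarray
    split_cost: str
    prune_rule: str
    cp: float
    pruned_alpha: float

    def predict(self, X) -> np.ndarray:
        return self.level_labels[_predict_codes(self.root, X)]

    @property
    def n_leaves(self) -> int:
        return _n_leaves(self.root)

    def feature_importances(self, n_features: int) -> np.ndarray:
        """Total generalized-Gini impurity decrease attributed to each
        feature across the pruned tree's splits."""
        C = cost_matrix(len(self.level_labels), self.split_cost)
        imp = np.zeros(n_features)

        def walk(nd):
            if nd.is_leaf:
                return
            delta = gini_risk(nd.counts, C) - gini_risk(nd.left.counts, C) - gini_risk(
                nd.right.counts, C
            )
            imp[nd.feature] += max(delta, 0.0)
            walk(nd.left)
            walk(nd.right)

        walk(self.root)
        return imp


def fit_ocart_core(
    X,
    y,
    cp: float = 0.01,
    split_cost: str = "absolute",
    prune_rule: str = "misclassification_rate",
    minsplit: int = 20,
    minbucket: int = 7,
    cv_folds: int = 5,
    seed: int = 0,
) -> OcartFit:
    """Grow a generalized-Gini tree gated by ``cp`` and prune it by
    internally cross-validated misclassification (rate or cost)."""
    if cp < 0:
        raise ValueError("cp must be >= 0")
    if prune_rule not in ("misclassification_rate", "misclassification_cost"):
        raise ValueError("prune_rule must be 'misclassification_rate' or 'misclassification_cost'")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels, codes = np.unique(np.asarray(y), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("outcome has a single level; cannot fit a tree")
    K = len(labels)
    C = cost_matrix(K, split_cost)
    Cp = None if prune_rule == "misclassification_rate" else C
    n = len(codes)
    root_counts = np.bincount(codes, minlength=K).astype(float)
    cp_abs = cp * gini_risk(root_counts, C)

    full = _grow(X, codes, np.arange(n), K, C, cp_abs, minsplit, minbucket, 0)
    _subtree_stats(full, Cp)
    gs: list[float] = []
    _collect_g(full, gs)
    alpha_best = 0.0
    if gs:
        gs = np.unique(np.maximum(gs, 0.0))
        # candidate alphas: 0, geometric midpoints, and beyond the largest g
        mids = np.sqrt(gs[:-1] * np.maximum(gs[1:], 1e-12)) if len(gs) > 1 else np.array([])
        candidates = np.concatenate([[0.0], mids, [gs[-1] * 1.001 + 1e-9]])

        rng = np.random.default_rng(seed)
        fold_of = rng.permutation(n) % cv_folds
        cv_risk = np.zeros(len(candidates))
        for f in range(cv_folds):
            tr = np.flatnonzero(fold_of != f)
            te = np.flatnonzero(fold_of == f)
            if len(np.unique(codes[tr])) < 2 or len(te) == 0:
                continue
            counts_tr = np.bincount(codes[tr], minlength=K).astype(float)
            cp_abs_f = cp * gini_risk(counts_tr, C)
            tree_f = _grow(X, codes, tr, K, C, cp_abs_f, minsplit, minbucket, 0)
            _subtree_stats(tree_f, Cp)
            for a, alpha in enumerate(candidates):
                pred = _predict_codes(_pruned_copy(tree_f, alpha), X[te])
                if Cp is None:
                    cv_risk[a] += np.sum(pred != codes[te])
                else:
                    cv_risk[a] += Cp[pred, codes[te]].sum()
        # least cross-validated risk; ties toward the larger alpha (smaller tree)
        alpha_best = float(candidates[len(cv_risk) - 1 - int(np.argmin(cv_risk[::-1]))])

    pruned = _pruned_copy(full, alpha_best)
    return OcartFit(
        root=pruned, level_labels=labels, split_cost=split_cost,
        prune_rule=prune_rule, cp=cp, pruned_alpha=alpha_best,
    )
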