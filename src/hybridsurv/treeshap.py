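"""Exact Shapley values for tree ensembles (interventional expectations).

For a tree, the prediction for a mixed input (features in S taken from the
foreground bird x, the rest from a background bird z) is a sum over leaves
of the leaf value times an indicator that the mixed input lands in the
leaf's hyperrectangle.  For a given (x, z) pair each leaf induces a set A of
features that must be in S (x falls inside the leaf's interval, z outside)
and a set B that must be outside S (the reverse); leaves where some feature
excludes both x and z are unreachable for every S.  The Shapley value then
has a closed form per leaf: a feature in A receives
``+v * |A\\{i}|! |B|! / (|A|+|B|)!``-style weight ``W(a-1, b)`` and a feature
in B receives ``-v * W(a, b-1)``, with ``W(p, q) = p! q! / (p + q + 1)!``.
Averaging over a background sample gives exact interventional Shapley
values satisfying additivity: base value + row sum = model output.

The exhaustive subset-enumeration oracle used to validate the closed form
lives here too (exponential in the feature count; tests only).
"""

from __future__ import annotations

from math import factorial

import numpy as np

__all__ = [
    "leaf_boxes",
    "tree_shap",
    "forest_shap",
    "shap_bruteforce",
]


def _weight_table(d: int) -> np.ndarray:
    """W[p, q] = p! q! / (p + q + 1)! for p, q in 0..d."""
    W = np.zeros((d + 1, d + 1))
    for p in range(d + 1):
        for q in range(d + 1):
            W[p, q] = factorial(p) * factorial(q) / factorial(p + q + 1)
    return W


def leaf_boxes(tree, n_features: int):
    """Decompose a fitted sklearn decision tree into leaf hyperrectangles.

    Returns a list of (class1_prob, features, lo, hi) where membership of a
    point u is ``all(lo < u[features] <= hi)`` (sklearn sends x <= threshold
    left).  Only constrained features are listed.
    """
    t = tree.tree_
    class1_col = int(np.searchsorted(tree.classes_, 1)) if 1 in tree.classes_ else None
    out = []

    def rec(node, lo, hi):
        if t.children_left[node] == -1:
            counts = t.value[node][0]
            total = counts.sum()
            if class1_col is None:
                v = 0.0
            else:
                v = float(counts[class1_col] / total) if total > 0 else 0.0
            feats = np.flatnonzero(np.isfinite(lo) | np.isfinite(hi))
            out.append((v, feats, lo[feats].copy(), hi[feats].copy()))
            return
        f, thr = t.feature[node], t.threshold[node]
        hi_l = hi.copy()
        hi_l[f] = min(hi_l[f], thr)
        rec(t.children_left[node], lo.copy(), hi_l)
        lo_r = lo.copy()
        lo_r[f] = max(lo_r[f], thr)
        rec(t.children_right[node], lo_r, hi.copy())

    rec(0, np.full(n_features, -np.inf), np.full(n_features, np.inf))
    return out


def tree_shap(tree, X, background, W: np.ndarray | None = None):
    """Exact interventional Shapley values for one tree.

    Returns (phi, base) with phi of shape (n_x, n_features) and base the
    background-mean tree output (class-1 probability).
    """
    # sklearn trees route samples in float32; mirror that so leaf membership
    # here agrees with predict_proba for values near a split threshold
    X = np.asarray(X, dtype=np.float32).astype(float)
    Z = np.asarray(background, dtype=np.float32).astype(float)
    n_x, d = X.shape
    n_z = Z.shape[0]
    if W is None:
        W = _weight_table(d)
    phi = np.zeros((n_x, d))
    base = 0.0
    for v, feats, lo, hi in leaf_boxes(tree, d):
        if len(feats) == 0:
            base += v  # single-leaf tree: constant output, no attributions
            continue
        inX = (X[:, feats] > lo) & (X[:, feats] <= hi)  # (n_x, m)
        inZ = (Z[:, feats] > lo) & (Z[:, feats] <= hi)  # (n_z, m)
        base += v * inZ.all(axis=1).mean()
        if v == 0.0:
            continue
        IX = inX[:, None, :]
        IZ = inZ[None, :, :]
        onlyX = IX & ~IZ
        onlyZ = ~IX & IZ
        dead = (~IX & ~IZ).any(axis=2)
        a = onlyX.sum(axis=2)
        b = onlyZ.sum(axis=2)
        alive = ~dead
        wA = np.where((a > 0) & alive, W[np.clip(a - 1, 0, d), np.clip(b, 0, d)], 0.0)
        wB = np.where((b > 0) & alive, W[np.clip(a, 0, d), np.clip(b - 1, 0, d)], 0.0)
        contrib = onlyX * (v * wA)[:, :, None] - onlyZ * (v * wB)[:, :, None]
        phi[:, feats] += contrib.mean(axis=1)
    return phi, float(base)


def forest_shap(forest, X, background):
    """Average exact tree Shapley values over a fitted balanced forest.

    The forest's class-1 probability is the mean of per-tree leaf
    frequencies, so averaging per-tree phi and base preserves additivity:
    base + phi row sum = forest predict_proba(x)[1] exactly (to float
    accumulation error).
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    W = _weight_table(d)
    phi = np.zeros((X.shape[0], d))
    base = 0.0
    for tree in forest.trees_:
        p, b = tree_shap(tree, X, background, W)
        phi += p
        base += b
    n = len(forest.trees_)
    return phi / n, base / n


def shap_bruteforce(predict, x, background, n_features: int):
    """Oracle: Shapley values by exhaustive subset enumeration.

    ``predict`` maps an (n, d) array to outputs; v(S) is the background mean
    of predictions with features in S taken from x.  Exponential in d — use
    only on tiny feature counts in tests.
    """
    Z = np.asarray(background, dtype=float)
    x = np.asarray(x, dtype=float)
    d = n_features

    def value(S_mask):
        mixed = Z.copy()
        for j in range(d):
            if S_mask >> j & 1:
                mixed[:, j] = x[j]
        return float(np.mean(predict(mixed)))

    vals = {S: value(S) for S in range(2**d)}
    phi = np.zeros(d)
    for i in range(d):
        for S in range(2**d):
            if S >> i & 1:
                continue
            s = bin(S).count("1")
            w = factorial(s) * factorial(d - s - 1) / factorial(d)
            phi[i] += w * (vals[S | (1 << i)] - vals[S])
    return phi, vals[0]
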