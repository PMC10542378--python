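"""Random-forest regressor specialized to a small set of binary features.

The prediction harness regresses covariate-adjusted binding residuals on five
0/1 carrier indicators. With p binary features every sample is one of 2**p
feature patterns, so a bootstrap sample reduces to per-pattern counts and
response sums, and a regression tree is a recursive partition of the pattern
set. Fitting a tree is then a few thousand integer/float operations, which is
what makes the fully nested permutation scheme (cross-validation repeated
inside every permutation) tractable.

Mechanics mirror the classic random-forest regression defaults: ``n_trees``
bootstrap trees; at each node ``mtry`` candidate features are drawn without
replacement (default max(1, floor(p/3))) and the best sum-of-squares split
among candidates that separate the node is taken; nodes of size <= ``min_node``
(default 5) are terminal; forest prediction is the mean over trees.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["RandomForestRegressorLite", "encode_patterns", "forest_predict"]

MAX_FEATURES = 12  # pattern table is 2**p


def encode_patterns(X) -> tuple[np.ndarray, int]:
    """Encode rows of a binary feature matrix as integer patterns."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-d")
    p = X.shape[1]
    if p == 0 or p > MAX_FEATURES:
        raise ValueError(f"between 1 and {MAX_FEATURES} binary features supported")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("features must be binary 0/1")
    codes = (X.astype(np.int64) * (1 << np.arange(p, dtype=np.int64))).sum(axis=1)
    return codes.astype(np.int64), p


@njit(cache=True)
def _forest(pat_tr, y_tr, pat_te, p, n_trees, mtry, min_node, seed):  # pragma: no cover
    np.random.seed(seed)
    n = pat_tr.size
    n_pat = 1 << p
    preds = np.zeros(pat_te.size)
    cnt = np.zeros(n_pat)
    ssum = np.zeros(n_pat)
    value = np.zeros(n_pat)
    order = np.empty(n_pat, dtype=np.int64)
    tmp = np.empty(n_pat, dtype=np.int64)
    max_nodes = 4 * n_pat + 8
    st_lo = np.empty(max_nodes, dtype=np.int64)
    st_hi = np.empty(max_nodes, dtype=np.int64)
    st_mean = np.empty(max_nodes)
    feats = np.empty(p, dtype=np.int64)

    for _t in range(n_trees):
        for k in range(n_pat):
            cnt[k] = 0.0
            ssum[k] = 0.0
        for _j in range(n):
            i = np.random.randint(0, n)
            k = pat_tr[i]
            cnt[k] += 1.0
            ssum[k] += y_tr[i]
        for k in range(n_pat):
            order[k] = k
        root_mean = 0.0
        tot = 0.0
        for k in range(n_pat):
            tot += cnt[k]
            root_mean += ssum[k]
        root_mean = root_mean / tot

        sp = 0
        st_lo[sp] = 0
        st_hi[sp] = n_pat
        st_mean[sp] = root_mean
        sp += 1
        while sp > 0:
            sp -= 1
            lo, hi, parent_mean = st_lo[sp], st_hi[sp], st_mean[sp]
            n_node = 0.0
            s_node = 0.0
            for q in range(lo, hi):
                n_node += cnt[order[q]]
                s_node += ssum[order[q]]
            mean = s_node / n_node if n_node > 0 else parent_mean
            split_f = -1
            if n_node > min_node and hi - lo > 1:
                # features are inspected in random order; only features that
                # actually separate the node count toward the mtry budget
                for f in range(p):
                    feats[f] = f
                best_score = -np.inf
                n_valid = 0
                for d in range(p):
                    j = d + np.random.randint(0, p - d)
                    feats[d], feats[j] = feats[j], feats[d]
                    f = feats[d]
                    nl = 0.0
                    sl = 0.0
                    for q in range(lo, hi):
                        k = order[q]
                        if (k >> f) & 1 == 0:
                            nl += cnt[k]
                            sl += ssum[k]
                    nr = n_node - nl
                    if nl <= 0.0 or nr <= 0.0:
                        continue
                    n_valid += 1
                    sr = s_node - sl
                    score = sl * sl / nl + sr * sr / nr
                    if score > best_score:
                        best_score = score
                        split_f = f
                    if n_valid >= mtry:
                        break
            if split_f < 0:
                for q in range(lo, hi):
                    value[order[q]] = mean
                continue
            # stable partition of patterns by the split bit
            a = lo
            b = 0
            for q in range(lo, hi):
                k = order[q]
                if (k >> split_f) & 1 == 0:
                    order[a] = k
                    a += 1
                else:
                    tmp[b] = k
                    b += 1
            for q in range(b):
                order[a + q] = tmp[q]
            st_lo[sp] = lo
            st_hi[sp] = a
            st_mean[sp] = mean
            sp += 1
            st_lo[sp] = a
            st_hi[sp] = hi
            st_mean[sp] = mean
            sp += 1

        for j in range(pat_te.size):
            preds[j] += value[pat_te[j]]
    return preds / n_trees


def forest_predict(
    X_train,
    y_train,
    X_test,
    n_trees: int = 500,
    mtry: int | None = None,
    min_node: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Fit a forest on (X_train, y_train) and predict X_test in one call."""
    pat_tr, p = encode_patterns(X_train)
    pat_te, p2 = encode_patterns(X_test)
    if p2 != p:
        raise ValueError("train/test feature counts differ")
    y = np.ascontiguousarray(np.asarray(y_train, dtype=np.float64))
    if y.size != pat_tr.size:
        raise ValueError("X_train and y_train sizes differ")
    if y.size == 0:
        raise ValueError("empty training set")
    if mtry is None:
        mtry = max(1, p // 3)
    return _forest(
        pat_tr, y, pat_te, p, int(n_trees), int(mtry), float(min_node), int(seed) % (2**32)
    )


class RandomForestRegressorLite(RegressorMixin, BaseEstimator):
    """sklearn-style wrapper around the pattern forest.

    Training data are stored at ``fit`` and trees are grown (deterministically
    from ``random_state``) at ``predict``; with no per-tree structure to keep,
    this lazy scheme is equivalent and cheaper.
    """

    def __init__(self, n_estimators=500, max_features=None, min_node=5, random_state=0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_node = min_node
        self.random_state = random_state

    def fit(self, X, y):
        pat, p = encode_patterns(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (pat.size,):
            raise ValueError("y must be a vector matching X rows")
        self._X = np.asarray(X)
        self._y = y
        self.n_features_in_ = p
        return self

    def predict(self, X):
        if not hasattr(self, "_X"):
            raise RuntimeError("estimator is not fitted")
        return forest_predict(
            self._X,
            self._y,
            X,
            n_trees=self.n_estimators,
            mtry=self.max_features,
            min_node=self.min_node,
            seed=self.random_state or 0,
        )
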