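"""Shapley attributions for tree ensembles.

Implements the polynomial-time path-dependent algorithm for decision-tree
Shapley values (the classic "TreeSHAP" recursion, numba-compiled), together
with a brute-force subset-enumeration oracle of the same conditional-
expectation game for small trees.  For a tree, the value of a feature subset
S is the expectation of the tree output when features in S follow the sample
and the remaining splits are averaged with the training cover fractions;
the attributions of the ensemble are tree-averaged and satisfy local
accuracy: base + sum_i phi_i = predicted class probability.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
from numba import njit

__all__ = ["forest_shap_values", "brute_force_shap_values", "flatten_forest"]


def flatten_forest(model):
    """Flatten an sklearn decision tree / random forest into plain arrays."""
    estimators = getattr(model, "estimators_", None)
    trees = [e.tree_ for e in estimators] if estimators is not None else [model.tree_]
    lefts, rights, feats, thrs, covers, values = [], [], [], [], [], []
    offsets = [0]
    for t in trees:
        lefts.append(t.children_left.astype(np.int64))
        rights.append(t.children_right.astype(np.int64))
        feats.append(t.feature.astype(np.int64))
        thrs.append(t.threshold.astype(np.float64))
        covers.append(t.weighted_n_node_samples.astype(np.float64))
        v = t.value[:, 0, :].astype(np.float64)
        s = v.sum(axis=1, keepdims=True)
        values.append(np.where(s > 0, v / np.where(s > 0, s, 1.0), 0.0))
        offsets.append(offsets[-1] + len(t.children_left))
    return (
        np.concatenate(lefts),
        np.concatenate(rights),
        np.concatenate(feats),
        np.concatenate(thrs),
        np.concatenate(covers),
        np.vstack(values),
        np.asarray(offsets, dtype=np.int64),
    )


@njit(cache=False)
def _unwound_sum(mz, mo, mw, plen, i):
    o = mo[i]
    z = mz[i]
    total = 0.0
    nxt = mw[plen - 1]
    for j in range(plen - 2, -1, -1):
        if o != 0.0:
            t = nxt * plen / ((j + 1) * o)
            total += t
            nxt = mw[j] - t * z * (plen - 1 - j) / plen
        else:
            total += mw[j] * plen / (z * (plen - 1 - j))
    return total


@njit(cache=False)
def _recurse(node, md, mz, mo, mw, plen, pz, po, pi, x, left, right, feat, thr, cover, leafval, phi):
    # EXTEND the path with the incoming split's fractions
    L = plen + 1
    nd = np.empty(L, np.int64)
    nz = np.empty(L)
    no = np.empty(L)
    nw = np.empty(L)
    for k in range(plen):
        nd[k] = md[k]
        nz[k] = mz[k]
        no[k] = mo[k]
        nw[k] = mw[k]
    nd[plen] = pi
    nz[plen] = pz
    no[plen] = po
    nw[plen] = 1.0 if plen == 0 else 0.0
    for i in range(plen - 1, -1, -1):
        nw[i + 1] += po * nw[i] * (i + 1) / L
        nw[i] = pz * nw[i] * (plen - i) / L

    if left[node] < 0:  # leaf
        for i in range(1, L):
            w = _unwound_sum(nz, no, nw, L, i)
            scale = w * (no[i] - nz[i])
            d = nd[i]
            for c in range(leafval.shape[1]):
                phi[d, c] += scale * leafval[node, c]
        return

    f = feat[node]
    if x[f] <= thr[node]:
        hot, cold = left[node], right[node]
    else:
        hot, cold = right[node], left[node]
    iz = 1.0
    io = 1.0
    k = -1
    for i in range(1, L):
        if nd[i] == f:
            k = i
            break
    if k >= 0:
        # UNWIND the previous occurrence of this feature
        iz = nz[k]
        io = no[k]
        ud = np.empty(L - 1, np.int64)
        uz = np.empty(L - 1)
        uo = np.empty(L - 1)
        uw = np.empty(L - 1)
        n_ = nw[L - 1]
        for j in range(L - 2, -1, -1):
            if io != 0.0:
                t = n_ * L / ((j + 1) * io)
                n_ = nw[j] - t * iz * (L - 1 - j) / L
                uw[j] = t
            else:
                uw[j] = nw[j] * L / (iz * (L - 1 - j))
        for i in range(L - 1):
            src = i if i < k else i + 1
            ud[i] = nd[src]
            uz[i] = nz[src]
            uo[i] = no[src]
        cd, cz, co, cw, cl = ud, uz, uo, uw, L - 1
    else:
        cd, cz, co, cw, cl = nd, nz, no, nw, L

    rj = cover[node]
    _recurse(hot, cd, cz, co, cw, cl, iz * cover[hot] / rj, io, f,
             x, left, right, feat, thr, cover, leafval, phi)
    _recurse(cold, cd, cz, co, cw, cl, iz * cover[cold] / rj, 0.0, f,
             x, left, right, feat, thr, cover, leafval, phi)


@njit(cache=False)
def _forest_shap(X, left, right, feat, thr, cover, leafval, offsets, phi):
    ntrees = len(offsets) - 1
    d = X.shape[1]
    c = leafval.shape[1]
    md0 = np.empty(0, np.int64)
    mz0 = np.empty(0, np.float64)
    mo0 = np.empty(0, np.float64)
    mw0 = np.empty(0, np.float64)
    for s in range(X.shape[0]):
        for t in range(ntrees):
            a, b = offsets[t], offsets[t + 1]
            _recurse(
                0, md0, mz0, mo0, mw0, 0, 1.0, 1.0, -1, X[s],
                left[a:b], right[a:b], feat[a:b], thr[a:b], cover[a:b],
                leafval[a:b], phi[s],
            )
        for i in range(d):
            for j in range(c):
                phi[s, i, j] /= ntrees


def _base_values(left, cover, leafval, offsets) -> np.ndarray:
    ntrees = len(offsets) - 1
    base = np.zeros(leafval.shape[1])
    for t in range(ntrees):
        a, b = offsets[t], offsets[t + 1]
        leaves = np.nonzero(left[a:b] < 0)[0]
        base += (cover[a:b][leaves] / cover[a]) @ leafval[a:b][leaves]
    return base / ntrees


def forest_shap_values(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample Shapley attributions of a fitted tree ensemble.

    Returns ``(phi, base)`` with ``phi`` of shape (n_samples, n_features,
    n_outputs) and ``base`` the cover-weighted expected output per class,
    such that ``base + phi.sum(axis=1)`` equals the model's predicted
    probabilities.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    left, right, feat, thr, cover, leafval, offsets = flatten_forest(model)
    nf = getattr(model, "n_features_in_", X.shape[1])
    if X.shape[1] != nf:
        raise ValueError(f"X has {X.shape[1]} features, model expects {nf}")
    phi = np.zeros((X.shape[0], X.shape[1], leafval.shape[1]))
    _forest_shap(X, left, right, feat, thr, cover, leafval, offsets, phi)
    return phi, _base_values(left, cover, leafval, offsets)


def _cond_exp(node, in_s, x, left, right, feat, thr, cover, leafval):
    """Cover-weighted conditional expectation of one tree given feature set."""
    if left[node] < 0:
        return leafval[node]
    f = feat[node]
    if in_s[f]:
        child = left[node] if x[f] <= thr[node] else right[node]
        return _cond_exp(child, in_s, x, left, right, feat, thr, cover, leafval)
    lo = _cond_exp(left[node], in_s, x, left, right, feat, thr, cover, leafval)
    hi = _cond_exp(right[node], in_s, x, left, right, feat, thr, cover, leafval)
    return (cover[left[node]] * lo + cover[right[node]] * hi) / cover[node]


def brute_force_shap_values(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Exact Shapley values by enumerating all feature subsets per tree.

    Exponential in the number of distinct features used by each tree; the
    independent oracle for :func:`forest_shap_values` on small models.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    left, right, feat, thr, cover, leafval, offsets = flatten_forest(model)
    ntrees = len(offsets) - 1
    nclass = leafval.shape[1]
    phi = np.zeros((X.shape[0], X.shape[1], nclass))
    for t in range(ntrees):
        a, b = offsets[t], offsets[t + 1]
        tl, tr, tf, tt, tc, tv = (left[a:b], right[a:b], feat[a:b], thr[a:b],
                                  cover[a:b], leafval[a:b])
        used = sorted({f for f in tf if f >= 0})
        m = len(used)
        if m > 20:
            raise ValueError("brute-force enumeration limited to 20 features per tree")
        for s in range(X.shape[0]):
            x = X[s]
            cache: dict[frozenset, np.ndarray] = {}

            def value(subset):
                key = frozenset(subset)
                if key not in cache:
                    in_s = np.zeros(X.shape[1], dtype=bool)
                    in_s[list(key)] = True
                    cache[key] = _cond_exp(0, in_s, x, tl, tr, tf, tt, tc, tv)
                return cache[key]

            for i in used:
                others = [f for f in used if f != i]
                for k in range(m):
                    w = factorial(k) * factorial(m - k - 1) / factorial(m)
                    for sub in combinations(others, k):
                        phi[s, i] += w * (value(set(sub) | {i}) - value(sub))
    phi /= ntrees
    return phi, _base_values(left, cover, leafval, offsets)
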