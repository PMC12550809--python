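"""Exact path-dependent Shapley attributions for sklearn regression trees.

For each decision tree, a feature's attribution is its Shapley value in the
cooperative game whose value for a feature subset S is the tree's expected
output conditioned on S via cover-weighted path traversal (absent features
split the flow proportionally to the training cover of each child).  The
polynomial-time algorithm tracks, along each root-leaf path, the weighted
number of feature subsets of every size; it is numba-compiled with an
explicit stack and per-depth path buffers.

Local accuracy holds by construction: for every sample,
``base_value + sum(phi) == tree prediction`` to floating-point precision.
Tests verify equality against a brute-force subset-enumeration oracle on
small trees.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _shap_one_sample(x, cl, cr, feat, thr, val, cover, phi,
                     dbuf, zbuf, obuf, wbuf, plen,
                     s_node, s_q, s_pz, s_po, s_pi):
    s_node[0] = 0
    s_q[0] = 0
    s_pz[0] = 1.0
    s_po[0] = 1.0
    s_pi[0] = -1
    top = 1
    while top > 0:
        top -= 1
        node = s_node[top]
        q = s_q[top]
        pz = s_pz[top]
        po = s_po[top]
        pi = s_pi[top]

        if q == 0:
            L = 0
        else:
            L = plen[q - 1]
            for i in range(L):
                dbuf[q, i] = dbuf[q - 1, i]
                zbuf[q, i] = zbuf[q - 1, i]
                obuf[q, i] = obuf[q - 1, i]
                wbuf[q, i] = wbuf[q - 1, i]

        # extend the path with (pi, pz, po)
        dbuf[q, L] = pi
        zbuf[q, L] = pz
        obuf[q, L] = po
        wbuf[q, L] = 1.0 if L == 0 else 0.0
        for ip in range(L, 0, -1):
            wbuf[q, ip] += po * wbuf[q, ip - 1] * ip / (L + 1)
            wbuf[q, ip - 1] = pz * wbuf[q, ip - 1] * (L + 1 - ip) / (L + 1)
        Lq = L + 1

        if cl[node] < 0:  # leaf: unwind each path entry and accumulate
            leaf_v = val[node]
            for i in range(1, Lq):
                one_i = obuf[q, i]
                zero_i = zbuf[q, i]
                n = wbuf[q, Lq - 1]
                total = 0.0
                for jp in range(Lq - 1, 0, -1):
                    if one_i != 0.0:
                        t = n * Lq / (jp * one_i)
                        total += t
                        n = wbuf[q, jp - 1] - t * zero_i * (Lq - jp) / Lq
                    else:
                        total += wbuf[q, jp - 1] * Lq / (zero_i * (Lq - jp))
                phi[dbuf[q, i]] += total * (one_i - zero_i) * leaf_v
        else:
            f = feat[node]
            if x[f] <= thr[node]:
                hot, cold = cl[node], cr[node]
            else:
                hot, cold = cr[node], cl[node]
            iz = 1.0
            io = 1.0
            k = -1
            for i in range(1, Lq):
                if dbuf[q, i] == f:
                    k = i
                    break
            if k >= 0:  # feature already on the path: undo its entry first
                iz = zbuf[q, k]
                io = obuf[q, k]
                n = wbuf[q, Lq - 1]
                for jp in range(Lq - 1, 0, -1):
                    if io != 0.0:
                        t = wbuf[q, jp - 1]
                        wbuf[q, jp - 1] = n * Lq / (jp * io)
                        n = t - wbuf[q, jp - 1] * iz * (Lq - jp) / Lq
                    else:
                        wbuf[q, jp - 1] = wbuf[q, jp - 1] * Lq / (iz * (Lq - jp))
                for j in range(k, Lq - 1):
                    dbuf[q, j] = dbuf[q, j + 1]
                    zbuf[q, j] = zbuf[q, j + 1]
                    obuf[q, j] = obuf[q, j + 1]
                Lq -= 1
            plen[q] = Lq
            rj = cover[node]
            s_node[top] = cold
            s_q[top] = q + 1
            s_pz[top] = iz * cover[cold] / rj
            s_po[top] = 0.0
            s_pi[top] = f
            top += 1
            s_node[top] = hot
            s_q[top] = q + 1
            s_pz[top] = iz * cover[hot] / rj
            s_po[top] = io
            s_pi[top] = f
            top += 1


@njit(cache=False)
def _shap_all_samples(X, cl, cr, feat, thr, val, cover, phi_out,
                      dbuf, zbuf, obuf, wbuf, plen,
                      s_node, s_q, s_pz, s_po, s_pi):
    for s in range(X.shape[0]):
        _shap_one_sample(X[s], cl, cr, feat, thr, val, cover, phi_out[s],
                         dbuf, zbuf, obuf, wbuf, plen,
                         s_node, s_q, s_pz, s_po, s_pi)


def tree_shap_values(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley attributions for one fitted sklearn regression tree.

    Returns ``(phi, base)`` with ``phi`` of shape (n_samples, n_features)
    and ``base`` the cover-weighted expected tree output (root value).
    """
    t = tree.tree_
    X = np.ascontiguousarray(X, dtype=np.float64)
    depth = int(t.max_depth)
    width = depth + 3
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    dbuf = np.zeros((width, width), dtype=np.int64)
    zbuf = np.zeros((width, width), dtype=np.float64)
    obuf = np.zeros((width, width), dtype=np.float64)
    wbuf = np.zeros((width, width), dtype=np.float64)
    plen = np.zeros(width, dtype=np.int64)
    cap = 2 * width + 4
    s_node = np.zeros(cap, dtype=np.int64)
    s_q = np.zeros(cap, dtype=np.int64)
    s_pz = np.zeros(cap, dtype=np.float64)
    s_po = np.zeros(cap, dtype=np.float64)
    s_pi = np.zeros(cap, dtype=np.int64)
    _shap_all_samples(
        X,
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.value[:, 0, 0].astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        phi, dbuf, zbuf, obuf, wbuf, plen, s_node, s_q, s_pz, s_po, s_pi,
    )
    return phi, float(t.value[0, 0, 0])


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean tree-Shapley attributions over a fitted forest.

    By linearity of the Shapley value these are exact attributions of the
    forest's (averaged) prediction; local accuracy is inherited per tree.
    """
    if not hasattr(forest, "estimators_"):
        raise TypeError("forest_shap_values requires a fitted tree ensemble")
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    base = 0.0
    for tree in forest.estimators_:
        p, b = tree_shap_values(tree, X)
        phi += p
        base += b
    n = len(forest.estimators_)
    return phi / n, base / n
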