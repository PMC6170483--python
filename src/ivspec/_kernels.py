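"""Compiled numerical kernels for PLS1 and cross-validation.

These are the inner loops of every resampling selector (thousands of PLS
fits per selection run), so they are written as numba ``@njit`` functions.
All public entry points in :mod:`ivspec.pls` delegate to the same NIPALS
kernel, so there is exactly one PLS implementation in the package.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "pls1_nipals",
    "coef_path_from_nipals",
    "pls1_coef_path",
    "cv_predictions",
    "population_rmsecv",
]


@njit(cache=True)
def pls1_nipals(Xc, yc, max_lv):
    """Deflation-based PLS1 on centered data.

    Returns ``(T, W, P, q, a_used)`` where ``a_used <= max_lv`` is the number
    of components actually extracted (extraction stops early when the weight
    vector norm collapses, i.e. X or y is exhausted).
    """
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, max_lv))
    T = np.zeros((n, max_lv))
    P = np.zeros((p, max_lv))
    q = np.zeros(max_lv)
    a_used = 0
    scale0 = 0.0
    for a in range(max_lv):
        w = X.T @ y
        nw = np.sqrt(np.dot(w, w))
        if a == 0:
            scale0 = nw
        if nw <= 1e-12 * scale0 or nw == 0.0:
            break
        w = w / nw
        t = X @ w
        tt = np.dot(t, t)
        if tt <= 1e-30:
            break
        pv = (X.T @ t) / tt
        qa = np.dot(y, t) / tt
        X -= np.outer(t, pv)
        y -= qa * t
        W[:, a] = w
        T[:, a] = t
        P[:, a] = pv
        q[a] = qa
        a_used += 1
    return T, W, P, q, a_used


@njit(cache=True)
def coef_path_from_nipals(W, P, q, a_used, max_lv):
    """Cumulative regression-coefficient path b(A) for A = 1..max_lv.

    Uses the recursion r_a = w_a - sum_{j<a} (p_j . w_a) r_j, which builds
    R = W (P^T W)^{-1} column by column; b(A) = sum_{a<=A} q_a r_a.  Columns
    past ``a_used`` repeat the last achieved solution (rank-deficient case).
    """
    p = W.shape[0]
    B = np.zeros((p, max_lv))
    if a_used == 0:
        return B
    R = np.zeros((p, a_used))
    b = np.zeros(p)
    for a in range(a_used):
        r = W[:, a].copy()
        for j in range(a):
            r -= np.dot(P[:, j], W[:, a]) * R[:, j]
        R[:, a] = r
        b = b + q[a] * r
        B[:, a] = b
    for a in range(a_used, max_lv):
        B[:, a] = B[:, a_used - 1]
    return B


@njit(cache=True)
def pls1_coef_path(Xc, yc, max_lv):
    T, W, P, q, a_used = pls1_nipals(Xc, yc, max_lv)
    return coef_path_from_nipals(W, P, q, a_used, max_lv), a_used


@njit(cache=True)
def cv_predictions(X, y, fold_ids, n_folds, max_lv):
    """Out-of-fold predictions for every candidate component count.

    ``X``/``y`` are raw (uncentered); centering is re-estimated inside each
    training fold.  Returns ``(preds, lv_cap)`` with ``preds[i, a]`` the
    prediction for sample i left out, using a+1 latent variables, and
    ``lv_cap`` the largest count achievable in every training fold.
    """
    n, p = X.shape
    preds = np.zeros((n, max_lv))
    lv_cap = max_lv
    for f in range(n_folds):
        n_te = 0
        for i in range(n):
            if fold_ids[i] == f:
                n_te += 1
        if n_te == 0:
            continue
        n_tr = n - n_te
        Xtr = np.empty((n_tr, p))
        ytr = np.empty(n_tr)
        te_idx = np.empty(n_te, np.int64)
        it = 0
        ie = 0
        for i in range(n):
            if fold_ids[i] == f:
                te_idx[ie] = i
                ie += 1
            else:
                Xtr[it] = X[i]
                ytr[it] = y[i]
                it += 1
        xm = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n_tr):
                s += Xtr[i, j]
            xm[j] = s / n_tr
        ym = ytr.mean()
        amax_f = min(max_lv, n_tr - 1, p)
        if amax_f < 1:
            for e in range(n_te):
                for a in range(max_lv):
                    preds[te_idx[e], a] = ym
            continue
        if amax_f < lv_cap:
            lv_cap = amax_f
        Xtr_c = Xtr - xm
        ytr_c = ytr - ym
        B, a_used = pls1_coef_path(Xtr_c, ytr_c, amax_f)
        for e in range(n_te):
            i = te_idx[e]
            xc = X[i] - xm
            for a in range(max_lv):
                aa = a if a < amax_f else amax_f - 1
                preds[i, a] = np.dot(xc, B[:, aa]) + ym
    return preds, lv_cap


@njit(cache=True)
def population_rmsecv(X, y, member, fold_ids, n_folds, max_lv):
    """Minimum RMSECV (and its component count) for a population of subsets.

    ``member`` is a K x p boolean inclusion matrix; every subset is scored
    with the same fold assignment so the comparisons are paired.  Rows with
    no channels get an infinite score.
    """
    K, p = member.shape
    n = X.shape[0]
    scores = np.full(K, np.inf)
    nlv = np.zeros(K, np.int64)
    for k in range(K):
        m = 0
        for j in range(p):
            if member[k, j]:
                m += 1
        if m == 0:
            continue
        idx = np.empty(m, np.int64)
        c = 0
        for j in range(p):
            if member[k, j]:
                idx[c] = j
                c += 1
        Xs = np.empty((n, m))
        for i in range(n):
            for jj in range(m):
                Xs[i, jj] = X[i, idx[jj]]
        preds, lv_cap = cv_predictions(Xs, y, fold_ids, n_folds, max_lv)
        best = np.inf
        best_a = 0
        for a in range(lv_cap):
            s = 0.0
            for i in range(n):
                d = preds[i, a] - y[i]
                s += d * d
            r = np.sqrt(s / n)
            if r < best:
                best = r
                best_a = a
        scores[k] = best
        nlv[k] = best_a + 1
    return scores, nlv
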