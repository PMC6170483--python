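"""Independently coded reference implementations used only as test oracles.

Everything here is deliberately naive (plain loops / closed forms) and
written without reference to the package internals, so that agreement is
evidence of correctness rather than shared code.
"""

from __future__ import annotations

import numpy as np


def ols_fit(Xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Least-squares coefficients in centered space via numpy lstsq."""
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    return beta


def naive_kennard_stone(X: np.ndarray, n_cal: int) -> list[int]:
    """Brute-force greedy max-min selection with explicit loops."""
    n = X.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dist[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] > best[0]:
                best = (dist[i, j], (i, j))
    if best[1] is None:
        sel = [0, 1]
    else:
        sel = list(best[1])
    while len(sel) < n_cal:
        cand_best = (-np.inf, None)
        for i in range(n):
            if i in sel:
                continue
            d = min(dist[i][j] for j in sel)
            if d > cand_best[0]:
                cand_best = (d, i)
        sel.append(cand_best[1])
    return sel


def naive_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Plain-numpy NIPALS PLS1; returns (coef, scores, y_loadings)."""
    X = Xc.astype(float).copy()
    y = yc.astype(float).copy()
    n, p = X.shape
    Ws, Ps, qs, Ts = [], [], [], []
    for _ in range(n_lv):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = X @ w
        tt = t @ t
        if tt < 1e-30:
            break
        pv = X.T @ t / tt
        qa = y @ t / tt
        X = X - np.outer(t, pv)
        y = y - qa * t
        Ws.append(w)
        Ps.append(pv)
        qs.append(qa)
        Ts.append(t)
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.array(qs)
    coef = W @ np.linalg.solve(P.T @ W, q)
    return coef, np.column_stack(Ts), q


def naive_rmsecv(X, y, idx, fold_ids, n_folds, max_lv):
    """RMSECV curve for a channel subset, centered per training fold."""
    idx = np.asarray(idx, dtype=int)
    n = X.shape[0]
    caps = []
    for f in range(n_folds):
        caps.append(min(max_lv, int(np.sum(fold_ids != f)) - 1, idx.size))
    cap = min(caps)
    preds = np.zeros((n, cap))
    for f in range(n_folds):
        tr = fold_ids != f
        te = ~tr
        Xtr = X[tr][:, idx]
        ytr = y[tr]
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        for a in range(1, cap + 1):
            coef, _, _ = naive_pls1(Xtr - xm, ytr - ym, a)
            preds[te, a - 1] = (X[te][:, idx] - xm) @ coef + ym
    return np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))


def occupancy_expected_unique(m: int, draws: int) -> float:
    """Expected number of distinct values in `draws` uniform draws over m."""
    return m * (1.0 - (1.0 - 1.0 / m) ** draws)
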