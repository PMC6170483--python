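"""Bootstrapping Soft Shrinkage (BOSS).

Channel subsets are generated by weighted bootstrap sampling (WBS): p draws
with replacement under the current channel weights, collapsed to the unique
set.  Each subset is scored by k-fold RMSECV; the best fraction of the
sub-models contribute their absolute regression coefficients — each vector
normalized to unit L1 mass, channels outside the subset contributing 0 — to
the next round's weights (w_i = sum_k b_{i,k}).  Weights start uniform, so
the first round is a plain bootstrap.  Channels absent from every best model
get weight 0 and can never return ("soft shrinkage"); the subset with the
lowest RMSECV seen anywhere in the iteration is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .dataset import SpectralDataset, SplitResult
from .pls import assign_folds
from .selection import SelectionResult

__all__ = ["BossConfig", "BossTrace", "weighted_bootstrap_subsets", "select_boss"]


@dataclass
class BossConfig:
    n_subsets: int = 1000
    best_fraction: float = 0.1
    cv_folds: int = 5
    max_lv: int = 10
    max_iterations: int = 30
    seed: int = 0


@dataclass
class BossTrace:
    iterations: list = field(default_factory=list)  # dicts per iteration
    global_best_indices: np.ndarray | None = None
    global_best_rmsecv: float = np.inf
    global_best_nlv: int = 0


def weighted_bootstrap_subsets(
    w: np.ndarray,
    K: int,
    draws: int,
    seed: int | np.random.Generator,
) -> list[np.ndarray]:
    """K unique-index subsets from with-replacement draws under weights w."""
    w = np.asarray(w, dtype=float)
    if K < 1:
        raise ValueError("need at least one subset")
    if np.any(w < 0) or w.sum() == 0.0:
        raise ValueError("weights must be nonnegative with positive sum")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = w / w.sum()
    all_draws = rng.choice(w.size, size=(K, draws), replace=True, p=probs)
    return [np.unique(all_draws[k]) for k in range(K)]


def select_boss(
    ds: SpectralDataset,
    split: SplitResult,
    config: BossConfig | None = None,
) -> tuple[SelectionResult, BossTrace]:
    """Run BOSS on the calibration block of a dataset.

    Stops when the best subset is no larger than its latent-variable count
    plus one, or when the weight support stops shrinking for 3 consecutive
    iterations, or after ``max_iterations``.
    """
    cfg = config or BossConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_folds, rng_boot = (np.random.default_rng(c) for c in ss.spawn(2))

    X_cal = np.ascontiguousarray(ds.X[split.cal_indices], dtype=float)
    y_cal = np.ascontiguousarray(ds.y[split.cal_indices], dtype=float)
    n, p = X_cal.shape
    fold_ids = assign_folds(n, cfg.cv_folds, rng_folds)
    Xc = X_cal - X_cal.mean(axis=0)
    yc = y_cal - y_cal.mean()

    w = np.full(p, 1.0 / p)
    trace = BossTrace()
    n_best = max(1, int(round(cfg.best_fraction * cfg.n_subsets)))
    support_history: list[int] = []

    Xc_cont = np.ascontiguousarray(X_cal)
    for it in range(cfg.max_iterations):
        subsets = weighted_bootstrap_subsets(w, cfg.n_subsets, draws=p, seed=rng_boot)
        member = np.zeros((len(subsets), p), dtype=bool)
        for k, idx in enumerate(subsets):
            member[k, idx] = True
        scores, nlvs = _kernels.population_rmsecv(
            Xc_cont, y_cal, member, fold_ids, cfg.cv_folds, cfg.max_lv
        )
        skipped = int(np.sum(~np.isfinite(scores)))
        order = np.argsort(scores, kind="stable")
        best_k = int(order[0])
        if scores[best_k] < trace.global_best_rmsecv:
            trace.global_best_rmsecv = float(scores[best_k])
            trace.global_best_indices = subsets[best_k].copy()
            trace.global_best_nlv = int(nlvs[best_k])

        # weight update: sum of the best models' normalized |coefficients|
        new_w = np.zeros(p)
        for k in order[:n_best]:
            idx = subsets[k]
            B, a_used = _kernels.pls1_coef_path(
                np.ascontiguousarray(Xc[:, idx]), yc, int(nlvs[k])
            )
            b = np.abs(B[:, a_used - 1]) if a_used else np.zeros(idx.size)
            mass = b.sum()
            if mass > 0:
                new_w[idx] += b / mass
        if new_w.sum() == 0.0:
            break
        w = new_w / new_w.sum()

        support = int(np.count_nonzero(w))
        support_history.append(support)
        trace.iterations.append(
            {
                "best_indices": subsets[best_k].copy(),
                "best_rmsecv": float(scores[best_k]),
                "best_nlv": int(nlvs[best_k]),
                "mean_subset_size": float(np.mean([s.size for s in subsets])),
                "support_size": support,
                "skipped": skipped,
                "weights": w.copy(),
            }
        )
        if subsets[best_k].size <= nlvs[best_k] + 1:
            break
        if len(support_history) >= 3 and len(set(support_history[-3:])) == 1:
            break

    return (
        SelectionResult(
            method="boss",
            selected_indices=trace.global_best_indices,
            n_lv=trace.global_best_nlv,
            rmsecv=trace.global_best_rmsecv,
            diagnostics=trace,
        ),
        trace,
    )
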