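"""Competitive Adaptive Reweighted Sampling (CARS).

Each Monte Carlo run fits a PLS model on a random subset of calibration
samples restricted to the currently retained channels, then shrinks the
channel set twice: a forced step keeping the top round(r_i * p) channels by
|coefficient| (the exponentially decreasing function, EDF) and a stochastic
step resampling channels with replacement with probability proportional to
|coefficient| (adaptive reweighted sampling, ARS — "survival of the
fittest").  Every run's subset is scored by k-fold RMSECV on the full
calibration set and the subset of the lowest-RMSECV run is returned.

The EDF ratio r_i = a * exp(-k * i) with a = (p/2)^(1/(N-1)) and
k = ln(p/2)/(N-1) satisfies r_1 = 1 and r_N = 2/p identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .dataset import SpectralDataset, SplitResult
from .pls import assign_folds
from .selection import SelectionResult, evaluate_subset

__all__ = ["CarsConfig", "EDFSchedule", "CarsTrace", "edf_schedule", "ars_sample", "select_cars"]


@dataclass
class CarsConfig:
    n_runs: int = 100
    sample_fraction: float = 0.8
    cv_folds: int = 5
    max_lv: int = 10
    seed: int = 0


@dataclass
class EDFSchedule:
    a: float
    k: float
    ratios: np.ndarray
    p: int
    N: int


@dataclass
class CarsTrace:
    """Per-run records: retained channels, full-length coefficient vector
    (zeros for eliminated channels), pre-ARS retained count, RMSECV."""

    retained: list = field(default_factory=list)
    coefs: list = field(default_factory=list)
    pre_ars_counts: list = field(default_factory=list)
    rmsecv: list = field(default_factory=list)
    n_lv: list = field(default_factory=list)
    best_run: int = -1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "run": np.arange(1, len(self.rmsecv) + 1),
                "retained_count": [len(r) for r in self.retained],
                "rmsecv": self.rmsecv,
            }
        )


def edf_schedule(p: int, N: int) -> EDFSchedule:
    """Exponentially decreasing retention-ratio schedule r_i = a e^{-ki}."""
    if p < 3:
        raise ValueError("EDF needs at least 3 channels (r_N = 2/p)")
    if N < 2:
        raise ValueError("EDF needs at least 2 runs")
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = np.log(p / 2.0) / (N - 1)
    i = np.arange(1, N + 1)
    return EDFSchedule(a=a, k=k, ratios=a * np.exp(-k * i), p=p, N=N)


def ars_sample(
    weights: np.ndarray,
    draws: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Adaptive reweighted sampling: with-replacement draws proportional to
    the weights, collapsed to the unique index set (ascending)."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total == 0.0:
        raise ValueError("all-zero weights")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(w.size, size=draws, replace=True, p=w / total)
    return np.unique(idx)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_cars(
    ds: SpectralDataset,
    split: SplitResult,
    config: CarsConfig | None = None,
) -> tuple[SelectionResult, CarsTrace]:
    """Run CARS on the calibration block of a dataset."""
    cfg = config or CarsConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_folds, rng_mc = (np.random.default_rng(c) for c in ss.spawn(2))

    X_cal = np.ascontiguousarray(ds.X[split.cal_indices], dtype=float)
    y_cal = np.ascontiguousarray(ds.y[split.cal_indices], dtype=float)
    n, p = X_cal.shape
    m = int(round(cfg.sample_fraction * n))
    sched = edf_schedule(p, cfg.n_runs)
    fold_ids = assign_folds(n, cfg.cv_folds, rng_folds)

    retained = np.arange(p)
    trace = CarsTrace()
    for i in range(1, cfg.n_runs + 1):
        rows = rng_mc.choice(n, size=m, replace=False)
        Xs = X_cal[rows][:, retained]
        ys = y_cal[rows]
        # latent-variable count re-chosen per run on the drawn subsample
        sub_folds = assign_folds(m, cfg.cv_folds, rng_mc)
        preds, lv_cap = _kernels.cv_predictions(
            np.ascontiguousarray(Xs), ys, sub_folds, cfg.cv_folds, cfg.max_lv
        )
        curve = np.sqrt(np.mean((preds[:, :lv_cap] - ys[:, None]) ** 2, axis=0))
        a = int(np.argmin(curve)) + 1
        Xs_c = np.ascontiguousarray(Xs - Xs.mean(axis=0))
        B, a_used = _kernels.pls1_coef_path(Xs_c, ys - ys.mean(), a)
        coef = B[:, a_used - 1] if a_used else np.zeros(retained.size)
        full_coef = np.zeros(p)
        full_coef[retained] = coef

        # EDF step: forced shrink to round(r_i * p) of the original width,
        # floored at 2, capped by the current survivor count.
        keep_n = min(max(2, _round_half_away(sched.ratios[i - 1] * p)), retained.size)
        order = np.argsort(-np.abs(coef), kind="stable")
        kept = retained[np.sort(order[:keep_n])]
        trace.pre_ars_counts.append(keep_n)

        # ARS step: competitive resampling on the survivors' |coefficients|.
        w = np.abs(full_coef[kept])
        if w.sum() == 0.0:
            w = np.ones(kept.size)
        picked = ars_sample(w, draws=kept.size, seed=rng_mc)
        if picked.size < 2:  # keep the 2-channel floor: top weights survive
            picked = np.sort(np.argsort(-w, kind="stable")[:2])
        retained = kept[picked]

        r, nlv, _ = evaluate_subset(X_cal, y_cal, retained, fold_ids, cfg.cv_folds, cfg.max_lv)
        trace.retained.append(retained.copy())
        trace.coefs.append(full_coef)
        trace.rmsecv.append(r)
        trace.n_lv.append(nlv)

    trace.best_run = int(np.argmin(trace.rmsecv))
    best = trace.best_run
    result = SelectionResult(
        method="cars",
        selected_indices=trace.retained[best],
        n_lv=trace.n_lv[best],
        rmsecv=trace.rmsecv[best],
        diagnostics=trace,
    )
    return result, trace
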