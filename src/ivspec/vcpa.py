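"""Variable Combination Population Analysis (VCPA).

Each EDF run draws a population of random channel combinations by binary
matrix sampling (BMS: every live channel included independently with the
same probability), scores each combination by k-fold RMSECV, ranks the live
channels by how often they appear in the best fraction of the sub-models
(model population analysis), and shrinks the live set along a geometric
schedule running from the full channel count down to omega.  After the last
run the omega survivors are searched exhaustively: every nonempty subset is
scored with one shared fold assignment and the minimum-RMSECV subset is
returned (fewest channels, then lexicographic order, on exact ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .dataset import SpectralDataset, SplitResult
from .pls import assign_folds
from .selection import SelectionResult

__all__ = ["VcpaConfig", "BmsDesign", "VcpaTrace", "bms_matrix", "vcpa_edf_counts", "select_vcpa"]


@dataclass
class VcpaConfig:
    edf_runs: int = 50
    n_bms: int = 1000
    omega: int = 14
    best_fraction: float = 0.1
    inclusion_ratio: float = 0.5
    cv_folds: int = 5
    max_lv: int = 10
    seed: int = 0


@dataclass
class BmsDesign:
    B: np.ndarray  # K x m boolean inclusion matrix
    inclusion_ratio: float


@dataclass
class VcpaTrace:
    runs: list = field(default_factory=list)  # dicts per EDF run
    final_candidates: np.ndarray | None = None
    final_best_indices: np.ndarray | None = None
    final_best_rmsecv: float = np.inf
    final_best_nlv: int = 0
    fold_ids: np.ndarray | None = None


def bms_matrix(
    m: int,
    K: int,
    inclusion_ratio: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> BmsDesign:
    """K x m binary inclusion matrix; rows with fewer than 2 ones resampled."""
    if m < 2:
        raise ValueError("need at least 2 live channels")
    if K < 10:
        raise ValueError("need at least 10 sampling runs")
    if not 0.0 < inclusion_ratio < 1.0:
        raise ValueError("inclusion_ratio must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = rng.random((K, m)) < inclusion_ratio
    bad = B.sum(axis=1) < 2
    while np.any(bad):
        B[bad] = rng.random((int(bad.sum()), m)) < inclusion_ratio
        bad = B.sum(axis=1) < 2
    return BmsDesign(B=B, inclusion_ratio=inclusion_ratio)


def vcpa_edf_counts(p: int, omega: int, runs: int) -> np.ndarray:
    """Live-set sizes along a geometric schedule from p down to omega.

    n_i = round(p * (omega/p)^((i-1)/(runs-1))); endpoints exact, sequence
    non-increasing.
    """
    if omega < 2:
        raise ValueError("omega must be at least 2")
    if p <= omega:
        raise ValueError("p must exceed omega")
    if runs < 2:
        raise ValueError("need at least 2 runs")
    i = np.arange(runs, dtype=float)
    counts = np.floor(p * (omega / p) ** (i / (runs - 1)) + 0.5).astype(int)
    counts[0] = p
    counts[-1] = omega
    counts = np.minimum.accumulate(counts)
    counts = np.maximum(counts, omega)
    return counts


def select_vcpa(
    ds: SpectralDataset,
    split: SplitResult,
    config: VcpaConfig | None = None,
) -> tuple[SelectionResult, VcpaTrace]:
    """Run VCPA on the calibration block of a dataset."""
    cfg = config or VcpaConfig()
    X_cal = np.ascontiguousarray(ds.X[split.cal_indices], dtype=float)
    y_cal = np.ascontiguousarray(ds.y[split.cal_indices], dtype=float)
    n, p = X_cal.shape
    if p <= cfg.omega:
        raise ValueError(f"channel count {p} must exceed omega = {cfg.omega}")

    ss = np.random.SeedSequence(cfg.seed)
    rng_folds, rng_bms = (np.random.default_rng(c) for c in ss.spawn(2))
    fold_ids = assign_folds(n, cfg.cv_folds, rng_folds)

    counts = vcpa_edf_counts(p, cfg.omega, cfg.edf_runs)
    live = np.arange(p)
    n_best = max(1, int(round(cfg.best_fraction * cfg.n_bms)))
    trace = VcpaTrace(fold_ids=fold_ids)

    for run in range(cfg.edf_runs):
        design = bms_matrix(live.size, cfg.n_bms, cfg.inclusion_ratio, rng_bms)
        X_live = np.ascontiguousarray(X_cal[:, live])
        scores, _ = _kernels.population_rmsecv(
            X_live, y_cal, design.B, fold_ids, cfg.cv_folds, cfg.max_lv
        )
        order = np.argsort(scores, kind="stable")[:n_best]
        freq = design.B[order].sum(axis=0)
        target = counts[run + 1] if run + 1 < cfg.edf_runs else cfg.omega
        # rank live channels by best-model frequency; stable sort keeps the
        # lowest index on ties
        rank = np.argsort(-freq, kind="stable")
        trace.runs.append(
            {
                "live_count": live.size,
                "best_mean_rmsecv": float(scores[order].mean()),
                "frequency": freq.copy(),
                "live": live.copy(),
            }
        )
        live = np.sort(live[rank[:target]])
        if live.size < 2:
            raise ValueError("live channel set collapsed below 2")

    trace.final_candidates = live.copy()

    # Exhaustive stage: all nonempty subsets of the omega survivors, scored
    # with the same fold assignment so comparisons are paired.
    omega = live.size
    masks = np.arange(1, 1 << omega, dtype=np.uint32)
    member = (masks[:, None] >> np.arange(omega, dtype=np.uint32)[None, :] & 1).astype(bool)
    X_final = np.ascontiguousarray(X_cal[:, live])
    scores, nlvs = _kernels.population_rmsecv(
        X_final, y_cal, member, fold_ids, cfg.cv_folds, cfg.max_lv
    )
    best_rmsecv = float(np.min(scores))
    ties = np.flatnonzero(scores == best_rmsecv)
    # fewest channels, then lexicographic channel order, on exact ties
    keyed = sorted(
        ties, key=lambda k: (int(member[k].sum()), tuple(live[member[k]]))
    )
    best_k = int(keyed[0])
    best_idx = live[member[best_k]]
    best_nlv = int(nlvs[best_k])
    trace.final_best_indices = best_idx
    trace.final_best_rmsecv = float(best_rmsecv)
    trace.final_best_nlv = best_nlv

    return (
        SelectionResult(
            method="vcpa",
            selected_indices=best_idx,
            n_lv=best_nlv,
            rmsecv=float(best_rmsecv),
            diagnostics=trace,
        ),
        trace,
    )
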