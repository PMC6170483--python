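"""Monte Carlo Uninformative Variable Elimination (MCUVE).

Artificial noise channels are appended to the centered calibration matrix;
PLS models are fitted on repeated random subsets of the calibration samples
and the per-channel regression coefficients collected.  The stability of
channel j is c_j = mean(beta_j) / sd(beta_j) over the Monte Carlo runs
(sample standard deviation, N-1 denominator).  Real channels whose |c|
falls below the largest artificial |c| are eliminated; the survivors are
ranked by |c| and nested prefixes of the ranking are scored by k-fold
RMSECV (latent-variable count re-chosen per prefix); the prefix with the
lowest RMSECV is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .dataset import SpectralDataset, SplitResult
from .pls import assign_folds
from .selection import SelectionResult, evaluate_subset

__all__ = [
    "McuveConfig",
    "StabilityProfile",
    "append_noise_variables",
    "compute_stability",
    "select_mcuve",
]


@dataclass
class McuveConfig:
    n_runs: int = 500
    sample_fraction: float = 0.8
    n_artificial: int | None = None  # None -> one artificial channel per real one
    noise_amplitude: float = 1e-3  # relative to the median column SD
    cv_folds: int = 5
    max_lv: int = 10
    seed: int = 0


@dataclass
class StabilityProfile:
    c_real: np.ndarray
    c_artif: np.ndarray
    n_runs: int
    samples_per_run: int


def append_noise_variables(
    Xc: np.ndarray,
    n_artificial: int,
    amplitude: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Append seeded uniform noise channels to a centered matrix.

    Noise is uniform on [-1, 1] scaled by ``amplitude`` times the median
    column standard deviation of ``Xc``, so the artificial block is tiny
    relative to the real signal and does not perturb the model.
    """
    if n_artificial < 1:
        raise ValueError("need at least one artificial channel")
    if amplitude <= 0:
        raise ValueError("noise amplitude must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xc = np.asarray(Xc, dtype=float)
    scale = amplitude * float(np.median(Xc.std(axis=0)))
    if scale == 0.0:
        scale = amplitude
    noise = rng.uniform(-1.0, 1.0, size=(Xc.shape[0], n_artificial)) * scale
    X_aug = np.hstack([Xc, noise])
    artif_idx = np.arange(Xc.shape[1], Xc.shape[1] + n_artificial)
    return X_aug, artif_idx


def compute_stability(
    X_aug: np.ndarray,
    yc: np.ndarray,
    n_real: int,
    n_runs: int = 500,
    sample_fraction: float = 0.8,
    n_lv: int = 2,
    seed: int | np.random.Generator = 0,
) -> StabilityProfile:
    """Coefficient-stability profile over Monte Carlo PLS fits.

    Each run draws ``round(sample_fraction * n)`` samples without
    replacement, re-centers them, and records the PLS coefficient vector at
    ``n_lv`` components.  Requires ``n_runs >= 2`` (the standard deviation
    uses an N-1 denominator).
    """
    if n_runs < 2:
        raise ValueError("stability needs at least 2 Monte Carlo runs")
    X_aug = np.ascontiguousarray(X_aug, dtype=float)
    yc = np.ascontiguousarray(yc, dtype=float).ravel()
    n, p_tot = X_aug.shape
    m = int(round(sample_fraction * n))
    if m < n_lv + 1:
        raise ValueError(f"sampling fraction too small: {m} samples for {n_lv} latent variables")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    betas = np.empty((n_runs, p_tot))
    for r in range(n_runs):
        rows = rng.choice(n, size=m, replace=False)
        Xs = X_aug[rows]
        ys = yc[rows]
        Xs = Xs - Xs.mean(axis=0)
        ys = ys - ys.mean()
        B, a_used = _kernels.pls1_coef_path(np.ascontiguousarray(Xs), ys, n_lv)
        betas[r] = B[:, n_lv - 1]
    sd = betas.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        j = int(np.flatnonzero(sd == 0.0)[0])
        raise ValueError(f"zero coefficient variance across runs at channel {j}")
    c = betas.mean(axis=0) / sd
    return StabilityProfile(
        c_real=c[:n_real], c_artif=c[n_real:], n_runs=n_runs, samples_per_run=m
    )


def select_mcuve(
    ds: SpectralDataset,
    split: SplitResult,
    config: McuveConfig | None = None,
) -> SelectionResult:
    """Run MCUVE on the calibration block of a dataset."""
    cfg = config or McuveConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_folds, rng_noise, rng_mc = (np.random.default_rng(c) for c in ss.spawn(3))

    X_cal = ds.X[split.cal_indices]
    y_cal = ds.y[split.cal_indices]
    n, p = X_cal.shape

    # Latent-variable count for the stability runs: the full-spectrum CV
    # choice, so every Monte Carlo fit lives in one consistent coefficient
    # space.
    fold_ids = assign_folds(n, cfg.cv_folds, rng_folds)
    _, n_lv_full, _ = evaluate_subset(X_cal, y_cal, np.arange(p), fold_ids, cfg.cv_folds, cfg.max_lv)

    Xc = X_cal - X_cal.mean(axis=0)
    yc = y_cal - y_cal.mean()
    p_artif = cfg.n_artificial if cfg.n_artificial is not None else p
    X_aug, artif_idx = append_noise_variables(Xc, p_artif, cfg.noise_amplitude, rng_noise)
    profile = compute_stability(
        X_aug, yc, n_real=p, n_runs=cfg.n_runs,
        sample_fraction=cfg.sample_fraction, n_lv=n_lv_full, seed=rng_mc,
    )

    cutoff = float(np.max(np.abs(profile.c_artif)))
    survivors = np.flatnonzero(np.abs(profile.c_real) >= cutoff)
    if survivors.size == 0:
        raise ValueError(
            "all channels eliminated by the artificial-noise cutoff; "
            "lower noise_amplitude"
        )
    # Rank survivors by |c| descending; stable sort keeps lowest index first
    # on ties.
    order = survivors[np.argsort(-np.abs(profile.c_real[survivors]), kind="stable")]

    prefix_rmsecv = np.empty(order.size)
    prefix_nlv = np.empty(order.size, dtype=int)
    for L in range(1, order.size + 1):
        idx = np.sort(order[:L])
        r, a, _ = evaluate_subset(X_cal, y_cal, idx, fold_ids, cfg.cv_folds, cfg.max_lv)
        prefix_rmsecv[L - 1] = r
        prefix_nlv[L - 1] = a
    best = int(np.argmin(prefix_rmsecv))
    selected = np.sort(order[: best + 1])
    return SelectionResult(
        method="mcuve",
        selected_indices=selected,
        n_lv=int(prefix_nlv[best]),
        rmsecv=float(prefix_rmsecv[best]),
        diagnostics={
            "profile": profile,
            "cutoff": cutoff,
            "ranking": order,
            "prefix_rmsecv": prefix_rmsecv,
            "n_lv_full": n_lv_full,
            "fold_ids": fold_ids,
        },
    )
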