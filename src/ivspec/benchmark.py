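"""The repeated-evaluation protocol: split once, run full-spectrum PLS and
the four selectors, repeat, and summarize mean +/- SD per method.

The Kennard-Stone split is deterministic and computed once; each repeat
re-runs every stochastic selector with ``seed = base_seed + repeat`` and
re-selects the latent-variable count, which is why mean nLV can be
fractional.  Summaries use the n-1 sample standard deviation.  Failed
repeats are recorded and excluded from the aggregates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .boss import BossConfig, select_boss
from .cars import CarsConfig, select_cars
from .dataset import SpectralDataset, SplitResult, kennard_stone_split
from .mcuve import McuveConfig, select_mcuve
from .pls import MetricsReport, fit_pls, kfold_cv, predict, q2, rmse, sd_over_runs
from .vcpa import VcpaConfig, select_vcpa

__all__ = ["BenchmarkConfig", "BenchmarkReport", "evaluate_model", "run_benchmark"]

_METRICS = ["nvar", "nlv", "q2cv", "q2test", "rmsec", "rmsep"]


@dataclass
class BenchmarkConfig:
    methods: tuple[str, ...] = ("pls", "mcuve", "cars", "boss", "vcpa")
    repeats: int = 50
    base_seed: int = 0
    cal_fraction: float = 36 / 59  # the study's 36-of-59 calibration share
    cv_folds: int = 5
    max_lv: int = 10
    mcuve: McuveConfig = field(default_factory=McuveConfig)
    cars: CarsConfig = field(default_factory=CarsConfig)
    boss: BossConfig = field(default_factory=BossConfig)
    vcpa: VcpaConfig = field(default_factory=VcpaConfig)


@dataclass
class BenchmarkReport:
    summary: pd.DataFrame
    details: pd.DataFrame
    repeats: int
    seeds: list[int]
    failures: list[tuple[str, int, str]] = field(default_factory=list)

    def to_csv(self, path_or_buf=None):
        return self.summary.to_csv(path_or_buf, index=False, lineterminator="\n")

    @staticmethod
    def read_summary(path_or_buf) -> pd.DataFrame:
        return pd.read_csv(path_or_buf)


def evaluate_model(
    ds: SpectralDataset,
    split: SplitResult,
    indices: np.ndarray,
    cv_folds: int = 5,
    max_lv: int = 10,
    seed: int = 0,
) -> tuple[MetricsReport, int]:
    """Metrics for a channel subset under the standard protocol.

    Restricts X to the subset, chooses the latent-variable count by k-fold
    CV on the calibration block (centering re-estimated per fold), refits
    on the whole calibration block, and reports RMSEC, Q2cv (from pooled
    out-of-fold predictions), RMSEP and Q2test (independent test set).
    """
    indices = np.sort(np.asarray(indices, dtype=int))
    if indices.size == 0:
        raise ValueError("empty channel subset")
    X_cal = ds.X[split.cal_indices][:, indices]
    y_cal = ds.y[split.cal_indices]
    X_te = ds.X[split.test_indices][:, indices]
    y_te = ds.y[split.test_indices]

    cv = kfold_cv(X_cal, y_cal, k=cv_folds, max_nlv=max_lv, seed=seed)
    n_lv = cv.chosen_nlv
    xm = X_cal.mean(axis=0)
    ym = float(y_cal.mean())
    from .dataset import CenteringTransform

    tr = CenteringTransform(xm, ym)
    model = fit_pls(X_cal - xm, y_cal - ym, n_lv, centering=tr)
    yhat_cal = predict(model, X_cal)
    report = MetricsReport(
        rmsec=rmse(y_cal, yhat_cal),
        rmsep=rmse(y_te, predict(model, X_te)) if y_te.size else float("nan"),
        q2_cv=q2(y_cal, cv.cv_predictions),
        q2_test=q2(y_te, predict(model, X_te)) if y_te.size >= 2 else float("nan"),
    )
    return report, model.n_lv


_SELECTORS = {
    "mcuve": lambda ds, split, cfg: select_mcuve(ds, split, cfg),
    "cars": lambda ds, split, cfg: select_cars(ds, split, cfg)[0],
    "boss": lambda ds, split, cfg: select_boss(ds, split, cfg)[0],
    "vcpa": lambda ds, split, cfg: select_vcpa(ds, split, cfg)[0],
}


def run_benchmark(ds: SpectralDataset, config: BenchmarkConfig | None = None) -> BenchmarkReport:
    """Run the full repeated-evaluation protocol on one dataset."""
    cfg = config or BenchmarkConfig()
    if cfg.repeats < 2:
        raise ValueError("need at least 2 repeats for a standard deviation")
    n_cal = max(2, int(round(cfg.cal_fraction * ds.n_samples)))
    split = kennard_stone_split(ds, n_cal)
    seeds = [cfg.base_seed + r for r in range(cfg.repeats)]

    rows = []
    failures: list[tuple[str, int, str]] = []
    for method in cfg.methods:
        for r, seed in enumerate(seeds):
            try:
                if method == "pls":
                    # deterministic: same full-spectrum model every repeat
                    indices = np.arange(ds.n_channels)
                    metrics, n_lv = evaluate_model(
                        ds, split, indices, cfg.cv_folds, cfg.max_lv, seed=cfg.base_seed
                    )
                    nvar = ds.n_channels
                else:
                    method_cfg = replace(getattr(cfg, method), seed=seed)
                    sel = _SELECTORS[method](ds, split, method_cfg)
                    metrics, n_lv = evaluate_model(
                        ds, split, sel.selected_indices, cfg.cv_folds, cfg.max_lv, seed=seed
                    )
                    nvar = sel.selected_indices.size
            except Exception as exc:  # degenerate configs must not kill the run
                failures.append((method, seed, str(exc)))
                continue
            rows.append(
                {
                    "method": method,
                    "repeat": r,
                    "seed": seed,
                    "nvar": nvar,
                    "nlv": n_lv,
                    "q2cv": metrics.q2_cv,
                    "q2test": metrics.q2_test,
                    "rmsec": metrics.rmsec,
                    "rmsep": metrics.rmsep,
                }
            )
    details = pd.DataFrame(rows)

    summary_rows = []
    for method in cfg.methods:
        sub = details[details["method"] == method]
        row: dict[str, object] = {"method": method, "n_ok": len(sub)}
        for metric in _METRICS:
            vals = sub[metric].to_numpy(dtype=float)
            row[f"{metric}_mean"] = float(vals.mean()) if vals.size else float("nan")
            row[f"{metric}_sd"] = sd_over_runs(vals) if vals.size >= 2 else float("nan")
        if method == "pls":
            row["nvar_sd"] = float("nan")  # constant by construction
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    return BenchmarkReport(
        summary=summary, details=details, repeats=cfg.repeats, seeds=seeds, failures=failures
    )
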