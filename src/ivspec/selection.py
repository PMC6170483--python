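"""Shared result type and helpers for the wavelength-selection methods."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _kernels

__all__ = ["SelectionResult", "evaluate_subset"]


@dataclass
class SelectionResult:
    """Channels retained by a selector, with the CV evidence behind them."""

    method: str
    selected_indices: np.ndarray
    n_lv: int
    rmsecv: float
    diagnostics: Any = field(default=None, repr=False)

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("empty selection")
        if len(set(idx.tolist())) != idx.size:
            raise ValueError("duplicate channel indices")
        self.selected_indices = np.sort(idx)


def evaluate_subset(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    fold_ids: np.ndarray,
    n_folds: int,
    max_lv: int,
):
    """RMSECV of a channel subset with the latent-variable count re-chosen.

    Returns ``(rmsecv, n_lv, curve)`` where ``n_lv`` attains the minimum of
    the RMSECV curve (smallest count on ties).  The fold assignment is taken
    as given so that subsets evaluated with the same folds are paired.
    """
    idx = np.asarray(idx, dtype=int)
    Xs = np.ascontiguousarray(X[:, idx], dtype=float)
    preds, lv_cap = _kernels.cv_predictions(
        Xs, np.ascontiguousarray(y, dtype=float), fold_ids, n_folds, max_lv
    )
    resid = preds[:, :lv_cap] - np.asarray(y, dtype=float)[:, None]
    curve = np.sqrt(np.mean(resid ** 2, axis=0))
    a = int(np.argmin(curve))
    return float(curve[a]), a + 1, curve
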