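"""PLS1 regression, k-fold cross-validation and validation metrics.

The calibration model is the bilinear decomposition X = T P' + E,
y = T q' + f; the regression coefficient vector b (in centered space) is
recovered from the weights/loadings so that predictions via b equal
predictions via the score decomposition.  The number of latent variables is
chosen by k-fold cross-validation on pooled out-of-fold residuals (RMSECV),
with ties broken toward the smaller count.

Metrics follow the standard chemometric definitions:
``rmse = sqrt(sum (y - yhat)^2 / n)`` and ``q2 = 1 - PRESS/TSS`` with the
total sum of squares taken about the mean of the supplied reference vector;
``sd_over_runs`` is the n-1 sample standard deviation used to summarize
repeated runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .dataset import CenteringTransform

__all__ = [
    "PLSModel",
    "CVResult",
    "MetricsReport",
    "fit_pls",
    "predict",
    "kfold_cv",
    "assign_folds",
    "rmsecv_curve",
    "rmse",
    "q2",
    "sd_over_runs",
    "dump_model",
]


@dataclass
class PLSModel:
    scores_T: np.ndarray
    loadings_P: np.ndarray
    y_loadings_q: np.ndarray
    weights_W: np.ndarray
    coef_b: np.ndarray
    n_lv: int
    centering: CenteringTransform | None = None


@dataclass
class CVResult:
    rmsecv_by_nlv: np.ndarray
    chosen_nlv: int
    cv_predictions: np.ndarray
    fold_assignment: np.ndarray

    @property
    def rmsecv(self) -> float:
        return float(self.rmsecv_by_nlv[self.chosen_nlv - 1])


@dataclass
class MetricsReport:
    rmsec: float
    rmsep: float
    q2_cv: float
    q2_test: float


def fit_pls(
    Xc: np.ndarray,
    yc: np.ndarray,
    n_lv: int,
    centering: CenteringTransform | None = None,
) -> PLSModel:
    """Fit a deflation-based PLS1 model on centered data.

    If X is rank-deficient and fewer than ``n_lv`` components can be
    extracted, the model stops early and reports the achieved count in
    ``model.n_lv``.
    """
    Xc = np.ascontiguousarray(Xc, dtype=float)
    yc = np.ascontiguousarray(yc, dtype=float).ravel()
    n, p = Xc.shape
    if n_lv < 1:
        raise ValueError("n_lv must be at least 1")
    if n_lv > min(n - 1, p):
        raise ValueError(f"n_lv {n_lv} exceeds min(n-1, p) = {min(n - 1, p)}")
    T, W, P, q, a_used = _kernels.pls1_nipals(Xc, yc, n_lv)
    if a_used == 0:
        raise ValueError("no PLS component extractable (zero covariance)")
    B = _kernels.coef_path_from_nipals(W, P, q, a_used, n_lv)
    return PLSModel(
        scores_T=T[:, :a_used],
        loadings_P=P[:, :a_used],
        y_loadings_q=q[:a_used],
        weights_W=W[:, :a_used],
        coef_b=B[:, a_used - 1],
        n_lv=a_used,
        centering=centering,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict the response for raw spectra.

    Applies the model's centering transform, multiplies by the coefficient
    vector and adds back the calibration response mean.  A model fitted
    without a centering transform predicts in centered space.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef_b.size:
        raise ValueError(f"expected {model.coef_b.size} channels, got {X.shape[1]}")
    if model.centering is None:
        return X @ model.coef_b
    return model.centering.center_x(X) @ model.coef_b + model.centering.y_mean


def assign_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels via a seeded permutation cut into near-equal blocks."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError(f"{k} folds exceed {n} samples")
    perm = rng.permutation(n)
    fold_ids = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold_ids[chunk] = f
    return fold_ids


def rmsecv_curve(
    X: np.ndarray,
    y: np.ndarray,
    fold_ids: np.ndarray,
    n_folds: int,
    max_lv: int,
) -> np.ndarray:
    """RMSECV for 1..lv_cap latent variables from pooled out-of-fold residuals."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float).ravel()
    preds, lv_cap = _kernels.cv_predictions(X, y, fold_ids, n_folds, max_lv)
    resid = preds[:, :lv_cap] - y[:, None]
    return np.sqrt(np.mean(resid ** 2, axis=0))


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    max_nlv: int = 10,
    seed: int = 0,
) -> CVResult:
    """Choose the latent-variable count by k-fold cross-validation.

    Folds come from a seeded permutation cut into contiguous blocks;
    centering is re-estimated inside each training fold.  If ``max_nlv``
    exceeds the capacity of the smallest training fold it is capped (the
    returned curve is correspondingly shorter).  The chosen count attains
    the minimum RMSECV, smallest count on ties.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    fold_ids = assign_folds(X.shape[0], k, rng)
    preds, lv_cap = _kernels.cv_predictions(X, y, fold_ids, k, max_nlv)
    resid = preds[:, :lv_cap] - y[:, None]
    curve = np.sqrt(np.mean(resid ** 2, axis=0))
    chosen = int(np.argmin(curve)) + 1
    return CVResult(
        rmsecv_by_nlv=curve,
        chosen_nlv=chosen,
        cv_predictions=preds[:, chosen - 1].copy(),
        fold_assignment=fold_ids,
    )


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error, sqrt(sum (y_i - yhat_i)^2 / n)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size < 1:
        raise ValueError("need at least one value")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def q2(y: np.ndarray, yhat: np.ndarray) -> float:
    """1 - sum (y - yhat)^2 / sum (y - ybar)^2, ybar the mean of ``y``.

    Equals 1 for perfect prediction, 0 for the mean predictor, and may be
    negative.  Undefined (raises) for a constant reference vector.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least two values")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("q2 undefined for constant reference values")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / tss


def sd_over_runs(values: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) across repeated runs."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least two values for a standard deviation")
    return float(np.std(values, ddof=1))


def dump_model(model: PLSModel) -> str:
    """Plain-text key-value dump of a fitted model (for reproducibility)."""
    lines = [f"n_lv={model.n_lv}"]
    if model.centering is not None:
        lines.append("y_mean=" + repr(model.centering.y_mean))
        lines.append("x_means=" + ",".join(repr(v) for v in model.centering.x_means))
    lines.append("coef_b=" + ",".join(repr(v) for v in model.coef_b))
    return "\n".join(lines) + "\n"
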