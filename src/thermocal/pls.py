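"""Univariate PLS regression (NIPALS), random-subset cross-validation,
latent-variable selection and prediction summary metrics.

For a single response the NIPALS recursion is non-iterative per
component: with X and y mean-centred,

    w_k = X^T y / ||X^T y||,   t_k = X w_k,
    p_k = X^T t_k / t_k^T t_k, q_k = y^T t_k / t_k^T t_k,
    X <- X - t_k p_k^T,        y <- y - q_k t_k.

The regression vector is b = W (P^T W)^{-1} q, and predictions are
(X - x_mean) b + y_mean.  With as many components as the centred rank,
PLS reproduces the minimum-norm least-squares fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import (
    DegenerateTargetError,
    DesignError,
    ParameterError,
    RankError,
)
from .preprocess import apply_center, fit_center
from .spectra_core import SpectrumMeta


@dataclass
class PLSModel:
    """Fitted PLS calibration mapping spectra to concentration."""

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # W (p, n_lv)
    x_loadings: np.ndarray  # P (p, n_lv)
    y_loadings: np.ndarray  # q (n_lv,)
    coef: np.ndarray  # b (p,), derived
    preprocessing_tag: str | None = None

    def to_dict(self) -> dict:
        return {
            "n_lv": self.n_lv,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "preprocessing_tag": self.preprocessing_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            n_lv=int(d["n_lv"]),
            x_mean=np.asarray(d["x_mean"], float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], float),
            x_loadings=np.asarray(d["x_loadings"], float),
            y_loadings=np.asarray(d["y_loadings"], float),
            coef=np.asarray(d["coef"], float),
            preprocessing_tag=d.get("preprocessing_tag"),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int, allow_early_stop: bool = False):
    """NIPALS on centred data; returns W, P, q, scores T, n_found.

    With ``allow_early_stop`` the recursion stops quietly when X or the y
    residual is numerically exhausted (further components cannot change
    predictions) and returns the components found so far; otherwise
    exhaustion before ``n_lv`` raises :class:`RankError`.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    X = Xc.copy()
    y = yc.copy()
    x_scale = np.linalg.norm(Xc) or 1.0
    n_found = 0
    for k in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        exhausted = nw <= 1e-13 * x_scale * (np.linalg.norm(yc) or 1.0)
        if not exhausted:
            w /= nw
            t = X @ w
            tt = float(t @ t)
            exhausted = tt <= (1e-13 * x_scale) ** 2
        if exhausted:
            if allow_early_stop:
                break
            raise RankError(
                f"data support only {k} latent variables (requested {n_lv})"
            )
        W[:, k] = w
        T[:, k] = t
        P[:, k] = X.T @ t / tt
        q[k] = float(y @ t) / tt
        X -= np.outer(t, P[:, k])
        y = y - q[k] * t
        n_found = k + 1
    return W[:, :n_found], P[:, :n_found], q[:n_found], T[:, :n_found], n_found


def _coef_from_factors(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression vector using the first k components."""
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    preprocessing_tag: str | None = None,
) -> PLSModel:
    """Fit a mean-centred univariate PLS model with ``n_lv`` components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ParameterError("X must be 2-D with one row per y value")
    n, p = X.shape
    if n < 2:
        raise ParameterError("PLS needs at least 2 calibration rows")
    if np.ptp(y) == 0:
        raise DegenerateTargetError("response has zero variance")
    if not 1 <= n_lv <= min(n - 1, p):
        raise RankError(f"n_lv={n_lv} outside [1, min(rows-1={n-1}, columns={p})]")

    x_mean = fit_center(X)
    y_mean = float(y.mean())
    W, P, q, _, _ = _nipals(X - x_mean, y - y_mean, n_lv)
    b = _coef_from_factors(W, P, q, n_lv)
    return PLSModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=b,
        preprocessing_tag=preprocessing_tag,
    )


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict concentrations:  (X - x_mean) b + y_mean."""
    X = np.asarray(X, dtype=float)
    one = X.ndim == 1
    Xc = apply_center(X, model.x_mean)
    yhat = Xc @ model.coef + model.y_mean
    return float(yhat[0]) if one else yhat


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    """Random-subset cross-validation settings (default 3 splits, 20
    iterations, grouping by sample so replicates move as one unit)."""

    n_splits: int = 3
    n_iterations: int = 20
    max_lv: int | None = None
    seed: int = 0
    grouping: str = "by_sample"  # "by_sample" | "by_spectrum"

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ParameterError("n_splits must be >= 2")
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        if self.max_lv is not None and self.max_lv < 1:
            raise ParameterError("max_lv must be >= 1")
        if self.grouping not in ("by_sample", "by_spectrum"):
            raise ParameterError(f"unknown grouping {self.grouping!r}")


@dataclass
class CVResult:
    """Pooled RMSECV per latent-variable count plus raw residual records."""

    rmsecv: np.ndarray  # (max_lv,)
    chosen_lv: int
    residuals: np.ndarray  # (n_iterations, n_spectra, max_lv)
    held_out_groups: list[list[list]]  # per iteration, per fold: group keys

    @property
    def max_lv(self) -> int:
        return int(self.rmsecv.size)


def resolve_max_lv(n_rows: int, n_cols: int, n_groups: int, cfg: CVConfig,
                   max_group_size: int) -> int:
    """Largest safe LV count: bounded by columns and by the smallest
    training-fold row count minus one."""
    fold_groups = math.ceil(n_groups / cfg.n_splits)
    min_train_rows = n_rows - fold_groups * max_group_size
    cap = min(n_cols, max(1, min_train_rows - 1))
    return min(cfg.max_lv if cfg.max_lv is not None else 15, cap)


def random_subset_cv(
    X: np.ndarray,
    y: np.ndarray,
    meta: Sequence[SpectrumMeta] | Sequence | None,
    cfg: CVConfig,
) -> CVResult:
    """Random-subset CV: per iteration, groups are randomly partitioned
    into ``n_splits`` folds and each fold is held out once, the model
    being refitted (including re-centering) on the remainder for every
    LV count; squared errors are pooled over folds and iterations.

    ``meta`` supplies the grouping unit: with ``by_sample`` all spectra
    sharing a ``sample_id`` (a (concentration, temperature) experiment and
    its replicates) move together, preventing replicate leakage.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if cfg.grouping == "by_sample":
        if meta is None:
            raise ParameterError("by_sample grouping requires metadata")
        keys = [m.sample_id if isinstance(m, SpectrumMeta) else m for m in meta]
    else:
        keys = list(range(n))
    unique_keys = sorted(set(keys), key=str)
    if len(unique_keys) < cfg.n_splits:
        raise DesignError(
            f"{len(unique_keys)} groups cannot be split into {cfg.n_splits} folds"
        )
    key_index = {k: i for i, k in enumerate(unique_keys)}
    group_of = np.array([key_index[k] for k in keys])
    group_rows = [np.flatnonzero(group_of == g) for g in range(len(unique_keys))]
    max_group = max(len(r) for r in group_rows)

    max_lv = resolve_max_lv(n, p, len(unique_keys), cfg, max_group)
    rng = np.random.default_rng(cfg.seed)
    residuals = np.full((cfg.n_iterations, n, max_lv), np.nan)
    held_out: list[list[list]] = []

    for it in range(cfg.n_iterations):
        perm = rng.permutation(len(unique_keys))
        folds = np.array_split(perm, cfg.n_splits)
        fold_keys: list[list] = []
        for fold in folds:
            fold_keys.append([unique_keys[g] for g in fold])
            test_rows = np.concatenate([group_rows[g] for g in fold])
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_rows] = False
            X_tr, y_tr = X[train_mask], y[train_mask]
            x_mean = fit_center(X_tr)
            y_mean = float(y_tr.mean())
            W, P, q, _, k_avail = _nipals(
                X_tr - x_mean, y_tr - y_mean, max_lv, allow_early_stop=True
            )
            Xc_te = X[test_rows] - x_mean
            for k in range(1, max_lv + 1):
                # beyond the supported rank the fit (and prediction) is frozen
                b = _coef_from_factors(W, P, q, min(k, k_avail))
                residuals[it, test_rows, k - 1] = y[test_rows] - (Xc_te @ b + y_mean)
        held_out.append(fold_keys)

    rmsecv = np.sqrt(np.mean(residuals**2, axis=(0, 1)))
    chosen = select_latent_variables(rmsecv)
    return CVResult(
        rmsecv=rmsecv, chosen_lv=chosen, residuals=residuals, held_out_groups=held_out
    )


def select_latent_variables(
    result: CVResult | np.ndarray, tolerance_fraction: float = 0.10
) -> int:
    """Most parsimonious LV count whose RMSECV is within
    ``tolerance_fraction`` of the minimum RMSECV."""
    rmsecv = result.rmsecv if isinstance(result, CVResult) else np.asarray(result, float)
    if rmsecv.size == 0:
        raise ParameterError("empty RMSECV curve")
    limit = (1.0 + tolerance_fraction) * rmsecv.min()
    return int(np.flatnonzero(rmsecv <= limit)[0]) + 1


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(RMSE, R^2) of predictions against references."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ParameterError("regression_metrics needs two equal-length vectors (n >= 2)")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateTargetError("R^2 undefined for zero-variance references")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    rmse = math.sqrt(ss_res / y_true.size)
    return rmse, 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class PredictionSummary:
    """Accuracy/precision summary of repeated predictions of one known
    sample: RMSE vs truth, mean/min/max of the predictions and the
    relative standard deviation 100 * sd / mean (sample sd, n-1)."""

    rmse: float
    mean: float
    min: float
    max: float
    rsd: float

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mean": self.mean,
            "min": self.min,
            "max": self.max,
            "rsd": self.rsd,
        }


def prediction_summary(y_pred: np.ndarray, y_true_scalar: float) -> PredictionSummary:
    y_pred = np.asarray(y_pred, float).ravel()
    if y_pred.size == 0:
        raise ParameterError("prediction_summary needs at least one prediction")
    mean = float(y_pred.mean())
    if mean == 0:
        raise DegenerateTargetError("RSD undefined for zero-mean predictions")
    sd = float(y_pred.std(ddof=1)) if y_pred.size > 1 else 0.0
    rmse = float(np.sqrt(np.mean((y_pred - y_true_scalar) ** 2)))
    return PredictionSummary(
        rmse=rmse,
        mean=mean,
        min=float(y_pred.min()),
        max=float(y_pred.max()),
        rsd=100.0 * sd / mean,
    )
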