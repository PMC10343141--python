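"""Two-step hierarchical cross-validation.

Step 1 (``select_kernel``): for every candidate kernel, each outer fold
is scored with the lambda chosen by an inner CV on the remaining folds;
the kernel with the best mean outer score wins (ties break by grid
order).  Step 2 (``refit_lambda``): the winning kernel's lambda is
re-chosen by inner CV on the full data and the final model is fit on
everything.

The accounting identity ``fit_count = K * H * N_in * N_out`` (kernels x
lambdas x inner folds x outer folds) is audited by an actual counter on
the dual solves of the inner loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import (
    InvalidInputError,
    SelectionFailureError,
    UndefinedMetricError,
)
from .estimators import FittedModel, fit_counter, krr_fit, solve_dual
from .kernels import KernelSpec, gram_matrix, psd_clip
from .simplex import as_table

logger = logging.getLogger(__name__)

SCORINGS = ("neg-rmse", "balanced-accuracy")


def default_lambda_grid(size: int = 10) -> np.ndarray:
    """Log-spaced lambda grid, 1e-6 .. 1e3."""
    return np.logspace(-6, 3, size)


@dataclass
class CVConfig:
    """Configuration of the hierarchical CV."""

    n_outer: int = 10
    n_inner: int = 5
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    scoring: str = "neg-rmse"
    stratified: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_outer < 2 or self.n_inner < 2:
            raise InvalidInputError("n_outer and n_inner must be >= 2")
        self.lambda_grid = np.sort(np.asarray(self.lambda_grid, dtype=float))
        if self.lambda_grid.size < 1 or np.any(self.lambda_grid <= 0):
            raise InvalidInputError("lambda grid must be non-empty and positive")
        if self.scoring not in SCORINGS:
            raise InvalidInputError(f"scoring must be one of {SCORINGS}")

    @property
    def task(self) -> str:
        return "classification" if self.scoring == "balanced-accuracy" else "regression"


@dataclass
class SelectionResult:
    """Outcome of the kernel-selection step."""

    best_spec: KernelSpec
    best_lambda: float | None
    cv_table: pd.DataFrame
    fit_count: int


def cv_score(y_true, y_pred, scoring: str) -> float:
    """neg-RMSE for regression, balanced accuracy for classification."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("y_true and y_pred must have equal length")
    if scoring == "neg-rmse":
        return -float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if scoring == "balanced-accuracy":
        classes = np.unique(y_true)
        if classes.size < 2:
            raise UndefinedMetricError(
                "balanced accuracy undefined: a class is absent from y_true"
            )
        recalls = [np.mean(y_pred[y_true == cl] == cl) for cl in classes]
        return float(np.mean(recalls))
    raise InvalidInputError(f"unknown scoring {scoring!r}")


def _scores_to_labels(scores: np.ndarray) -> np.ndarray:
    return np.where(scores >= 0, 1.0, -1.0)


def _folds(y: np.ndarray, n_splits: int, stratified: bool, seed: int):
    """Deterministic (optionally stratified) shuffled folds."""
    if stratified:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros_like(y), y))
    splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros_like(y)))


def _fold_fit_score(K: np.ndarray, y: np.ndarray, tr, te, lam: float,
                    config: CVConfig) -> float:
    """Fit the dual system on ``tr`` and score predictions on ``te``."""
    Ktr = K[np.ix_(tr, tr)]
    if config.task == "regression":
        mu = float(y[tr].mean())
        alpha = solve_dual(Ktr, y[tr] - mu, lam)
    else:
        mu = 0.0
        alpha = solve_dual(Ktr, y[tr], lam)
    pred = K[np.ix_(te, tr)] @ alpha + mu
    if config.task == "classification":
        pred = _scores_to_labels(pred)
    return cv_score(y[te], pred, config.scoring)


def _inner_select_lambda(K: np.ndarray, y: np.ndarray, idx: np.ndarray,
                         config: CVConfig) -> float:
    """Pick lambda by ``n_inner``-fold CV restricted to ``idx``.

    Ties go to the smaller lambda (stronger regularization relative to
    interpolation; the grid is sorted ascending so argmax suffices).
    """
    inner = _folds(y[idx], config.n_inner, config.stratified, config.seed)
    means = np.empty(config.lambda_grid.size)
    for li, lam in enumerate(config.lambda_grid):
        scores = []
        for itr, ite in inner:
            scores.append(_fold_fit_score(K, y, idx[itr], idx[ite], lam, config))
        means[li] = np.mean(scores)
    return float(config.lambda_grid[int(np.argmax(means))])


def select_kernel(X, y, kernel_grid: list[KernelSpec], config: CVConfig | None = None
                  ) -> SelectionResult:
    """Hierarchical CV over a kernel grid; returns the winning spec.

    ``best_lambda`` is left unset here — it is chosen on the full data by
    :func:`refit_lambda` (or use :func:`fit_pipeline` for both steps).
    """
    X = as_table(X)
    y = np.asarray(y, dtype=float)
    config = config or CVConfig()
    if not kernel_grid:
        raise InvalidInputError("kernel grid must be non-empty")
    if X.n < config.n_outer:
        raise InvalidInputError("need at least n_outer samples")

    fit_counter.reset()
    outer = _folds(y, config.n_outer, config.stratified, config.seed)

    rows = []
    failures: dict[str, str] = {}
    best_idx, best_mean = None, -np.inf
    for ki, spec in enumerate(kernel_grid):
        try:
            K = gram_matrix(spec, X).values
            if spec.family == "heat-diffusion":
                K = psd_clip(K)
            outer_scores = []
            for tr, te in outer:
                tr = np.asarray(tr)
                lam = _inner_select_lambda(K, y, tr, config)
                # outer refit with the chosen lambda, not part of fit_count
                Ktr = K[np.ix_(tr, tr)]
                mu = float(y[tr].mean()) if config.task == "regression" else 0.0
                alpha = solve_dual(Ktr, y[tr] - mu, lam, count=False)
                pred = K[np.ix_(te, tr)] @ alpha + mu
                if config.task == "classification":
                    pred = _scores_to_labels(pred)
                outer_scores.append(cv_score(y[te], pred, config.scoring))
        except Exception as exc:
            logger.warning("kernel %s failed during CV: %s", spec.name, exc)
            failures[spec.name] = str(exc)
            rows.append({"kernel": spec.name, "family": spec.family,
                         "mean_score": np.nan, "sd_score": np.nan})
            continue
        mean, sd = float(np.mean(outer_scores)), float(np.std(outer_scores))
        rows.append({"kernel": spec.name, "family": spec.family,
                     "mean_score": mean, "sd_score": sd})
        if mean > best_mean:  # strict: ties break by grid order
            best_mean, best_idx = mean, ki

    if best_idx is None:
        raise SelectionFailureError(
            "all kernels failed during selection: " + "; ".join(
                f"{k}: {v}" for k, v in failures.items())
        )
    return SelectionResult(
        best_spec=kernel_grid[best_idx],
        best_lambda=None,
        cv_table=pd.DataFrame(rows),
        fit_count=fit_counter.count,
    )


def refit_lambda(X, y, spec: KernelSpec, config: CVConfig | None = None
                 ) -> tuple[float, FittedModel]:
    """Choose lambda by inner CV on the full data and fit the final model."""
    X = as_table(X)
    y = np.asarray(y, dtype=float)
    config = config or CVConfig()
    K = gram_matrix(spec, X).values
    if spec.family == "heat-diffusion":
        K = psd_clip(K)
    lam = _inner_select_lambda(K, y, np.arange(X.n), config)
    model = krr_fit(X, y, spec, lam, task=config.task)
    return lam, model


def fit_pipeline(X, y, kernel_grid: list[KernelSpec] | None = None,
                 config: CVConfig | None = None
                 ) -> tuple[SelectionResult, FittedModel]:
    """Both selection steps: pick the kernel, then lambda, then fit."""
    from .kernels import default_kernel_grid

    X = as_table(X)
    config = config or CVConfig()
    grid = kernel_grid if kernel_grid is not None else default_kernel_grid(X)
    result = select_kernel(X, y, grid, config)
    lam, model = refit_lambda(X, y, result.best_spec, config)
    result.best_lambda = lam
    return result, model
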