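"""Kernel ridge regression/classification in dual form.

``krr_fit`` solves ``(K + n lambda I) alpha = y_centered`` so the
penalty scales with sample size and lambda grids transfer across n.
Classification fits the same system on +/-1 labels and thresholds the
score at zero.  ``path_derivative`` is the central finite difference of
a function along the multiplicative simplex perturbation, the building
block of the feature-influence statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import InvalidInputError, NumericalError, SchemaError
from .kernels import KernelSpec, gram_matrix, psd_clip
from .simplex import CompositionTable, as_table, check_composition, psi_perturb

#: default finite-difference step for path derivatives
DEFAULT_FD_STEP = 1e-4

TASKS = ("regression", "classification")


class FitCounter:
    """Counts dual-system solves; audited by the CV accounting."""

    def __init__(self):
        self.count = 0

    def reset(self):
        self.count = 0

    def increment(self):
        self.count += 1


fit_counter = FitCounter()


@dataclass
class FittedModel:
    """Dual-form kernel model ``f(x) = sum_i alpha_i k(X_i, x) + intercept``."""

    spec: KernelSpec
    train_X: CompositionTable
    alpha: np.ndarray
    intercept: float
    lam: float
    task: str = "regression"

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape[0] != self.train_X.n:
            raise InvalidInputError("alpha length must equal the training sample size")
        if self.lam <= 0:
            raise InvalidInputError("lambda must be > 0")
        if self.task not in TASKS:
            raise InvalidInputError(f"unknown task {self.task!r}")

    def __call__(self, X) -> np.ndarray:
        """Evaluate the score function on rows of ``X`` (array or table),
        without label checking — internal use by influence estimators."""
        if isinstance(X, CompositionTable):
            X = X.values
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Kc = gram_matrix(self.spec, self.train_X, CompositionTable(
            X, component_labels=self.train_X.component_labels)).values
        return Kc.T @ self.alpha + self.intercept


def solve_dual(K: np.ndarray, y_centered: np.ndarray, lam: float,
               count: bool = True) -> np.ndarray:
    """Solve ``(K + n lambda I) alpha = y_centered``."""
    n = K.shape[0]
    A = K + n * lam * np.eye(n)
    try:
        alpha = scipy.linalg.solve(A, y_centered, assume_a="pos")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
        try:
            alpha = scipy.linalg.solve(A, y_centered)
        except Exception as exc:  # pragma: no cover - defensive
            raise NumericalError(
                "ridge system is singular beyond solver tolerance; "
                "increase lambda"
            ) from exc
    if not np.all(np.isfinite(alpha)):
        raise NumericalError(
            "ridge solve produced non-finite coefficients; increase lambda"
        )
    if count:
        fit_counter.increment()
    return alpha


def krr_fit(X, y, spec: KernelSpec, lam: float, task: str = "regression") -> FittedModel:
    """Fit kernel ridge regression (or +/-1 classification) by the
    representer theorem.

    Heat-diffusion Gram matrices are spectrally repaired (negative
    eigenvalues clipped at zero) before solving.
    """
    X = as_table(X)
    y = np.asarray(y, dtype=float)
    if X.n < 2:
        raise InvalidInputError("need at least 2 samples")
    if y.shape != (X.n,):
        raise InvalidInputError("response length must equal the sample size")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("response contains non-finite values")
    if lam <= 0:
        raise InvalidInputError("lambda must be > 0")
    if task not in TASKS:
        raise InvalidInputError(f"unknown task {task!r}")
    if task == "classification" and not set(np.unique(y)) <= {-1.0, 1.0}:
        raise InvalidInputError("classification requires labels in {-1, +1}")

    K = gram_matrix(spec, X).values
    if spec.family == "heat-diffusion":
        K = psd_clip(K)
    if task == "regression":
        intercept = float(y.mean())
        yc = y - intercept
    else:
        intercept = 0.0
        yc = y
    alpha = solve_dual(K, yc, lam)
    return FittedModel(spec=spec, train_X=X, alpha=alpha,
                       intercept=intercept, lam=lam, task=task)


def predict(model: FittedModel, Xnew) -> np.ndarray:
    """Evaluate the fitted score function on new samples.

    Component labels must match the training table exactly (no silent
    reordering).  For classification the returned values are scores;
    use :func:`predict_labels` for the +/-1 decision.
    """
    Xnew = as_table(Xnew)
    if Xnew.component_labels != model.train_X.component_labels:
        raise SchemaError(
            "component labels of the new table do not match the training "
            "table; align columns explicitly before predicting"
        )
    return model(Xnew.values)


def predict_labels(model: FittedModel, Xnew) -> np.ndarray:
    """Class labels in {-1, +1} by thresholding the score at zero."""
    scores = predict(model, Xnew)
    return np.where(scores >= 0, 1.0, -1.0)


def path_derivative(f, x, j: int, h: float = DEFAULT_FD_STEP) -> float:
    """Central finite difference of ``c -> f(psi_j(x, c))`` at ``c = 1``.

    For differentiable ``f`` this estimates
    ``x_j (d_j f(x) - sum_l x_l d_l f(x))`` with O(h^2) error.
    """
    if not 0 < h < 1:
        raise InvalidInputError("step h must be in (0, 1)")
    if not callable(f):
        raise InvalidInputError("f must be callable or a FittedModel")
    x = check_composition(x)
    xp = psi_perturb(x, j, 1.0 + h)
    xm = psi_perturb(x, j, 1.0 - h)
    fp = float(np.asarray(f(xp)).ravel()[0])
    fm = float(np.asarray(f(xm)).ravel()[0])
    return (fp - fm) / (2.0 * h)


MODEL_FORMAT_VERSION = 1


def save_model(model: FittedModel, path) -> None:
    """Serialize a fitted model to a versioned JSON container."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": model.spec.to_dict(),
        "component_labels": model.train_X.component_labels,
        "sample_ids": model.train_X.sample_ids,
        "train_X": model.train_X.values.tolist(),
        "alpha": model.alpha.tolist(),
        "intercept": model.intercept,
        "lambda": model.lam,
        "task": model.task,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> FittedModel:
    """Load a model written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise SchemaError("unsupported model format version")
    table = CompositionTable(
        np.asarray(payload["train_X"], dtype=float),
        component_labels=payload["component_labels"],
        sample_ids=payload["sample_ids"],
    )
    return FittedModel(
        spec=KernelSpec.from_dict(payload["spec"]),
        train_X=table,
        alpha=np.asarray(payload["alpha"], dtype=float),
        intercept=float(payload["intercept"]),
        lam=float(payload["lambda"]),
        task=payload["task"],
    )
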