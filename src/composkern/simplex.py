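"""Compositions, closure, the centered log-ratio transform and the two
simplex perturbations that model interpretation rests on.

A composition is a vector of ``p >= 2`` non-negative proportions summing
to one.  Two coordinate-wise perturbations keep a point on the simplex:

* ``psi_perturb`` multiplies one component by a factor ``c`` and
  re-closes the vector (multiplicative perturbation);
* ``phi_perturb`` pins one component to a value ``z`` and rescales the
  remaining mass proportionally.

``clr_shift`` is the centered log-ratio transform with an optional
additive shift that moves zero entries into the interior before taking
logs; the shift is applied to *all* entries and the vector is re-closed,
so it acts as a single tunable pseudo-count hyperparameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegeneratePerturbationError,
    InvalidInputError,
    ZeroHandlingError,
)

logger = logging.getLogger(__name__)

#: rows whose sum deviates from 1 by at most this are accepted as-is
SUM_TOL = 1e-9
#: rows off by more than SUM_TOL but at most this are re-closed with a warning
RECLOSE_TOL = 1e-6


def closure(v) -> np.ndarray:
    """Normalize a non-negative vector onto the simplex.

    Parameters
    ----------
    v : array-like, shape (p,)
        Non-negative entries, at least one strictly positive, ``p >= 2``.

    Returns
    -------
    ndarray
        ``v / sum(v)``.  Idempotent on simplex points.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.shape[0] < 2:
        raise InvalidInputError("closure requires a vector with at least 2 entries")
    if np.any(v < 0):
        raise InvalidInputError("closure requires non-negative entries")
    s = v.sum()
    if s <= 0:
        raise InvalidInputError("closure undefined for the all-zero vector")
    return v / s


def closure_rows(M) -> np.ndarray:
    """Row-wise closure of a non-negative matrix."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise InvalidInputError("expected an n x p matrix with p >= 2")
    if np.any(M < 0):
        raise InvalidInputError("closure requires non-negative entries")
    s = M.sum(axis=1, keepdims=True)
    if np.any(s <= 0):
        raise InvalidInputError("closure undefined for all-zero rows")
    return M / s


def check_composition(x) -> np.ndarray:
    """Validate a single composition, re-closing within tolerance.

    Accepts row sums within ``SUM_TOL`` of 1; sums within ``RECLOSE_TOL``
    are silently re-closed (logged); anything further off is rejected.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise InvalidInputError("a composition needs p >= 2 entries")
    if np.any(x < 0):
        raise InvalidInputError("composition entries must be non-negative")
    s = x.sum()
    if abs(s - 1.0) <= SUM_TOL:
        return x
    if abs(s - 1.0) <= RECLOSE_TOL:
        logger.warning("re-closing composition with row sum %.12f", s)
        return x / s
    raise InvalidInputError(f"composition sums to {s!r}, outside tolerance {RECLOSE_TOL}")


@dataclass
class CompositionTable:
    """n samples by p components, each row on the simplex.

    Attributes
    ----------
    values : ndarray, shape (n, p)
    component_labels : list of p unique strings
    sample_ids : list of n strings
    """

    values: np.ndarray
    component_labels: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[1] < 2:
            raise InvalidInputError("expected an n x p matrix with p >= 2")
        if np.any(V < 0):
            raise InvalidInputError("composition entries must be non-negative")
        s = V.sum(axis=1)
        bad = np.abs(s - 1.0) > SUM_TOL
        if np.any(bad):
            far = np.abs(s - 1.0) > RECLOSE_TOL
            if np.any(far):
                i = int(np.argmax(far))
                raise InvalidInputError(
                    f"row {i} sums to {s[i]!r}, outside tolerance {RECLOSE_TOL}"
                )
            logger.warning("re-closing %d rows with sums off by <= %g", int(bad.sum()), RECLOSE_TOL)
            V = V / s[:, None]
        self.values = V
        n, p = V.shape
        if self.component_labels is None:
            self.component_labels = [f"c{j}" for j in range(p)]
        else:
            self.component_labels = [str(l) for l in self.component_labels]
        if len(self.component_labels) != p:
            raise InvalidInputError("component_labels length must equal p")
        if len(set(self.component_labels)) != p:
            raise InvalidInputError("component labels must be unique")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        else:
            self.sample_ids = [str(i) for i in self.sample_ids]
        if len(self.sample_ids) != n:
            raise InvalidInputError("sample_ids length must equal n")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def component_index(self, label: str) -> int:
        try:
            return self.component_labels.index(label)
        except ValueError:
            raise InvalidInputError(f"unknown component label {label!r}") from None

    def subset(self, idx) -> "CompositionTable":
        idx = np.asarray(idx)
        return CompositionTable(
            self.values[idx],
            component_labels=self.component_labels,
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
        )


def as_table(X) -> CompositionTable:
    """Coerce an array or table into a :class:`CompositionTable`."""
    if isinstance(X, CompositionTable):
        return X
    return CompositionTable(np.asarray(X, dtype=float))


def psi_perturb(x, j: int, c: float) -> np.ndarray:
    """Multiply component ``j`` by ``c`` and re-close.

    The closed form is ``result_j = c x_j / (1 + (c-1) x_j)`` and
    ``result_l = x_l / (1 + (c-1) x_j)`` for ``l != j``.
    """
    x = check_composition(x)
    if c < 0:
        raise InvalidInputError("psi perturbation requires c >= 0")
    if c == 0 and x[j] >= 1.0:
        raise DegeneratePerturbationError(
            "cannot zero a component carrying the full mass"
        )
    denom = 1.0 + (c - 1.0) * x[j]
    out = x / denom
    out[j] = c * x[j] / denom
    return out


def phi_perturb(x, j: int, z: float) -> np.ndarray:
    """Pin component ``j`` to ``z`` and rescale the remaining mass."""
    x = check_composition(x)
    if not 0.0 <= z <= 1.0:
        raise InvalidInputError("phi perturbation requires z in [0, 1]")
    if x[j] >= 1.0 and z < 1.0:
        raise DegeneratePerturbationError(
            "remaining components carry no mass to rescale"
        )
    out = x * ((1.0 - z) / (1.0 - x[j])) if z < 1.0 else np.zeros_like(x)
    out[j] = z
    return out


def psi_perturb_rows(X: np.ndarray, j: int, c: float) -> np.ndarray:
    """Vectorized :func:`psi_perturb` over the rows of a matrix.

    Degenerate rows (``x_j == 1`` with ``c == 0``) are the caller's
    responsibility; with ``c > 0`` the formula is defined everywhere.
    """
    if c < 0:
        raise InvalidInputError("psi perturbation requires c >= 0")
    denom = 1.0 + (c - 1.0) * X[:, j]
    out = X / denom[:, None]
    out[:, j] = c * X[:, j] / denom
    return out


def phi_perturb_rows(X: np.ndarray, j: int, z: float) -> np.ndarray:
    """Vectorized :func:`phi_perturb`; rows with ``x_j == 1`` give NaN for z<1."""
    if not 0.0 <= z <= 1.0:
        raise InvalidInputError("phi perturbation requires z in [0, 1]")
    if z == 1.0:
        out = np.zeros_like(X)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = X * ((1.0 - z) / (1.0 - X[:, j]))[:, None]
    out[:, j] = z
    return out


def clr_shift(x, c: float = 0.0) -> np.ndarray:
    """Centered log-ratio transform with an additive zero-shift.

    Computes ``log(x~) - mean(log(x~))`` with ``x~ = closure(x + c)``.
    The output sums to zero.

    Raises
    ------
    ZeroHandlingError
        if ``c == 0`` and ``x`` has zero entries.
    """
    x = check_composition(x)
    return clr_rows(x[None, :], c)[0]


def clr_rows(X: np.ndarray, c: float = 0.0) -> np.ndarray:
    """Row-wise :func:`clr_shift` on an (n, p) matrix."""
    X = np.asarray(X, dtype=float)
    if c < 0:
        raise InvalidInputError("shift c must be non-negative")
    if c == 0 and np.any(X <= 0):
        raise ZeroHandlingError(
            "clr undefined at zero entries; supply a positive shift c"
        )
    Xs = X + c
    Xs = Xs / Xs.sum(axis=1, keepdims=True)
    L = np.log(Xs)
    return L - L.mean(axis=1, keepdims=True)


def barycenter(p: int) -> np.ndarray:
    """The uniform composition (1/p, ..., 1/p)."""
    if p < 2:
        raise InvalidInputError("p must be >= 2")
    return np.full(p, 1.0 / p)
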