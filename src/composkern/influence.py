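"""Compositional feature influence (CFI) and compositional perturbation
dependence (CPD).

CFI of component ``j`` is the empirical mean over samples of the
derivative at ``c = 1`` of ``c -> f(psi_j(x, c))``, estimated by a
central finite difference.  Because the per-sample derivatives
``x_j (d_j f - sum_l x_l d_l f)`` telescope over ``j``, the CFI values
always sum to zero.

CPD of component ``j`` is the curve
``z -> mean_i f(phi_j(x_i, z)) - mean_i f(x_i)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .estimators import DEFAULT_FD_STEP, FittedModel
from .simplex import as_table, phi_perturb_rows, psi_perturb_rows

logger = logging.getLogger(__name__)


@dataclass
class InfluenceResult:
    """Per-component CFI values."""

    cfi: np.ndarray
    component_labels: list[str]
    h: float
    n_used: int


@dataclass
class CPDCurve:
    """CPD curve of a single component."""

    component: str
    grid: np.ndarray
    values: np.ndarray
    baseline: float


def _as_batch_function(f):
    """Normalize a model or callable to a rows -> vector function."""
    if isinstance(f, FittedModel):
        return lambda rows: np.asarray(f(rows), dtype=float).ravel()
    if callable(f):
        def func(rows):
            try:
                out = np.asarray(f(rows), dtype=float)
                if out.shape != (rows.shape[0],):
                    raise ValueError
            except Exception:
                # plain per-sample callable: apply row-wise
                out = np.asarray([float(f(r)) for r in rows])
            return out.ravel()
        return func
    raise InvalidInputError("f must be a FittedModel or a callable")


def cfi(f, X, h: float = DEFAULT_FD_STEP) -> InfluenceResult:
    """Monte-Carlo CFI estimate for every component.

    Samples where the perturbed evaluation is non-finite are dropped
    with a warning; ``n_used`` reports the smallest per-component count
    that entered an average.
    """
    X = as_table(X)
    if X.n == 0:
        raise InvalidInputError("X must be non-empty")
    if not 0 < h < 1:
        raise InvalidInputError("step h must be in (0, 1)")
    func = _as_batch_function(f)
    V = X.values
    values = np.empty(X.p)
    n_used = X.n
    for j in range(X.p):
        fp = func(psi_perturb_rows(V, j, 1.0 + h))
        fm = func(psi_perturb_rows(V, j, 1.0 - h))
        deriv = (fp - fm) / (2.0 * h)
        ok = np.isfinite(deriv)
        if not np.all(ok):
            logger.warning(
                "dropping %d samples with degenerate perturbation for "
                "component %s", int((~ok).sum()), X.component_labels[j],
            )
        if not np.any(ok):
            raise InvalidInputError(
                f"no usable samples for component {X.component_labels[j]}"
            )
        values[j] = deriv[ok].mean()
        n_used = min(n_used, int(ok.sum()))
    return InfluenceResult(cfi=values, component_labels=list(X.component_labels),
                           h=h, n_used=n_used)


def default_cpd_grid(X, j: int, num: int = 25) -> np.ndarray:
    """Grid of 25 points spanning the [5%, 95%] quantile range of X_j.

    Staying inside the observed support avoids extrapolating the fitted
    function where the CPD is not identified.
    """
    X = as_table(X)
    col = X.values[:, j]
    lo, hi = np.quantile(col, [0.05, 0.95])
    lo = max(float(lo), 1e-12)
    hi = min(float(hi), 1.0 - 1e-12)
    if hi <= lo:
        hi = lo + 1e-9
    return np.linspace(lo, hi, num)


def cpd(f, X, j, grid=None) -> CPDCurve:
    """Monte-Carlo CPD curve for component ``j`` (index or label).

    ``S_j(z) = mean_i f(phi_j(x_i, z)) - mean_i f(x_i)``; samples where
    the phi perturbation is degenerate (``x_j = 1`` with ``z < 1``) are
    skipped with a warning.
    """
    X = as_table(X)
    if isinstance(j, str):
        j = X.component_index(j)
    func = _as_batch_function(f)
    if grid is None:
        grid = default_cpd_grid(X, j)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise InvalidInputError("grid must be a non-empty vector")
    if np.any((grid < 0) | (grid > 1)):
        raise InvalidInputError("grid values must lie in [0, 1]")
    if np.any(np.diff(grid) <= 0) and grid.size > 1:
        raise InvalidInputError("grid must be strictly increasing")

    V = X.values
    baseline = float(func(V).mean())
    values = np.empty(grid.size)
    for zi, z in enumerate(grid):
        fz = func(phi_perturb_rows(V, j, z))
        ok = np.isfinite(fz)
        if not np.all(ok):
            logger.warning("dropping %d degenerate samples at z=%g",
                           int((~ok).sum()), z)
        if not np.any(ok):
            raise InvalidInputError(f"no usable samples at z={z}")
        values[zi] = fz[ok].mean() - baseline
    return CPDCurve(component=X.component_labels[j], grid=grid,
                    values=values, baseline=baseline)
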