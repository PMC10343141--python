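"""Kernel PCA with compositionally adjusted component influence, and
kernel-distance scalar summaries.

The PC influence of a component is the CFI of the out-of-sample PC
score function, so "how does multiplying this component up or down move
a sample along this axis" is answered with the same simplex perturbation
used for model interpretation.

``closeness_score`` turns the kernel-induced distance to a reference
point into a scalar ``D(x) = -d_k^2(x, u)``; with the barycenter as
reference this is a data-adaptive alpha-diversity (for the linear
kernel it is the Gini-Simpson index shifted by ``(p-1)/p``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .influence import cfi
from .kernels import GramMatrix, KernelSpec, gram_matrix, psd_clip
from .simplex import CompositionTable, as_table, barycenter, check_composition

#: eigenvalues below this fraction of the largest are treated as null
_EIG_FLOOR_RTOL = 1e-12


@dataclass
class EmbeddingResult:
    """Kernel PCA scores plus everything needed for out-of-sample
    projection of new points."""

    coordinates: np.ndarray          # n x m scores (columns scaled by sqrt(eig))
    eigenvalues: np.ndarray          # m non-negative, non-increasing
    pc_influence: np.ndarray | None  # p x m, filled by pc_influence()
    spec: KernelSpec
    train_X: CompositionTable = field(repr=False)
    _eigvecs: np.ndarray = field(repr=False)       # n x m unit eigenvectors
    _row_means: np.ndarray = field(repr=False)     # column means of training Gram
    _grand_mean: float = field(repr=False)

    @property
    def m(self) -> int:
        return self.eigenvalues.shape[0]

    def score_function(self, m_idx: int):
        """Out-of-sample score function of PC ``m_idx`` (rows -> vector),
        using the standard centered-projection formula with training-set
        centering statistics."""
        lam = self.eigenvalues[m_idx]
        if lam <= 0:
            raise InvalidInputError("score function undefined for a null component")
        v = self._eigvecs[:, m_idx] / np.sqrt(lam)
        train = self.train_X

        def score(rows: np.ndarray) -> np.ndarray:
            rows = np.atleast_2d(np.asarray(rows, dtype=float))
            Kc = gram_matrix(self.spec, train, CompositionTable(
                rows, component_labels=train.component_labels)).values.T  # n_new x n
            Kc = (Kc - self._row_means[None, :]
                  - Kc.mean(axis=1, keepdims=True) + self._grand_mean)
            return Kc @ v

        return score


@dataclass
class SummaryStat:
    """Per-sample closeness values ``-d_k^2(x_i, u)`` to a reference."""

    reference: np.ndarray
    values: np.ndarray
    spec: KernelSpec


def kpca(spec: KernelSpec, X, m: int) -> EmbeddingResult:
    """Kernel PCA: double-center the Gram matrix, eigendecompose, keep
    the top ``m`` components.

    Scores are eigenvectors scaled by the square root of their
    eigenvalue; each column's sign is fixed so its largest-magnitude
    entry is positive.  Requires ``m <= n - 1`` (one direction is lost
    to centering).
    """
    X = as_table(X)
    n = X.n
    if not 1 <= m <= n - 1:
        raise InvalidInputError("require 1 <= m <= n - 1")
    K = gram_matrix(spec, X).values
    if spec.family == "heat-diffusion":
        K = psd_clip(K)
    row_means = K.mean(axis=0)
    grand = float(K.mean())
    Kc = K - row_means[None, :] - row_means[:, None] + grand
    w, V = np.linalg.eigh(Kc)
    order = np.argsort(w)[::-1][:m]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    scores = V * np.sqrt(w)[None, :]
    # sign convention: largest-magnitude entry of each score column positive
    for k in range(m):
        i = int(np.argmax(np.abs(scores[:, k])))
        if scores[i, k] < 0:
            scores[:, k] = -scores[:, k]
            V[:, k] = -V[:, k]
    return EmbeddingResult(
        coordinates=scores, eigenvalues=w, pc_influence=None, spec=spec,
        train_X=X, _eigvecs=V, _row_means=row_means, _grand_mean=grand,
    )


def pc_influence(embedding: EmbeddingResult, X=None, h: float = 1e-4) -> np.ndarray:
    """p x m matrix of CFI values of each PC score function.

    Columns sum to zero by the same telescoping identity as the CFI.
    Null components (zero eigenvalue) get a zero column.
    """
    Xt = embedding.train_X if X is None else as_table(X)
    lam_max = float(embedding.eigenvalues[0]) if embedding.m else 0.0
    cols = []
    for k in range(embedding.m):
        if embedding.eigenvalues[k] <= _EIG_FLOOR_RTOL * max(lam_max, 1e-300):
            cols.append(np.zeros(Xt.p))
            continue
        res = cfi(embedding.score_function(k), Xt, h=h)
        cols.append(res.cfi)
    out = np.column_stack(cols) if cols else np.zeros((Xt.p, 0))
    embedding.pc_influence = out
    return out


def closeness_score(spec: KernelSpec, X, u) -> SummaryStat:
    """``D(x_i) = -d_k^2(x_i, u)`` for every sample."""
    X = as_table(X)
    u = check_composition(u)
    if u.shape[0] != X.p:
        raise InvalidInputError("reference point has wrong dimension")
    U = CompositionTable(u[None, :], component_labels=X.component_labels)
    Kxu = gram_matrix(spec, X, U).values[:, 0]
    Kxx = np.diag(gram_matrix(spec, X).values)
    kuu = gram_matrix(spec, U).values[0, 0]
    d2 = np.clip(Kxx - 2.0 * Kxu + kuu, 0.0, None)
    return SummaryStat(reference=u, values=-d2, spec=spec)


def geometric_median(spec: KernelSpec, X, subset=None) -> int:
    """Index (into ``X``) of the observation with the smallest total
    induced distance to all other observations in ``subset``.

    Ties break to the lowest index.
    """
    X = as_table(X)
    if subset is None:
        subset = np.arange(X.n)
    subset = np.asarray(subset)
    if subset.dtype == bool:
        subset = np.flatnonzero(subset)
    if subset.size == 0:
        raise InvalidInputError("subset must be non-empty")
    K = gram_matrix(spec, X.subset(subset)).values
    diag = np.diag(K)
    d2 = np.clip(diag[:, None] + diag[None, :] - 2.0 * K, 0.0, None)
    totals = np.sqrt(d2).sum(axis=1)
    return int(subset[int(np.argmin(totals))])


def alpha_diversity(spec: KernelSpec, X) -> SummaryStat:
    """Closeness to the barycenter: a data-adaptive alpha-diversity.

    For the linear kernel this equals the Gini-Simpson index
    ``1 - sum_j x_j^2`` minus ``(p-1)/p`` (direct expansion of
    ``-||x - u||^2`` at ``u = (1/p, ..., 1/p)``).
    """
    X = as_table(X)
    return closeness_score(spec, X, barycenter(X.p))
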