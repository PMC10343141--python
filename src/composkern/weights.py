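"""Prior-knowledge weight matrices and their application to kernels.

A weight matrix ``W`` is p x p, symmetric, entrywise non-negative and
positive semi-definite.  ``partition_weights`` builds the block
projector that ties coefficients together within blocks;
``tree_weights`` derives a similarity matrix from patristic distances
on a phylogeny (a Gaussian-of-distance stand-in for UniFrac-style
constructions, with spectral clipping to restore PSD-ness);
``apply_weights`` attaches ``W`` to a kernel spec so Gram computations
use the weighted forms.
"""

from __future__ import annotations

import io as _io
import logging
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import (
    InvalidInputError,
    InvalidPartitionError,
    InvalidTreeError,
    LabelMismatchError,
)
from .kernels import KernelSpec

logger = logging.getLogger(__name__)

#: eigenvalues in [-EIG_CLIP_RTOL * lambda_max, 0) are clipped to 0;
#: anything more negative is a hard error
EIG_CLIP_RTOL = 1e-8


@dataclass
class WeightMatrix:
    """Symmetric, entrywise non-negative, PSD prior-similarity matrix."""

    values: np.ndarray
    component_labels: list[str] | None = field(default=None)

    def __post_init__(self):
        W = np.asarray(self.values, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise InvalidInputError("weight matrix must be square")
        if not np.allclose(W, W.T, atol=1e-10):
            raise InvalidInputError("weight matrix must be symmetric")
        W = 0.5 * (W + W.T)
        if np.any(W < 0):
            raise InvalidInputError("weight matrix entries must be non-negative")
        w, V = np.linalg.eigh(W)
        lam_max = max(float(w[-1]), np.finfo(float).tiny)
        if w[0] < -EIG_CLIP_RTOL * lam_max:
            raise InvalidInputError(
                f"weight matrix is not PSD (min eigenvalue {w[0]:.3e})"
            )
        if w[0] < 0:
            w = np.clip(w, 0.0, None)
            W = (V * w) @ V.T
            W = 0.5 * (W + W.T)
        self.values = W
        if self.component_labels is not None:
            self.component_labels = [str(l) for l in self.component_labels]
            if len(self.component_labels) != W.shape[0]:
                raise InvalidInputError("label count must match matrix dimension")

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class Partition:
    """Disjoint, non-empty blocks covering {0, ..., p-1} (0-based)."""

    blocks: list[list[int]]

    def validate(self, p: int) -> None:
        seen: set[int] = set()
        for block in self.blocks:
            if len(block) == 0:
                raise InvalidPartitionError("empty block in partition")
            bset = set(int(i) for i in block)
            if bset & seen:
                raise InvalidPartitionError("overlapping blocks in partition")
            if not bset <= set(range(p)):
                raise InvalidPartitionError("block index out of range")
            seen |= bset
        if seen != set(range(p)):
            raise InvalidPartitionError("blocks do not cover all components")


def partition_weights(partition: Partition, p: int) -> WeightMatrix:
    """Block weight matrix ``W_ij = sum_l (1/|P_l|) 1{i,j in P_l}``.

    Each block contributes a rank-one projector, so the eigenvalues of
    the result are exactly 0 and 1.
    """
    partition.validate(p)
    W = np.zeros((p, p))
    for block in partition.blocks:
        idx = np.asarray(sorted(int(i) for i in block))
        W[np.ix_(idx, idx)] = 1.0 / len(idx)
    return WeightMatrix(W)


def tree_weights(tree, labels: list[str], bandwidth: float) -> WeightMatrix:
    """Gaussian-of-patristic-distance weights from a Newick tree.

    ``W~_ij = exp(-D_ij / bandwidth)`` with ``D`` the leaf-to-leaf
    patristic distance; negative eigenvalues are clipped to zero and the
    diagonal rescaled to one.  Branch lengths are required.

    Parameters
    ----------
    tree : str or path
        Newick string or path to a Newick file.
    labels : list of str
        Leaf labels, one per component, in component order.
    bandwidth : float
        Positive similarity bandwidth.
    """
    if bandwidth <= 0:
        raise InvalidInputError("bandwidth must be > 0")
    if isinstance(tree, (str, os.PathLike)) and os.path.exists(str(tree)):
        t = dendropy.Tree.get(path=str(tree), schema="newick")
    else:
        t = dendropy.Tree.get(file=_io.StringIO(str(tree)), schema="newick")
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        if edge.length is None:
            raise InvalidTreeError("tree has edges without branch lengths")
    taxa = {taxon.label: taxon for taxon in t.taxon_namespace}
    missing = [l for l in labels if l not in taxa]
    if missing:
        raise LabelMismatchError(f"labels not found as tree leaves: {missing}")
    pdm = t.phylogenetic_distance_matrix()
    p = len(labels)
    D = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    Wt = np.exp(-D / bandwidth)
    w, V = np.linalg.eigh(0.5 * (Wt + Wt.T))
    w = np.clip(w, 0.0, None)
    W = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(W), np.finfo(float).tiny, None))
    W = W / np.outer(d, d)
    W = np.clip(0.5 * (W + W.T), 0.0, None)
    return WeightMatrix(W, component_labels=list(labels))


def apply_weights(spec: KernelSpec, W: WeightMatrix | np.ndarray) -> KernelSpec:
    """Return a weighted copy of ``spec``.

    The weighted evaluations are: ``x^T W y`` (linear),
    ``clr^T W clr`` (aitchison), ``sum_ij W_ij k0(x_i, y_j)`` for the
    componentwise probability kernels, and exponentials of the
    corresponding W-quadratic-form distances for the RBF-type families.
    """
    if isinstance(W, WeightMatrix):
        W = W.values
    else:
        W = WeightMatrix(np.asarray(W, dtype=float)).values  # validate
    return spec.with_weights(W)


def write_weights(path, W: WeightMatrix, sep: str = "\t") -> None:
    """Write a labeled square weight matrix as delimited text."""
    import pandas as pd

    labels = W.component_labels or [f"c{j}" for j in range(W.p)]
    pd.DataFrame(W.values, index=labels, columns=labels).to_csv(path, sep=sep)


def read_weights(path) -> WeightMatrix:
    """Read a labeled square weight matrix from delimited text."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if list(df.index) != list(df.columns):
        raise LabelMismatchError("weight matrix row and column labels differ")
    return WeightMatrix(df.to_numpy(dtype=float), component_labels=list(df.columns))
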