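"""Synthetic compositional data generators.

Covariates are compositional log-normal draws (``closure(exp(Z))`` with
Gaussian ``Z``), optionally sparsified by multinomial resampling at a
finite sequencing depth.  Responses follow log-contrast models
``y = beta^T log(x) + noise`` with ``sum(beta) = 0``, including two
block-structured variants: one where a block weighting is informative
(constant coefficient per designated block) and one where it is
adversarial (+/- split within each block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, ZeroHandlingError
from .simplex import CompositionTable, as_table
from .weights import Partition


@dataclass
class LogContrastModel:
    """Coefficients of ``x -> beta^T log(x)`` with ``sum(beta) = 0``."""

    beta: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if abs(self.beta.sum()) > 1e-9:
            raise InvalidInputError("log-contrast coefficients must sum to 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")

    def __call__(self, X) -> np.ndarray:
        V = X.values if isinstance(X, CompositionTable) else np.atleast_2d(X)
        if np.any(V <= 0):
            raise ZeroHandlingError("log-contrast model undefined at zeros")
        return np.log(V) @ self.beta


@dataclass
class SyntheticDataset:
    """A generated table, response, and the generating truth."""

    X: CompositionTable
    y: np.ndarray
    truth: LogContrastModel
    partition: Partition | None = None
    dgp_tag: str = "example"


def sample_logistic_normal(n: int, p: int, mu=None, sigma=None,
                           seed: int = 0) -> CompositionTable:
    """Draw ``closure(exp(Z))`` rows with ``Z ~ N(mu, sigma)``.

    Defaults: ``mu = 0``, ``sigma = I``.  Rows are strictly positive.
    """
    if n < 1 or p < 2:
        raise InvalidInputError("need n >= 1 and p >= 2")
    mu = np.zeros(p) if mu is None else np.asarray(mu, dtype=float)
    sigma = np.eye(p) if sigma is None else np.asarray(sigma, dtype=float)
    if mu.shape != (p,) or sigma.shape != (p, p):
        raise InvalidInputError("mu must be (p,) and sigma (p, p)")
    eigs = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))
    if eigs[0] < -1e-10 * max(abs(eigs[-1]), 1.0):
        raise InvalidInputError("sigma must be positive semi-definite")
    rng = np.random.default_rng(seed)
    Z = rng.multivariate_normal(mu, sigma, size=n, method="svd")
    E = np.exp(Z)
    return CompositionTable(E / E.sum(axis=1, keepdims=True))


def zero_inflate(X, depth: int, seed: int = 0) -> CompositionTable:
    """Resample each row as ``multinomial(depth, x) / depth``.

    Emulates the sparsity of finite-depth sequencing: rare components
    drop to exact zeros with probability ``(1 - x_j)^depth``.
    """
    X = as_table(X)
    if depth < 1:
        raise InvalidInputError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.stack([rng.multinomial(depth, row / row.sum())
                       for row in X.values])
    return CompositionTable(counts / depth,
                            component_labels=X.component_labels,
                            sample_ids=X.sample_ids)


def logcontrast_response(X, model: LogContrastModel, seed: int = 0) -> np.ndarray:
    """``y_i = beta^T log(x_i) + N(0, noise_sd^2)`` noise."""
    X = as_table(X)
    if np.any(X.values <= 0):
        raise ZeroHandlingError(
            "log-contrast response requires strictly positive compositions"
        )
    rng = np.random.default_rng(seed)
    y = model(X)
    if model.noise_sd > 0:
        y = y + rng.normal(0.0, model.noise_sd, size=X.n)
    return y


def block_dgp(X, partition: Partition, beta_B: float, beta_P: float,
              variant: str = "dgp1", noise_sd: float = 0.5,
              seed: int = 0) -> SyntheticDataset:
    """Block-structured log-contrast response on given covariates.

    The first two blocks of ``partition`` are the designated blocks with
    base coefficients ``beta_B`` and ``beta_P``; all other components
    get 0.  Variant ``dgp1`` assigns the constant block coefficient
    (a matching block weighting is informative); ``dgp2`` splits each
    designated block into a -/+ half (the block weighting is
    adversarial).  The final beta is re-centered to sum to zero.
    """
    X = as_table(X)
    partition.validate(X.p)
    if len(partition.blocks) < 2:
        raise InvalidInputError("need at least two blocks (two designated)")
    if variant not in ("dgp1", "dgp2"):
        raise InvalidInputError("variant must be 'dgp1' or 'dgp2'")
    beta = np.zeros(X.p)
    for block, base in zip(partition.blocks[:2], (beta_B, beta_P)):
        idx = np.asarray(sorted(int(i) for i in block))
        if variant == "dgp1":
            beta[idx] = base
        else:
            if idx.size < 2:
                raise InvalidInputError("dgp2 requires designated blocks of size >= 2")
            half = idx.size // 2
            beta[idx[:half]] = -base
            beta[idx[half:]] = base
    beta = beta - beta.mean()
    truth = LogContrastModel(beta=beta, noise_sd=noise_sd)
    y = logcontrast_response(X, truth, seed=seed)
    return SyntheticDataset(X=X, y=y, truth=truth, partition=partition,
                            dgp_tag=variant)


def example_logcontrast(p: int = 4) -> LogContrastModel:
    """The running 4-component example: ``beta = (2, -1, -1, 0, ...)``."""
    if p < 4:
        raise InvalidInputError("need p >= 4")
    beta = np.zeros(p)
    beta[:3] = (2.0, -1.0, -1.0)
    return LogContrastModel(beta=beta, noise_sd=1.0)
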