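"""Kernels on the simplex, Gram matrices, induced distances and the
default kernel grid.

Families
--------
``linear``, ``rbf``
    Euclidean kernels restricted to the simplex.
``aitchison``, ``aitchison-rbf``
    Linear/RBF kernels in centered log-ratio coordinates with a
    zero-shift hyperparameter ``c``.
``prob-js``, ``prob-hellinger``, ``prob-tv``, ``prob-chisq``
    Kernels built from squared distances between discrete probability
    distributions via the anchored construction
    ``k(x, y) = (delta(x, u0) + delta(y, u0) - delta(x, y)) / 2``
    with the barycenter as anchor ``u0``.  Because each squared distance
    is conditionally negative definite, the result is positive
    semi-definite and, since every ``delta`` decomposes as a sum over
    components, the kernels admit the entrywise weighting of
    :func:`composkern.weights.apply_weights`.
``heat-diffusion``
    Gaussian of the spherical geodesic ``2 arccos(sum_j sqrt(x_j y_j))``
    with diffusion time ``t``; only approximately positive definite, so
    square Gram matrices are spectrally repaired before entering solvers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvalidInputError, ZeroHandlingError
from .simplex import CompositionTable, as_table, barycenter, check_composition, clr_rows

logger = logging.getLogger(__name__)

FAMILIES = (
    "linear",
    "rbf",
    "aitchison",
    "aitchison-rbf",
    "prob-js",
    "prob-hellinger",
    "prob-tv",
    "prob-chisq",
    "heat-diffusion",
)

PROB_FAMILIES = ("prob-js", "prob-hellinger", "prob-tv", "prob-chisq")

#: relative eigenvalue tolerance for "numerically PSD"
PSD_RTOL = 1e-8


@dataclass
class KernelSpec:
    """A kernel family plus the parameters that fully determine it.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    g : float, optional
        Bandwidth for ``rbf`` / ``aitchison-rbf`` (required, > 0).
    c : float, optional
        Zero-shift for ``aitchison`` / ``aitchison-rbf`` (required, >= 0).
    t : float, optional
        Diffusion time for ``heat-diffusion`` (required, > 0).
    scale : float, optional
        Positive multiplier of the squared distance for the probability
        families (defaults to 1).
    weights : ndarray, optional
        p x p entrywise non-negative PSD weight matrix; see
        :func:`composkern.weights.apply_weights`.
    """

    family: str
    g: float | None = None
    c: float | None = None
    t: float | None = None
    scale: float | None = None
    weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidInputError(f"unknown kernel family {self.family!r}")
        if self.family in ("rbf", "aitchison-rbf"):
            if self.g is None or self.g <= 0:
                raise InvalidInputError(f"{self.family} requires bandwidth g > 0")
        elif self.g is not None:
            raise InvalidInputError(f"{self.family} takes no bandwidth g")
        if self.family in ("aitchison", "aitchison-rbf"):
            if self.c is None or self.c < 0:
                raise InvalidInputError(f"{self.family} requires shift c >= 0")
        elif self.c is not None:
            raise InvalidInputError(f"{self.family} takes no shift c")
        if self.family == "heat-diffusion":
            if self.t is None or self.t <= 0:
                raise InvalidInputError("heat-diffusion requires diffusion time t > 0")
        elif self.t is not None:
            raise InvalidInputError(f"{self.family} takes no diffusion time t")
        if self.family in PROB_FAMILIES:
            if self.scale is None:
                self.scale = 1.0
            if self.scale <= 0:
                raise InvalidInputError("scale must be > 0")
        elif self.scale is not None:
            raise InvalidInputError(f"{self.family} takes no scale")
        if self.weights is not None:
            W = np.asarray(self.weights, dtype=float)
            if W.ndim != 2 or W.shape[0] != W.shape[1]:
                raise InvalidInputError("weights must be a square matrix")
            self.weights = W

    @property
    def name(self) -> str:
        """Compact human-readable identifier, used in CV tables."""
        parts = []
        for key in ("g", "c", "t", "scale"):
            v = getattr(self, key)
            if v is not None and not (key == "scale" and v == 1.0):
                parts.append(f"{key}={v:.6g}")
        tag = "" if self.weights is None else ",weighted"
        inner = ",".join(parts)
        return f"{self.family}({inner}{tag})" if (inner or tag) else self.family

    def with_weights(self, W: np.ndarray) -> "KernelSpec":
        return replace(self, weights=np.asarray(W, dtype=float))

    def to_dict(self) -> dict:
        d = {"family": self.family}
        for key in ("g", "c", "t", "scale"):
            v = getattr(self, key)
            if v is not None:
                d[key] = float(v)
        if self.weights is not None:
            d["weights"] = self.weights.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        d = dict(d)
        w = d.pop("weights", None)
        spec = cls(**d)
        if w is not None:
            spec = spec.with_weights(np.asarray(w, dtype=float))
        return spec


@dataclass
class GramMatrix:
    """Matrix of pairwise kernel evaluations together with its spec."""

    values: np.ndarray
    spec: KernelSpec


# ---------------------------------------------------------------------------
# squared distances between discrete distributions (all decompose over
# components, which the weighted variants rely on)
# ---------------------------------------------------------------------------


def _xlogx_ratio(a, m):
    """a * log(a / m) with the 0 log 0 = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = a * (np.log(a) - np.log(m))
    return np.where(a > 0, out, 0.0)


def _delta_pairwise(family: str, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """n x m matrix of squared distances delta(x_i, y_j)."""
    if family == "prob-hellinger":
        return cdist(np.sqrt(X), np.sqrt(Y), metric="sqeuclidean")
    if family == "prob-tv":
        return 0.5 * cdist(X, Y, metric="cityblock")
    if family == "prob-chisq":
        d = X[:, None, :] - Y[None, :, :]
        s = X[:, None, :] + Y[None, :, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = d * d / s
        return np.where(s > 0, terms, 0.0).sum(axis=2)
    if family == "prob-js":
        m = 0.5 * (X[:, None, :] + Y[None, :, :])
        terms = _xlogx_ratio(X[:, None, :], m) + _xlogx_ratio(Y[None, :, :], m)
        return 0.5 * terms.sum(axis=2)
    raise InvalidInputError(f"not a probability family: {family!r}")


def _delta0_elementwise(family: str, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Componentwise squared-distance term delta0(a, b), broadcasting."""
    if family == "prob-hellinger":
        d = np.sqrt(A) - np.sqrt(B)
        return d * d
    if family == "prob-tv":
        return 0.5 * np.abs(A - B)
    if family == "prob-chisq":
        s = A + B
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (A - B) ** 2 / s
        return np.where(s > 0, out, 0.0)
    if family == "prob-js":
        m = 0.5 * (A + B)
        return 0.5 * (_xlogx_ratio(A, m) + _xlogx_ratio(B, m))
    raise InvalidInputError(f"not a probability family: {family!r}")


# ---------------------------------------------------------------------------
# Gram computation
# ---------------------------------------------------------------------------


def _quad_form_dist2(X: np.ndarray, Y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """(x - y)^T W (x - y) for all row pairs."""
    XW = X @ W
    YW = Y @ W
    qx = np.einsum("ij,ij->i", XW, X)
    qy = np.einsum("ij,ij->i", YW, Y)
    return qx[:, None] + qy[None, :] - 2.0 * (XW @ Y.T)


def _gram_values(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    p = X.shape[1]
    W = spec.weights
    if W is not None and W.shape[0] != p:
        raise InvalidInputError(
            f"weight matrix is {W.shape[0]}x{W.shape[0]} but data has p={p}"
        )
    fam = spec.family

    if fam == "linear":
        return X @ Y.T if W is None else X @ W @ Y.T

    if fam == "rbf":
        d2 = cdist(X, Y, "sqeuclidean") if W is None else _quad_form_dist2(X, Y, W)
        return np.exp(-spec.g * d2)

    if fam in ("aitchison", "aitchison-rbf"):
        CX = clr_rows(X, spec.c)
        CY = clr_rows(Y, spec.c)
        if fam == "aitchison":
            return CX @ CY.T if W is None else CX @ W @ CY.T
        d2 = cdist(CX, CY, "sqeuclidean") if W is None else _quad_form_dist2(CX, CY, W)
        return np.exp(-spec.g * d2)

    if fam == "heat-diffusion":
        SX, SY = np.sqrt(X), np.sqrt(Y)
        inner = SX @ SY.T if W is None else SX @ W @ SY.T
        d = 2.0 * np.arccos(np.clip(inner, -1.0, 1.0))
        return np.exp(-(d * d) / (4.0 * spec.t))

    if fam in PROB_FAMILIES:
        u0 = barycenter(p)
        if W is None:
            du_x = _delta_pairwise(fam, X, u0[None, :])[:, 0]
            du_y = _delta_pairwise(fam, Y, u0[None, :])[:, 0]
            dxy = _delta_pairwise(fam, X, Y)
            K = 0.5 * (du_x[:, None] + du_y[None, :] - dxy)
        else:
            # k_W(x, y) = sum_ij W_ij k0(x_i, y_j) with the componentwise
            # anchored kernel k0(a, b) = (d0(a,u) + d0(b,u) - d0(a,b)) / 2
            s = W.sum(axis=1)  # symmetric W: row sums = column sums
            d0x = _delta0_elementwise(fam, X, u0[None, :])  # n x p
            d0y = _delta0_elementwise(fam, Y, u0[None, :])  # m x p
            ax = d0x @ s
            ay = d0y @ s
            cross = np.empty((X.shape[0], Y.shape[0]))
            for i in range(X.shape[0]):
                # d0(x_a, y_jb): p x m x p tensor contracted against W
                T = _delta0_elementwise(fam, X[i][:, None, None], Y[None, :, :])
                cross[i] = np.einsum("ab,ajb->j", W, T)
            K = 0.5 * (ax[:, None] + ay[None, :] - cross)
        return spec.scale * K

    raise InvalidInputError(f"unknown kernel family {fam!r}")


def gram_matrix(spec: KernelSpec, A, B=None) -> GramMatrix:
    """Pairwise kernel evaluations between the rows of ``A`` and ``B``.

    ``B`` absent gives the symmetric square Gram of ``A``.
    """
    A = as_table(A)
    if B is None:
        V = _gram_values(spec, A.values, A.values)
        V = 0.5 * (V + V.T)  # enforce exact symmetry
        return GramMatrix(V, spec)
    B = as_table(B)
    if A.p != B.p:
        raise InvalidInputError("tables have different numbers of components")
    return GramMatrix(_gram_values(spec, A.values, B.values), spec)


def kernel_eval(spec: KernelSpec, x, y) -> float:
    """Evaluate ``k(x, y)`` for two compositions."""
    x = check_composition(x)
    y = check_composition(y)
    if x.shape[0] != y.shape[0]:
        raise InvalidInputError("compositions have different lengths")
    if spec.family in ("aitchison", "aitchison-rbf") and spec.c == 0:
        if np.any(x == 0) or np.any(y == 0):
            raise ZeroHandlingError(
                "aitchison kernel with c=0 undefined on zero entries"
            )
    return float(_gram_values(spec, x[None, :], y[None, :])[0, 0])


def induced_distance(spec: KernelSpec, x, y) -> float:
    """Semi-metric induced by the kernel:
    ``sqrt(max(0, k(x,x) - 2 k(x,y) + k(y,y)))``."""
    kxx = kernel_eval(spec, x, x)
    kyy = kernel_eval(spec, y, y)
    kxy = kernel_eval(spec, x, y)
    return float(np.sqrt(max(0.0, kxx - 2.0 * kxy + kyy)))


def induced_distance_matrix(spec: KernelSpec, A, B=None) -> np.ndarray:
    """Pairwise induced distances between rows of ``A`` (and ``B``)."""
    A = as_table(A)
    Bt = A if B is None else as_table(B)
    Kab = gram_matrix(spec, A, Bt).values
    ka = np.diag(gram_matrix(spec, A).values) if B is not None else np.diag(Kab)
    kb = np.diag(gram_matrix(spec, Bt).values) if B is not None else ka
    d2 = ka[:, None] + kb[None, :] - 2.0 * Kab
    return np.sqrt(np.clip(d2, 0.0, None))


def psd_clip(K: np.ndarray, warn: bool = True) -> np.ndarray:
    """Spectrally repair a symmetric matrix by clipping negative
    eigenvalues at zero.  Used for the heat-diffusion family before
    Gram matrices enter solvers."""
    K = 0.5 * (K + K.T)
    w, V = np.linalg.eigh(K)
    if w[0] >= 0:
        return K
    if warn:
        logger.warning(
            "clipping %d negative eigenvalues (min %.3e) to repair Gram matrix",
            int((w < 0).sum()), float(w[0]),
        )
    w = np.clip(w, 0.0, None)
    R = (V * w) @ V.T
    return 0.5 * (R + R.T)


def is_psd(K: np.ndarray, rtol: float = PSD_RTOL) -> bool:
    """Numerical PSD check: min eigenvalue >= -rtol * max eigenvalue."""
    w = np.linalg.eigvalsh(0.5 * (K + K.T))
    return bool(w[0] >= -rtol * max(w[-1], np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# default grid
# ---------------------------------------------------------------------------


def median_heuristic(X: np.ndarray, max_rows: int = 500) -> float:
    """1 / median squared Euclidean distance between distinct rows.

    Deterministic: uses the first ``max_rows`` rows when n is large.
    """
    X = np.asarray(X, dtype=float)[:max_rows]
    d2 = cdist(X, X, "sqeuclidean")
    vals = d2[np.triu_indices_from(d2, k=1)]
    vals = vals[vals > 0]
    med = np.median(vals) if vals.size else 1.0
    return 1.0 / max(med, np.finfo(float).tiny)


def default_kernel_grid(X) -> list[KernelSpec]:
    """The 55-kernel default grid, with data-adaptive parameters.

    Composition: linear x1, rbf x5 (median-heuristic bandwidth scaled by
    5 factors), aitchison x5 (shifts at half the minimum non-zero
    abundance times 10^{-2..2}), aitchison-rbf x20 (5 shifts x 4
    clr-median-heuristic bandwidth factors), probability kernels x12
    (4 families x 3 scalings), heat-diffusion x12 (t log-spaced
    10^-2..10^1).  Deterministic given ``X``.
    """
    X = as_table(X)
    V = X.values
    specs: list[KernelSpec] = [KernelSpec("linear")]

    g0 = median_heuristic(V)
    specs += [KernelSpec("rbf", g=g0 * f) for f in (0.01, 0.1, 1.0, 10.0, 100.0)]

    nonzero = V[V > 0]
    c0 = 0.5 * float(nonzero.min()) if nonzero.size else 0.5
    shifts = [c0 * f for f in (1e-2, 1e-1, 1.0, 1e1, 1e2)]
    specs += [KernelSpec("aitchison", c=c) for c in shifts]

    for c in shifts:
        gc = median_heuristic(clr_rows(V, c))
        specs += [KernelSpec("aitchison-rbf", c=c, g=gc * f) for f in (0.1, 1.0, 10.0, 100.0)]

    for fam in PROB_FAMILIES:
        specs += [KernelSpec(fam, scale=s) for s in (0.5, 1.0, 2.0)]

    specs += [KernelSpec("heat-diffusion", t=t) for t in np.logspace(-2, 1, 12)]

    assert len(specs) == 55
    return specs
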