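"""Kernel evaluation and Gram-matrix handling.

Kernel PLS never touches the p-dimensional feature space directly: every
operation is phrased through the n x n Gram matrix ``K[i, j] = k(x_i, x_j)``,
so the cost of component extraction is independent of the number of genes.
This module builds the Gram matrix for the supported kernels and centers it
in feature space (the kernel analogue of column-centering the data matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import pairwise_kernels

__all__ = [
    "KernelSpec",
    "GramMatrix",
    "default_rbf_gamma",
    "compute_gram",
    "center_gram",
]

_VALID_KERNELS = ("linear", "rbf", "polynomial")


@dataclass(frozen=True)
class KernelSpec:
    """Choice of kernel function and its parameters.

    Parameters
    ----------
    name : {"linear", "rbf", "polynomial"}
        Kernel family.
    gamma : float, optional
        RBF width ``k(x, z) = exp(-gamma * ||x - z||^2)``.  If ``None`` the
        scale-free default ``1 / (p * var(X))`` is used at Gram time, where
        ``var`` is the overall element variance of the data matrix.
    degree : int
        Polynomial degree (polynomial kernel only).
    coef0 : float
        Additive constant of the polynomial kernel ``(x.z + coef0)^degree``.
    """

    name: str = "rbf"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in _VALID_KERNELS:
            raise ValueError(
                f"unknown kernel {self.name!r}; expected one of {_VALID_KERNELS}"
            )
        if self.gamma is not None and not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if self.name == "polynomial" and (
            int(self.degree) != self.degree or self.degree < 1
        ):
            raise ValueError("degree must be a positive integer")


@dataclass
class GramMatrix:
    """An n x n symmetric PSD kernel matrix with its centering state."""

    values: np.ndarray
    centered: bool = False
    spec: KernelSpec | None = field(default=None, compare=False)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, *, sym_tol: float = 1e-12, psd_tol: float = 1e-8) -> None:
        """Check symmetry and positive semi-definiteness within tolerance."""
        K = self.values
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError(f"Gram matrix must be square, got shape {K.shape}")
        scale = max(1.0, float(np.abs(K).max()))
        if np.abs(K - K.T).max() > sym_tol * scale:
            raise ValueError("Gram matrix is not symmetric")
        w = np.linalg.eigvalsh((K + K.T) / 2.0)
        if w[0] < -psd_tol * max(w[-1], 1e-300):
            raise ValueError(
                f"Gram matrix is not positive semi-definite "
                f"(min eigenvalue {w[0]:.3e}, max {w[-1]:.3e})"
            )


def default_rbf_gamma(X: np.ndarray) -> float:
    """Scale-free RBF width ``1 / (p * var(X))`` over all matrix elements."""
    X = np.asarray(X, dtype=float)
    v = float(X.var())
    if v <= 0:
        # constant matrix: any gamma gives K = all-ones; pick 1/p
        return 1.0 / X.shape[1]
    return 1.0 / (X.shape[1] * v)


def _validate_X(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D samples x genes matrix, got ndim={X.ndim}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to form a Gram matrix")
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(
            f"expression matrix contains a missing or non-finite value at "
            f"sample row {bad[0]}, gene column {bad[1]}; impute upstream"
        )
    return X


def compute_gram(X: np.ndarray, spec: KernelSpec) -> GramMatrix:
    """Evaluate ``K[i, j] = k(x_i, x_j)`` for all sample pairs.

    The result is uncentered; call :func:`center_gram` before component
    extraction.  The matrix is symmetrized to remove floating-point drift.
    """
    X = _validate_X(X)
    if spec.name == "linear":
        K = pairwise_kernels(X, metric="linear")
    elif spec.name == "rbf":
        gamma = spec.gamma if spec.gamma is not None else default_rbf_gamma(X)
        K = pairwise_kernels(X, metric="rbf", gamma=gamma)
    else:
        K = pairwise_kernels(
            X,
            metric="polynomial",
            degree=int(spec.degree),
            coef0=spec.coef0,
            gamma=1.0,
        )
    if not np.isfinite(K).all():
        raise ValueError("kernel evaluation produced a non-finite value")
    K = (K + K.T) / 2.0
    return GramMatrix(values=K, centered=False, spec=spec)


def center_gram(K: GramMatrix | np.ndarray) -> GramMatrix:
    """Center the Gram matrix in feature space.

    Applies the double projection ``(I - 11'/n) K (I - 11'/n)``, equivalent to
    subtracting the feature-space mean from every mapped sample.  Idempotent;
    preserves symmetry and positive semi-definiteness.
    """
    if isinstance(K, GramMatrix):
        spec = K.spec
        K = K.values
    else:
        spec = None
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    row_means = K.mean(axis=1, keepdims=True)
    col_means = K.mean(axis=0, keepdims=True)
    Kc = K - row_means - col_means + K.mean()
    Kc = (Kc + Kc.T) / 2.0
    return GramMatrix(values=Kc, centered=True, spec=spec)
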