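"""Kernel PLS component extraction with self-adaptive component counting.

Classification is posed as multivariate regression of a column-centered
one-hot indicator matrix Y (n x c) on the kernel matrix.  Each component is
a unit score vector t extracted by the kernel NIPALS inner iteration

    t <- K u / ||K u||,    c <- Y' t,    u <- Y c / ||Y c||,

whose fixed point makes t the dominant eigenvector of ``K Y Y'``.  After a
component is extracted, both working matrices are deflated by the projector
``I - t t'`` so successive score vectors are mutually orthogonal.

Each component h carries two diagnostics:

* ``rd`` — mean squared Pearson correlation between t_h and the columns of
  the *original* indicator matrix (its share of class variation explained);
  these weight the per-gene importance scores downstream.
* ``fisher_j`` — the kernel Fisher-discriminant ratio of the scores
  (between-class over within-class scatter), used by the self-adaptive
  stopping rule: extraction stops at the first component whose ratio falls
  below ``lambda_rel`` times the largest finite ratio seen so far.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .kernels import GramMatrix, KernelSpec, center_gram, compute_gram

__all__ = [
    "IndicatorMatrix",
    "Component",
    "ComponentSet",
    "KplsConfig",
    "SignalExhausted",
    "encode_labels",
    "extract_component",
    "deflate",
    "rd_contribution",
    "fisher_ratio",
    "fit_components",
    "KernelPLS",
]


class SignalExhausted(Exception):
    """Raised when the residual response (or kernel) carries no signal left."""


@dataclass
class IndicatorMatrix:
    """Column-centered one-hot response matrix for c classes."""

    values: np.ndarray  # n x c, columns sum to zero
    classes: list  # class labels in first-appearance order
    counts: np.ndarray  # per-class sample counts

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class Component:
    """One extracted kernel-PLS component."""

    t: np.ndarray  # unit score vector, length n
    u_dual: np.ndarray  # dual direction over samples, length n
    index: int  # 1-based extraction order
    rd: float = 0.0  # share of Y variation explained, in [0, 1]
    fisher_j: float = 0.0  # kernel FLDA ratio, >= 0 or +inf
    n_iter: int = 0
    converged: bool = True


@dataclass
class ComponentSet:
    """Retained components plus the reason extraction stopped."""

    components: list[Component] = field(default_factory=list)
    stopping_reason: str = "max_components"  # threshold | max_components | y_exhausted

    @property
    def kappa(self) -> int:
        return len(self.components)

    def scores(self) -> np.ndarray:
        """n x kappa matrix of score vectors."""
        return np.column_stack([c.t for c in self.components])

    def rd(self) -> np.ndarray:
        return np.array([c.rd for c in self.components])

    def fisher(self) -> np.ndarray:
        return np.array([c.fisher_j for c in self.components])


@dataclass(frozen=True)
class KplsConfig:
    """Extraction hyper-parameters.

    ``lambda_rel`` is the relative Fisher-ratio stopping threshold: component
    h > 1 is retained only while J_h >= lambda_rel * J*, with J* the largest
    finite ratio observed so far.  ``max_components`` is a hard cap, clipped
    to n - 1 at fit time.
    """

    max_components: int = 10
    lambda_rel: float = 0.05
    inner_tol: float = 1e-10
    inner_max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_components < 1:
            raise ValueError("max_components must be a positive integer")
        if not self.lambda_rel > 0:
            raise ValueError("lambda_rel must be positive")
        if not self.inner_tol > 0:
            raise ValueError("inner_tol must be positive")
        if self.inner_max_iter < 1:
            raise ValueError("inner_max_iter must be a positive integer")


def encode_labels(labels) -> IndicatorMatrix:
    """One-hot encode class labels and center each column to mean zero.

    Class order is first-appearance order.  Rejects degenerate designs: a
    single class, or any class with fewer than 2 samples (the within-class
    scatter of the Fisher ratio would be undefined).
    """
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-D array")
    n = labels.shape[0]
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 distinct classes")
    counts = np.array([int(np.sum(labels == c)) for c in classes])
    if counts.min() < 2:
        bad = classes[int(np.argmin(counts))]
        raise ValueError(
            f"class {bad!r} has fewer than 2 samples; "
            "within-class scatter is undefined"
        )
    Y = np.zeros((n, len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    Y -= Y.mean(axis=0, keepdims=True)
    return IndicatorMatrix(values=Y, classes=classes, counts=counts)


def extract_component(
    K_h: GramMatrix | np.ndarray,
    Y_h: np.ndarray,
    cfg: KplsConfig = KplsConfig(),
    index: int = 1,
) -> Component:
    """Extract one component from the residual kernel and response matrices.

    Runs the kernel NIPALS inner iteration until the score vector moves by
    less than ``cfg.inner_tol`` between passes.  The sign is fixed so that
    the entry of ``Y_h' t`` largest in magnitude is positive.

    Raises
    ------
    SignalExhausted
        If ``Y_h`` (or the image ``K_h u``) is numerically zero, i.e. the
        residuals carry no extractable signal.
    """
    K = K_h.values if isinstance(K_h, GramMatrix) else np.asarray(K_h, dtype=float)
    Y = np.asarray(Y_h, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if np.linalg.norm(Y) < 1e-12:
        raise SignalExhausted("response residual is numerically zero")

    # start from the strongest remaining response column
    col = int(np.argmax(np.linalg.norm(Y, axis=0)))
    u = Y[:, col].copy()
    u /= np.linalg.norm(u)

    t_old = np.zeros(K.shape[0])
    t = t_old
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.inner_max_iter + 1):
        t = K @ u
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            raise SignalExhausted("kernel residual annihilates the direction")
        t /= nt
        c = Y.T @ t
        u = Y @ c
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            raise SignalExhausted("response residual annihilates the score")
        u /= nu
        if np.linalg.norm(t - t_old) < cfg.inner_tol:
            converged = True
            break
        t_old = t
    if not converged:
        warnings.warn(
            f"kernel NIPALS inner loop did not converge in "
            f"{cfg.inner_max_iter} iterations (component {index})",
            RuntimeWarning,
            stacklevel=2,
        )

    # deterministic sign: largest-magnitude response coefficient positive
    c = Y.T @ t
    i_star = int(np.argmax(np.abs(c)))
    if c[i_star] < 0:
        t = -t
        u = -u
    return Component(t=t, u_dual=u, index=index, n_iter=n_iter, converged=converged)


def deflate(
    K_h: GramMatrix | np.ndarray, Y_h: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the component t from the working matrices.

    ``Y <- Y - t t' Y`` and ``K <- (I - t t') K (I - t t')``.  Afterwards t
    is orthogonal to the response residual and lies in the null space of the
    deflated kernel, which is what makes successive scores orthogonal.
    """
    K = K_h.values if isinstance(K_h, GramMatrix) else np.asarray(K_h, dtype=float)
    Y = np.asarray(Y_h, dtype=float)
    t = np.asarray(t, dtype=float)
    Y_next = Y - np.outer(t, t @ Y)
    Kt = K @ t
    K_next = K - np.outer(t, Kt) - np.outer(Kt, t) + np.outer(t, t) * float(t @ Kt)
    K_next = (K_next + K_next.T) / 2.0
    return K_next, Y_next


def rd_contribution(t: np.ndarray, Y: np.ndarray) -> float:
    """Variation of the response explained by one component.

    Mean of the squared Pearson correlations between t and each column of
    the original centered indicator matrix; in [0, 1].  Zero-variance
    columns contribute 0.
    """
    t = np.asarray(t, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    tc = t - t.mean()
    st = np.linalg.norm(tc)
    if st < 1e-15:
        warnings.warn("zero-variance score vector; Rd set to 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    total = 0.0
    for m in range(Y.shape[1]):
        yc = Y[:, m] - Y[:, m].mean()
        sy = np.linalg.norm(yc)
        if sy < 1e-15:
            continue
        r = float(tc @ yc) / (st * sy)
        total += r * r
    return total / Y.shape[1]


def fisher_ratio(t: np.ndarray, labels) -> float:
    """Kernel Fisher-discriminant ratio of the component scores.

    Between-class scatter ``sum_i n_i (m_i - m)^2`` over within-class scatter
    ``sum_i sum_{j in i} (t_j - m_i)^2`` of the projected scores.  Perfect
    separation (zero within-class scatter with positive between-class
    scatter) returns ``+inf``.
    """
    t = np.asarray(t, dtype=float)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    m = t.mean()
    between = 0.0
    within = 0.0
    for c in classes:
        tc = t[labels == c]
        mi = tc.mean()
        between += tc.size * (mi - m) ** 2
        within += float(((tc - mi) ** 2).sum())
    if within < 1e-12:
        return np.inf if between > 0 else 0.0
    return between / within


def fit_components(
    X: np.ndarray,
    labels,
    kernel_spec: KernelSpec = KernelSpec(),
    cfg: KplsConfig = KplsConfig(),
) -> tuple[ComponentSet, IndicatorMatrix, GramMatrix]:
    """Run the full self-adaptive extraction loop.

    Centers the Gram matrix, encodes the labels, then alternates extraction
    and deflation.  Component 1 is always retained; component h > 1 is
    retained while its Fisher ratio stays above ``lambda_rel`` times the
    largest finite ratio seen so far (infinite ratios — perfect separation —
    are always retained and never trigger stopping).  Stops at the first
    rejected component, at the component cap, or when the response residual
    is exhausted.

    Returns the retained components, the indicator matrix, and the centered
    Gram matrix.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need a 2-D matrix with at least 4 samples")
    indicator = encode_labels(labels)
    labels = np.asarray(labels)
    gram = center_gram(compute_gram(X, kernel_spec))

    n = X.shape[0]
    max_comp = min(cfg.max_components, n - 1)
    Y0 = indicator.values
    K_h, Y_h = gram.values, Y0.copy()

    cset = ComponentSet(stopping_reason="max_components")
    j_star: float | None = None  # largest finite Fisher ratio seen
    for h in range(1, max_comp + 1):
        try:
            comp = extract_component(K_h, Y_h, cfg, index=h)
        except SignalExhausted:
            cset.stopping_reason = "y_exhausted"
            break
        comp.rd = rd_contribution(comp.t, Y0)
        comp.fisher_j = fisher_ratio(comp.t, labels)

        if h > 1:
            j = comp.fisher_j
            reject = (
                np.isfinite(j)
                and j_star is not None
                and j < cfg.lambda_rel * j_star
            )
            if reject:
                cset.stopping_reason = "threshold"
                break
        cset.components.append(comp)
        if np.isfinite(comp.fisher_j):
            j_star = (
                comp.fisher_j if j_star is None else max(j_star, comp.fisher_j)
            )
        K_h, Y_h = deflate(K_h, Y_h, comp.t)
        if np.linalg.norm(Y_h) < 1e-12:
            cset.stopping_reason = "y_exhausted"
            break

    if not cset.components:  # unreachable for valid labels; defensive
        raise RuntimeError("no component could be extracted")
    return cset, indicator, gram


class KernelPLS(BaseEstimator):
    """Kernel partial least squares for class-labelled expression data.

    Extracts orthonormal per-sample score vectors from a centered Gram
    matrix, deflating after each component, and chooses the number of
    components self-adaptively from the kernel Fisher-discriminant ratio of
    the scores.

    Parameters
    ----------
    kernel : {"linear", "rbf", "polynomial"}, default "rbf"
    gamma : float or None
        RBF width; ``None`` selects ``1 / (p * var(X))``.
    degree, coef0 : polynomial-kernel parameters.
    max_components : int, default 10
        Hard cap on extracted components (also capped at n - 1).
    lambda_rel : float, default 0.05
        Relative Fisher-ratio stopping threshold.
    inner_tol, inner_max_iter : inner NIPALS loop controls.
    seed : int
        Recorded for provenance; extraction itself is deterministic.

    Attributes
    ----------
    scores_ : ndarray of shape (n, kappa)
        Orthonormal component score vectors.
    dual_coefs_ : ndarray of shape (n, kappa)
        Dual directions u_h over samples.
    rd_ : ndarray of shape (kappa,)
        Per-component share of class variation explained.
    fisher_j_ : ndarray of shape (kappa,)
        Per-component Fisher ratios.
    n_components_ : int
        Retained component count kappa.
    stopping_reason_ : str
        One of "threshold", "max_components", "y_exhausted".
    classes_ : list
        Class labels in first-appearance order.
    """

    def __init__(
        self,
        kernel: str = "rbf",
        gamma: float | None = None,
        degree: int = 3,
        coef0: float = 1.0,
        max_components: int = 10,
        lambda_rel: float = 0.05,
        inner_tol: float = 1e-10,
        inner_max_iter: int = 500,
        seed: int = 0,
    ):
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.max_components = max_components
        self.lambda_rel = lambda_rel
        self.inner_tol = inner_tol
        self.inner_max_iter = inner_max_iter
        self.seed = seed

    def _spec(self) -> KernelSpec:
        return KernelSpec(
            name=self.kernel, gamma=self.gamma, degree=self.degree, coef0=self.coef0
        )

    def _config(self) -> KplsConfig:
        return KplsConfig(
            max_components=self.max_components,
            lambda_rel=self.lambda_rel,
            inner_tol=self.inner_tol,
            inner_max_iter=self.inner_max_iter,
            seed=self.seed,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        cset, indicator, gram = fit_components(
            X, y, kernel_spec=self._spec(), cfg=self._config()
        )
        self.component_set_ = cset
        self.indicator_ = indicator
        self.gram_ = gram
        self.scores_ = cset.scores()
        self.dual_coefs_ = np.column_stack([c.u_dual for c in cset.components])
        self.rd_ = cset.rd()
        self.fisher_j_ = cset.fisher()
        self.n_components_ = cset.kappa
        self.stopping_reason_ = cset.stopping_reason
        self.classes_ = indicator.classes
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X=None):
        """Return the fitted score matrix (no out-of-sample projection)."""
        check_is_fitted(self, "scores_")
        return self.scores_
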