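"""Per-gene importance scores and the feature-selection estimator.

Components live in sample space; to rank genes they are mapped back to
feature space through the loading ``w_h = X' t_h`` (each column scaled to
unit norm).  Gene j's importance accumulates its squared loading over the
retained components, weighted by each component's share of class variation:

    score_j  proportional to  sum_h  Rd_h * w_{hj}^2,

normalized to sum to one.  Ranking is by descending importance with ties
broken by ascending gene identifier, so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .pls import ComponentSet, KernelPLS

__all__ = [
    "FeatureRanking",
    "feature_loadings",
    "importance_scores",
    "select_top_k",
    "KernelPLSSelector",
]


@dataclass
class FeatureRanking:
    """Per-gene importance scores with their rank order.

    ``rank`` is a permutation of 1..p over genes in input order (1 = most
    important); ``order`` lists gene indices from most to least important.
    """

    gene_ids: list[str]
    importance: np.ndarray  # length p, nonnegative, sums to 1
    rank: np.ndarray  # length p, rank of each gene in input order
    kappa_used: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def order(self) -> np.ndarray:
        return np.argsort(self.rank)

    def top_k(self, k: int) -> list[str]:
        return select_top_k(self, k)


def feature_loadings(
    X: np.ndarray,
    components: ComponentSet,
    mode: str = "projection",
) -> np.ndarray:
    """p x kappa matrix of per-gene weights on each component.

    ``projection`` (default): column h is ``X' t_h`` scaled to unit
    Euclidean norm.  ``correlation``: column h holds the Pearson correlation
    of each gene with t_h, then scaled to unit norm — useful when genes are
    on very different variance scales.  X is column-centered internally;
    score vectors of a centered Gram matrix are mean-zero, so centering
    does not change the projection but guards against uncentered input.
    """
    if mode not in ("projection", "correlation"):
        raise ValueError(f"unknown loading mode {mode!r}")
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    T = components.scores()
    if T.shape[0] != Xc.shape[0]:
        raise ValueError("components were fitted on a different sample count")
    W = Xc.T @ T  # p x kappa
    if mode == "correlation":
        gene_norms = np.linalg.norm(Xc, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.where(gene_norms[:, None] > 1e-15, W / gene_norms[:, None], 0.0)
    norms = np.linalg.norm(W, axis=0)
    for h in np.nonzero(norms <= 1e-15)[0]:
        warnings.warn(
            f"component {h + 1} has zero projection onto the genes; "
            "it contributes nothing to the ranking",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(norms[None, :] > 1e-15, W / norms[None, :], 0.0)
    return W


def importance_scores(
    loadings: np.ndarray,
    components: ComponentSet,
    gene_ids=None,
) -> FeatureRanking:
    """Accumulate Rd-weighted squared loadings into a normalized ranking."""
    W = np.asarray(loadings, dtype=float)
    rd = components.rd()
    if W.shape[1] != rd.shape[0]:
        raise ValueError("loading columns do not match component count")
    if np.all(rd == 0):
        raise ValueError("no component explains the response")
    raw = (W**2) @ rd
    total = raw.sum()
    if total <= 0:
        raise ValueError("no component explains the response")
    importance = raw / total
    p = W.shape[0]
    if gene_ids is None:
        width = len(str(p - 1)) if p > 1 else 1
        gene_ids = [f"g{str(j).zfill(width)}" for j in range(p)]
    gene_ids = [str(g) for g in gene_ids]
    if len(gene_ids) != p:
        raise ValueError("gene_ids length does not match loading rows")
    # descending importance, ties by ascending gene id
    order = np.lexsort((np.asarray(gene_ids), -importance))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return FeatureRanking(
        gene_ids=gene_ids,
        importance=importance,
        rank=rank,
        kappa_used=components.kappa,
    )


def select_top_k(ranking: FeatureRanking, k: int = 30) -> list[str]:
    """First k gene ids in rank order."""
    if not 1 <= k <= ranking.n_genes:
        raise ValueError(
            f"k must be in [1, {ranking.n_genes}], got {k}"
        )
    return [ranking.gene_ids[j] for j in ranking.order[:k]]


class KernelPLSSelector(SelectorMixin, BaseEstimator):
    """Filter-style gene selector built on kernel PLS importance scores.

    Fits :class:`~kernelpls.pls.KernelPLS` on (X, y), maps the retained
    components to per-gene importances, and keeps the ``top_k`` genes.
    Composes with sklearn pipelines: ``transform`` subsets the columns.

    Parameters
    ----------
    top_k : int, default 30
        Number of genes to keep.
    loading : {"projection", "correlation"}, default "projection"
        How component scores are mapped back to gene weights.
    Remaining parameters are forwarded to :class:`KernelPLS`.

    Attributes
    ----------
    ranking_ : FeatureRanking
        Full importance ranking over all genes.
    importances_ : ndarray of shape (p,)
        Normalized importance scores, summing to 1.
    kpls_ : KernelPLS
        The fitted component extractor.
    n_components_ : int
        Components retained by the self-adaptive stopping rule.
    """

    def __init__(
        self,
        top_k: int = 30,
        loading: str = "projection",
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
        self.top_k = top_k
        self.loading = loading
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.max_components = max_components
        self.lambda_rel = lambda_rel
        self.inner_tol = inner_tol
        self.inner_max_iter = inner_max_iter
        self.seed = seed

    def fit(self, X, y, gene_ids=None):
        X = np.asarray(X, dtype=float)
        if not 1 <= self.top_k <= X.shape[1]:
            raise ValueError(
                f"top_k must be in [1, {X.shape[1]}], got {self.top_k}"
            )
        kpls = KernelPLS(
            kernel=self.kernel,
            gamma=self.gamma,
            degree=self.degree,
            coef0=self.coef0,
            max_components=self.max_components,
            lambda_rel=self.lambda_rel,
            inner_tol=self.inner_tol,
            inner_max_iter=self.inner_max_iter,
            seed=self.seed,
        ).fit(X, y)
        W = feature_loadings(X, kpls.component_set_, mode=self.loading)
        self.ranking_ = importance_scores(W, kpls.component_set_, gene_ids=gene_ids)
        self.importances_ = self.ranking_.importance
        self.kpls_ = kpls
        self.n_components_ = kpls.n_components_
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.ranking_.n_genes, dtype=bool)
        mask[self.ranking_.order[: self.top_k]] = True
        return mask

    def selected_gene_ids(self) -> list[str]:
        check_is_fitted(self, "ranking_")
        return self.ranking_.top_k(self.top_k)
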