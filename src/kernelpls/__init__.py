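"""Kernel partial least squares feature-selection filter for expression data.

A multivariate, classifier-independent gene filter: kernel PLS components
are extracted from an n x n Gram matrix with NIPALS-style deflation, the
number of components is chosen self-adaptively from a kernel Fisher-
discriminant ratio, and genes are ranked by their accumulated share of the
class variation explained across the retained components.
"""

__version__ = "0.1.0"

from .evaluation import (
    EvalProtocol,
    auc_two_class,
    cohens_kappa,
    evaluate_selection,
    stratified_folds,
)
from .kernels import GramMatrix, KernelSpec, center_gram, compute_gram
from .pls import (
    Component,
    ComponentSet,
    IndicatorMatrix,
    KernelPLS,
    KplsConfig,
    deflate,
    encode_labels,
    extract_component,
    fisher_ratio,
    fit_components,
    rd_contribution,
)
from .selection import (
    FeatureRanking,
    KernelPLSSelector,
    feature_loadings,
    importance_scores,
    select_top_k,
)
from .simulate import SimulationConfig, SyntheticDataset, read_dataset, simulate, write_dataset

__all__ = [
    "__version__",
    "KernelSpec",
    "GramMatrix",
    "compute_gram",
    "center_gram",
    "IndicatorMatrix",
    "Component",
    "ComponentSet",
    "KplsConfig",
    "encode_labels",
    "extract_component",
    "deflate",
    "rd_contribution",
    "fisher_ratio",
    "fit_components",
    "KernelPLS",
    "FeatureRanking",
    "feature_loadings",
    "importance_scores",
    "select_top_k",
    "KernelPLSSelector",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate",
    "write_dataset",
    "read_dataset",
    "EvalProtocol",
    "stratified_folds",
    "auc_two_class",
    "cohens_kappa",
    "evaluate_selection",
]
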