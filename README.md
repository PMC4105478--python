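# kernelpls

A multivariate, classifier-independent gene-selection filter for
high-dimensional expression data (microarray or bulk/single-cell counts
after transformation), built on **kernel partial least squares**. It is
aimed at the n ≪ p regime — tens of samples, thousands of genes — where
univariate filters miss genes whose class information lives in gene–gene
interactions.

## Method in brief

Classification is treated as PLS regression of a column-centered one-hot
class indicator **Y** (n × c) on the kernel representation of the
expression matrix **X** (samples × genes). Working entirely with the n × n
centered Gram matrix **K**, components are extracted by the kernel NIPALS
iteration

&nbsp;&nbsp;&nbsp;&nbsp;t ← K u / ‖K u‖, c ← Yᵀt, u ← Y c / ‖Y c‖,

whose fixed point makes t the dominant eigenvector of K Y Yᵀ; after each
component, K and Y are deflated by the projector I − t tᵀ, so scores are
orthonormal. The number of components κ is chosen **self-adaptively**: each
component's Fisher-discriminant ratio J_h (between-class over within-class
scatter of its scores) is compared against the best ratio seen so far, and
extraction stops when J_h < λ·J* (default λ = 0.05). Genes are then ranked
by accumulated variation explanation

&nbsp;&nbsp;&nbsp;&nbsp;score_j ∝ Σ_{h=1..κ} Rd_h · w²_{hj},

where w_h = Xᵀt_h (unit-normalized) and Rd_h is the mean squared
correlation between t_h and the columns of Y. With the linear kernel the
whole procedure reduces exactly to classical primal NIPALS PLS2 (verified
against an independent oracle in the test suite). See `docs/methods.md`
for assumptions, edge cases, and a documented limitation of the per-gene
readout on purely interaction-coded genes.

The package follows scikit-learn conventions: `KernelPLS` (component
extractor) and `KernelPLSSelector` (a `SelectorMixin` filter that drops
into sklearn pipelines), with module-level functions underneath. A
synthetic-data generator with known ground-truth gene roles and a
cross-validated evaluation harness (stratified 10-fold for two-class,
5-fold for multi-class; accuracy, Mann–Whitney AUC, Cohen's kappa) are
included.

## Worked example

```sh
kernelpls simulate --out data --seed 7 --n-samples 60 --n-genes 1000
kernelpls rank --expr data/expression.tsv --labels data/labels.tsv \
    --kernel rbf --top-k 30 --out ranking.tsv
```

prints the per-component diagnostics and stopping decision:

```
component 1: Rd=0.9902 J=101.5
kappa=1 stopping_reason=threshold
wrote ranking of 1000 genes to ranking.tsv
wrote top-30 selection to ranking.top30.tsv
```

One component explains 99% of the class indicator's variation
(Rd = 0.9902) with a Fisher ratio of 101.5; the second component fell
below λ·J* and extraction stopped, so κ = 1. `ranking.tsv` records the
full importance ranking (importances sum to 1) under a provenance header:

```
# kernel=rbf
# gamma=auto
# kappa=1
# lambda_rel=0.05
# stopping_reason=threshold
# seed=0
rank	gene_id	importance
1	g000	0.03802605917
```

Cross-validated evaluation of the top-30 panel with the default KNN (k=5)
classifier:

```sh
kernelpls evaluate --expr data/expression.tsv --labels data/labels.tsv \
    --top-k 30 --report report.tsv
```

```
        acc  kappa    auc
fold
0    1.0000 1.0000 1.0000
...
mean 0.9333 0.8667 0.9944
sd   0.0861 0.1721 0.0176
```

Selection is re-fit inside every training fold, so these held-out numbers
contain no selection leakage: mean accuracy 93.3%, AUC 0.994 on this
synthetic two-class dataset.

The same pipeline from Python:

```python
from kernelpls import KernelPLSSelector, SimulationConfig, simulate

ds = simulate(SimulationConfig(seed=7))
sel = KernelPLSSelector(top_k=30, kernel="rbf").fit(
    ds.expression, ds.labels, gene_ids=ds.gene_ids
)
sel.selected_gene_ids()      # ranked top-30 gene ids
sel.kpls_.rd_, sel.kpls_.fisher_j_  # per-component diagnostics
```

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch — generates
the default synthetic dataset, ranks all genes with the RBF-kernel filter,
measures planted-gene recovery, and cross-validates the top-30 selection
under the stratified CV protocol — and writes its results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
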