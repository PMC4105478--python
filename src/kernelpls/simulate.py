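"""Microarray-like synthetic data with known ground-truth gene roles.

Emulates the n << p structure of expression studies: a handful of
class-informative genes, blocks of genes correlated with them (redundancy),
and a large majority of pure noise.  Two kinds of informative genes are
planted:

* *linear* — class-shifted Gaussians (adjacent classes differ by
  ``effect_size`` standard deviations in the mean), detectable by any
  univariate filter;
* *nonlinear* — genes whose class information lives in interactions or in
  the variance, with zero per-class mean difference, so univariate linear
  statistics are blind to them.  For two classes these come in XOR pairs:
  within a pair both genes share a random sign for class 0 and opposite
  behaviour for class 1, so the *product* of the pair encodes the class
  while each gene's class-conditional mean is exactly zero.  For three or
  more classes each gene carries a class-indexed radius with a random sign
  (distance-to-center coding).

The generator is fully determined by (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate",
    "write_dataset",
    "read_dataset",
]

ROLE_LINEAR = "informative_linear"
ROLE_NONLINEAR = "informative_nonlinear"
ROLE_REDUNDANT = "redundant"
ROLE_NOISE = "noise"


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    ``effect_size`` is the between-class mean shift of linear-informative
    genes in units of ``noise_sd``; the same scale sets the amplitude of
    the nonlinear genes.  ``redundancy_rho`` is the target correlation of a
    redundant gene with its informative parent.
    """

    n_samples: int = 60
    n_genes: int = 1000
    n_informative_linear: int = 5
    n_informative_nonlinear: int = 5
    n_redundant: int = 40
    n_classes: int = 2
    effect_size: float = 1.5
    redundancy_rho: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0
    class_proportions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n_inf = self.n_informative_linear + self.n_informative_nonlinear
        if n_inf + self.n_redundant > self.n_genes:
            raise ValueError("informative + redundant genes exceed n_genes")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_redundant > 0 and n_inf == 0:
            raise ValueError("redundant genes need an informative parent")
        if not 0 < self.redundancy_rho < 1:
            raise ValueError("redundancy_rho must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.class_proportions is not None:
            if len(self.class_proportions) != self.n_classes:
                raise ValueError("class_proportions length must equal n_classes")
            if abs(sum(self.class_proportions) - 1.0) > 1e-9:
                raise ValueError("class_proportions must sum to 1")


@dataclass
class SyntheticDataset:
    """Expression matrix, labels, and the ground-truth gene-role map."""

    expression: np.ndarray  # n x p
    labels: np.ndarray  # length n, string class labels
    truth: dict[str, str]  # gene id -> role
    sample_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g in self.gene_ids if self.truth[g] == role]


def _balanced_labels(cfg: SimulationConfig) -> np.ndarray:
    n, c = cfg.n_samples, cfg.n_classes
    if cfg.class_proportions is None:
        counts = [n // c] * c
        for i in range(n - sum(counts)):
            counts[i] += 1
    else:
        counts = [int(round(p * n)) for p in cfg.class_proportions]
        counts[-1] = n - sum(counts[:-1])
    if min(counts) < 2:
        raise ValueError("every class needs at least 2 samples")
    labels = np.concatenate(
        [np.full(k, f"class{i}") for i, k in enumerate(counts)]
    )
    return labels


def simulate(config: SimulationConfig = SimulationConfig()) -> SyntheticDataset:
    """Draw one dataset from the stated generative model."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_genes
    labels = _balanced_labels(cfg)
    y_idx = np.array([int(s.removeprefix("class")) for s in labels])

    X = np.empty((n, p))
    roles: list[str] = []
    col = 0

    # linear-informative: adjacent classes shifted by effect_size * noise_sd
    for _ in range(cfg.n_informative_linear):
        shift = cfg.effect_size * cfg.noise_sd * y_idx
        X[:, col] = shift + rng.normal(0.0, cfg.noise_sd, n)
        roles.append(ROLE_LINEAR)
        col += 1

    # nonlinear-informative
    nl_start = col
    n_nl = cfg.n_informative_nonlinear
    if n_nl:
        if cfg.n_classes == 2:
            # XOR pairs: product sign encodes the class, marginals mean-zero
            y_pm = np.where(y_idx == 0, 1.0, -1.0)
            cols = [np.empty(n) for _ in range(n_nl)]
            for a in range(0, n_nl - 1, 2):
                s = rng.choice([-1.0, 1.0], size=n)
                m_a = cfg.noise_sd * np.abs(rng.normal(cfg.effect_size, 1.0, n))
                m_b = cfg.noise_sd * np.abs(rng.normal(cfg.effect_size, 1.0, n))
                cols[a][:] = s * m_a
                cols[a + 1][:] = s * y_pm * m_b
            if n_nl % 2 == 1:
                # odd count: last gene pairs with the first one
                s_last = np.sign(cols[0]) if n_nl > 1 else rng.choice(
                    [-1.0, 1.0], size=n
                )
                m = cfg.noise_sd * np.abs(rng.normal(cfg.effect_size, 1.0, n))
                cols[n_nl - 1][:] = s_last * y_pm * m
            for c_arr in cols:
                X[:, col] = c_arr
                roles.append(ROLE_NONLINEAR)
                col += 1
        else:
            # class-indexed radius with random sign: |value| encodes class,
            # class-conditional means are all zero
            for _ in range(n_nl):
                s = rng.choice([-1.0, 1.0], size=n)
                radius = cfg.effect_size * cfg.noise_sd * y_idx
                X[:, col] = s * (radius + np.abs(rng.normal(0.0, cfg.noise_sd, n)))
                roles.append(ROLE_NONLINEAR)
                col += 1

    # redundant: rho-correlated copies of randomly chosen informative genes
    n_inf = cfg.n_informative_linear + cfg.n_informative_nonlinear
    rho = cfg.redundancy_rho
    for _ in range(cfg.n_redundant):
        parent = int(rng.integers(0, n_inf))
        z = X[:, parent]
        z_std = (z - z.mean()) / max(z.std(), 1e-12)
        g = rho * z_std + np.sqrt(1.0 - rho**2) * rng.normal(0.0, 1.0, n)
        X[:, col] = cfg.noise_sd * g
        roles.append(ROLE_REDUNDANT)
        col += 1

    # pure noise
    n_noise = p - col
    X[:, col:] = rng.normal(0.0, cfg.noise_sd, (n, n_noise))
    roles.extend([ROLE_NOISE] * n_noise)

    width = len(str(p - 1)) if p > 1 else 1
    gene_ids = [f"g{str(j).zfill(width)}" for j in range(p)]
    sample_ids = [f"s{str(i).zfill(len(str(n - 1)))}" for i in range(n)]
    truth = dict(zip(gene_ids, roles))

    # shuffle gene columns so position encodes nothing
    perm = rng.permutation(p)
    X = X[:, perm]
    gene_ids = [gene_ids[j] for j in perm]

    return SyntheticDataset(
        expression=X,
        labels=labels,
        truth=truth,
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        config=cfg,
    )


def write_dataset(ds: SyntheticDataset, path: str | Path) -> None:
    """Write expression.tsv, labels.tsv and truth.tsv under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    expr = pd.DataFrame(
        ds.expression, index=ds.sample_ids, columns=ds.gene_ids
    )
    expr.index.name = "sample_id"
    expr.to_csv(path / "expression.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.labels}).to_csv(
        path / "labels.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"gene_id": list(ds.truth), "role": list(ds.truth.values())}
    ).to_csv(path / "truth.tsv", sep="\t", index=False)


def read_dataset(path: str | Path) -> SyntheticDataset:
    """Round-trip reader for :func:`write_dataset` output."""
    from .io import attach_labels, read_expression, read_labels

    path = Path(path)
    ds = read_expression(path / "expression.tsv")
    attach_labels(ds, read_labels(path / "labels.tsv"))
    labels = ds.labels
    truth_df = pd.read_csv(path / "truth.tsv", sep="\t", dtype=str)
    truth = dict(zip(truth_df["gene_id"], truth_df["role"]))
    missing = set(ds.gene_ids) - set(truth)
    if missing:
        raise ValueError(f"truth.tsv missing roles for genes: {sorted(missing)[:5]}")
    return SyntheticDataset(
        expression=ds.expression,
        labels=labels,
        truth=truth,
        sample_ids=ds.sample_ids,
        gene_ids=ds.gene_ids,
    )
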