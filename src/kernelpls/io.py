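"""Readers and writers for expression matrices, labels and rankings.

Expression files are TSV/CSV with one header row and one id column.  Public
microarray matrices come in both orientations, so the reader takes an
explicit ``orientation`` flag instead of guessing; internally samples are
always rows and genes columns.  Missing values are rejected outright —
imputation belongs upstream (e.g. KNN imputation in a dedicated tool).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "read_labels",
    "attach_labels",
    "write_ranking",
    "read_ranking",
]


@dataclass
class ExpressionDataset:
    """Samples x genes matrix with ids and (optionally) class labels."""

    expression: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = field(default=None)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path, orientation: str = "samples_by_genes"
) -> ExpressionDataset:
    """Load a TSV/CSV expression matrix.

    ``orientation`` says what the *file* rows are; the returned matrix is
    always samples x genes.  Duplicate ids, non-numeric cells and missing
    values are rejected with the offending coordinates in the message.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row id {dup!r} in {path.name}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate column id {dup!r} in {path.name}")
    values = np.empty(df.shape, dtype=float)
    for j, colname in enumerate(df.columns):
        col = pd.to_numeric(df[colname], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy())[0]
        if bad.size:
            i = bad[0]
            raise ValueError(
                f"non-numeric or missing value {df.iat[i, j]!r} at row "
                f"{df.index[i]!r}, column {colname!r} in {path.name}; "
                "impute missing values upstream"
            )
        values[:, j] = col.to_numpy()
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at row {df.index[i]!r}, column "
            f"{df.columns[j]!r} in {path.name}"
        )
    if orientation == "genes_by_samples":
        values = values.T
        sample_ids = [str(c) for c in df.columns]
        gene_ids = [str(r) for r in df.index]
    else:
        sample_ids = [str(r) for r in df.index]
        gene_ids = [str(c) for c in df.columns]
    return ExpressionDataset(
        expression=values, sample_ids=sample_ids, gene_ids=gene_ids
    )


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(ds.expression, index=ds.sample_ids, columns=ds.gene_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column sample_id -> label TSV/CSV (header row required)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path.name} needs two columns")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"sample {dup!r} appears twice in {path.name}")
    return dict(zip(ids, df.iloc[:, 1].astype(str)))


def attach_labels(ds: ExpressionDataset, labels_map: dict[str, str]) -> None:
    """Match a label map against the dataset's samples (exact coverage)."""
    missing = [s for s in ds.sample_ids if s not in labels_map]
    if missing:
        raise ValueError(f"no label for sample {missing[0]!r}")
    extra = set(labels_map) - set(ds.sample_ids)
    if extra:
        raise ValueError(
            f"label file names unknown sample {sorted(extra)[0]!r}"
        )
    ds.labels = np.array([labels_map[s] for s in ds.sample_ids])


def write_ranking(
    ranking,
    path: str | Path,
    header_info: dict | None = None,
) -> None:
    """Write rank / gene_id / importance TSV with provenance comments."""
    path = Path(path)
    lines = []
    for key, val in (header_info or {}).items():
        lines.append(f"# {key}={val}")
    lines.append("rank\tgene_id\timportance")
    for pos, j in enumerate(ranking.order, start=1):
        lines.append(f"{pos}\t{ranking.gene_ids[j]}\t{ranking.importance[j]:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_ranking(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
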