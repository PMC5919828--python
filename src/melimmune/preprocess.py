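"""Expression-matrix container, per-gene standardization, and cohort splitting.

Expression values are held gene-wise (rows = gene symbols, columns = sample
IDs) on whatever scale the caller provides; clustering and scoring always
operate on the standardized state (per-gene mean 0, variance 1), mirroring
common practice for signature-based subtype discovery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CohortSplit",
    "standardize_genes",
    "log_transform",
    "split_cohort",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples real matrix with a raw/standardized state flag."""

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "standardized"):
            raise ValueError(f"unknown state {self.state!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict_genes(self, genes) -> "ExpressionMatrix":
        """Subset to ``genes`` (order of the matrix preserved; missing ignored)."""
        keep = self.values.index.intersection(pd.Index(genes))
        return ExpressionMatrix(self.values.loc[keep], state=self.state)

    def restrict_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], state=self.state)


@dataclass(frozen=True)
class CohortSplit:
    """Random partition of sample IDs into train/test sets."""

    train_ids: tuple
    test_ids: tuple
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def standardize_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Z-transform each gene row to mean 0, variance 1 (sample variance, n-1).

    Zero-variance genes carry no contrast and are dropped with a warning
    listing them; if every gene is constant an error is raised.
    """
    if X.state != "raw":
        raise ValueError("expected a raw expression matrix")
    vals = X.values
    sd = vals.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant) == len(vals):
        raise ValueError("all genes have zero variance; nothing to standardize")
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} zero-variance gene(s): "
            + ", ".join(map(str, constant[:20]))
            + ("..." if len(constant) > 20 else ""),
            stacklevel=2,
        )
        vals = vals.drop(index=constant)
        sd = sd.drop(index=constant)
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, state="standardized")


def log_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x+1) for count-scale inputs (e.g. RNA-seq) prior to standardization."""
    if (X.values.to_numpy() < 0).any():
        raise ValueError("log transform requires non-negative values")
    return ExpressionMatrix(np.log2(X.values + 1.0), state="raw")


def split_cohort(samples, fraction: float = 2.0 / 3.0, seed: int = 0) -> CohortSplit:
    """Uniform random train/test partition with |train| = round(fraction * n)."""
    samples = list(samples)
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if len(set(samples)) != n:
        raise ValueError("duplicate sample IDs")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = tuple(samples[i] for i in sorted(order[:n_train]))
    test = tuple(samples[i] for i in sorted(order[n_train:]))
    return CohortSplit(train_ids=train, test_ids=test, fraction=fraction, seed=seed)


def read_expression_tsv(path, state: str = "raw") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene symbols, header sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, state=state)


def write_expression_tsv(X: ExpressionMatrix, path) -> None:
    X.values.to_csv(path, sep="\t", index_label="gene")
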