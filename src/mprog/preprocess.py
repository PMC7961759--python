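"""Expression-matrix container, TPM normalization, batch correction, and
variance-based feature selection.

Downstream clustering and scoring assume TPM normalization, log2(TPM + 1)
transform, least-squares batch correction with the per-gene grand mean
preserved, and selection of the most variable genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "counts_to_tpm",
    "log_transform",
    "correct_batch",
    "top_variable_genes",
    "pca_embedding",
]

UNITS = ("counts", "TPM", "log2TPM")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples abundance matrix with a unit tag.

    ``unit`` transitions only through the declared operations:
    counts -> TPM (``counts_to_tpm``) -> log2TPM (``log_transform``).
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    unit: str
    gene_lengths: np.ndarray | None = None  # bp, required for counts -> TPM

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected {UNITS}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.unit != "log2TPM" and np.any(self.values < 0):
            raise ValueError(f"negative values in a {self.unit} matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str,
                   gene_lengths: np.ndarray | None = None) -> "ExpressionMatrix":
        return cls(values=df.to_numpy(dtype=float),
                   gene_ids=tuple(map(str, df.index)),
                   sample_ids=tuple(map(str, df.columns)),
                   unit=unit, gene_lengths=gene_lengths)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return replace(self, values=self.values[rows], gene_ids=tuple(genes))


def counts_to_tpm(m: ExpressionMatrix,
                  lengths: pd.Series | dict | np.ndarray) -> ExpressionMatrix:
    """Length-normalize read counts to transcripts-per-million.

    TPM_g = (c_g / len_g) / sum_g'(c_g' / len_g') * 1e6 per sample; every
    column of the result sums to 1e6.
    """
    if m.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit {m.unit!r}")
    if isinstance(lengths, dict):
        lengths = pd.Series(lengths)
    if isinstance(lengths, pd.Series):
        missing = [g for g in m.gene_ids if g not in lengths.index]
        if missing:
            raise ValueError(f"missing gene length for {missing[0]!r}")
        lengths = lengths.loc[list(m.gene_ids)].to_numpy(dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape[0] != m.n_genes:
        raise ValueError("one length per gene required")
    if np.any(lengths <= 0):
        bad = m.gene_ids[int(np.argmax(lengths <= 0))]
        raise ValueError(f"non-positive length for gene {bad!r}")
    rate = m.values / lengths[:, None]
    totals = rate.sum(axis=0)
    if np.any(totals == 0):
        bad = m.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total signal")
    tpm = rate / totals[None, :] * 1e6
    return replace(m, values=tpm, unit="TPM", gene_lengths=lengths)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount)."""
    if m.unit != "TPM":
        raise ValueError(f"expected a TPM matrix, got unit {m.unit!r}")
    return replace(m, values=np.log2(m.values + pseudocount), unit="log2TPM")


def correct_batch(m: ExpressionMatrix, batch) -> ExpressionMatrix:
    """Remove per-gene additive batch effects from a log2 matrix.

    Per gene, the least-squares batch coefficients of a batch-only design are
    subtracted (equivalently, each batch is centered) and the per-gene grand
    mean is restored.  Idempotent; with a single batch, the identity.
    """
    if m.unit != "log2TPM":
        raise ValueError("batch correction operates on log2TPM values")
    if isinstance(batch, (pd.Series, dict)):
        batch = pd.Series(batch)
        missing = [s for s in m.sample_ids if s not in batch.index]
        if missing:
            raise ValueError(f"no batch label for sample {missing[0]!r}")
        batch = batch.loc[list(m.sample_ids)]
    labels = pd.Index(batch).astype(str)
    if len(labels) != m.n_samples:
        raise ValueError("one batch label per sample required")
    if labels.nunique() == 1:
        return m
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index[0]
        raise ValueError(f"batch {small!r} has fewer than 2 samples")
    codes = labels.factorize()[0]
    n_batches = codes.max() + 1
    batch_sums = np.zeros((m.n_genes, n_batches))
    for b in range(n_batches):
        batch_sums[:, b] = m.values[:, codes == b].mean(axis=1)
    grand = m.values.mean(axis=1, keepdims=True)
    corrected = m.values - batch_sums[:, codes] + grand
    return replace(m, values=corrected)


def top_variable_genes(m: ExpressionMatrix, n: int = 2000) -> list[str]:
    """The ``n`` genes with the largest variance of log2(TPM + 1) across
    samples, in decreasing-variance order; ties broken lexicographically.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > m.n_genes:
        raise ValueError(f"n={n} exceeds gene count {m.n_genes}")
    vals = m.values if m.unit == "log2TPM" else np.log2(m.values + 1.0)
    var = vals.var(axis=1, ddof=1)
    order = sorted(range(m.n_genes), key=lambda i: (-var[i], m.gene_ids[i]))
    return [m.gene_ids[i] for i in order[:n]]


def pca_embedding(m: ExpressionMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample coordinates on the top ``k`` principal components of the
    centered log2 matrix.

    Returns ``(coords, explained_variance)`` with coords of shape
    (n_samples, k).  Sign convention: the largest-magnitude gene loading of
    each component is positive.
    """
    if k <= 0 or k > min(m.n_genes, m.n_samples):
        raise ValueError(f"k={k} out of range")
    vals = m.values if m.unit == "log2TPM" else np.log2(m.values + 1.0)
    centered = vals - vals.mean(axis=1, keepdims=True)
    # SVD of genes x samples: right singular vectors give sample coordinates
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    denom = max(m.n_samples - 1, 1)
    ev = (s ** 2) / denom
    coords = (vt.T * s)[:, :k]
    loadings = u[:, :k]
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            coords[:, j] *= -1.0
            loadings[:, j] *= -1.0
    if np.any(ev[: max(k - 1, 0)] + 1e-12 < ev[1:k]):
        warnings.warn("PC variances not sorted; numerical issue")
    return coords, ev[:k]
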