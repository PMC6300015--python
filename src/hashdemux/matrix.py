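"""Sparse barcode-by-tag UMI count matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse


class TagCountMatrix:
    """Barcode × tag matrix of non-negative integer UMI counts.

    Rows are droplet barcodes, columns are tag names (HTO samples or ADT
    antibodies). Counts are stored as a CSR sparse matrix of integers.

    Parameters
    ----------
    counts : array-like or scipy sparse matrix, shape (n_barcodes, n_tags)
        Non-negative integer UMI counts.
    barcodes : sequence of str
        Unique droplet barcode strings, one per row.
    tags : sequence of str
        Unique tag names, one per column.
    """

    def __init__(self, counts, barcodes, tags):
        barcodes = np.asarray(barcodes, dtype=object)
        tags = np.asarray(tags, dtype=object)
        X = sparse.csr_matrix(counts)
        if X.shape != (len(barcodes), len(tags)):
            raise ValueError(
                f"counts shape {X.shape} does not match "
                f"{len(barcodes)} barcodes x {len(tags)} tags"
            )
        if len(set(barcodes)) != len(barcodes):
            seen, dups = set(), []
            for b in barcodes:
                if b in seen:
                    dups.append(b)
                seen.add(b)
            raise ValueError(f"duplicate barcodes: {sorted(set(dups))}")
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate tag names")
        if X.nnz and X.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(X.dtype, np.integer):
            data = X.data
            if X.nnz and not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
            X = X.astype(np.int64)
        self.X = X
        self.barcodes = barcodes
        self.tags = tags

    @property
    def shape(self):
        return self.X.shape

    @property
    def n_barcodes(self):
        return self.X.shape[0]

    @property
    def n_tags(self):
        return self.X.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense int array (barcodes × tags)."""
        return np.asarray(self.X.todense())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.barcodes, columns=self.tags)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TagCountMatrix":
        return cls(df.to_numpy(), df.index.to_numpy(), df.columns.to_numpy())

    def subset(self, barcodes) -> "TagCountMatrix":
        """Row-subset by barcode, preserving the given order."""
        pos = {b: i for i, b in enumerate(self.barcodes)}
        try:
            idx = np.array([pos[b] for b in barcodes], dtype=int)
        except KeyError as e:
            raise KeyError(f"barcode not in matrix: {e.args[0]}") from None
        return TagCountMatrix(self.X[idx], np.asarray(barcodes, dtype=object), self.tags)

    def __eq__(self, other):
        if not isinstance(other, TagCountMatrix):
            return NotImplemented
        return (
            np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.tags, other.tags)
            and (self.X != other.X).nnz == 0
        )

    def __repr__(self):
        return f"TagCountMatrix({self.n_barcodes} barcodes x {self.n_tags} tags, nnz={self.X.nnz})"
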