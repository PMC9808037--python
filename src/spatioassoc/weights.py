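"""Sparse row-indexed spatial weights shared by aggregation and lag features."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["SpatialWeights"]


@dataclass
class SpatialWeights:
    """Nonnegative pairwise weights from row units onto column units.

    ``matrix`` is a CSR matrix of shape (len(row_ids), len(col_ids)); rows
    with any qualifying neighbor are normalized to sum to one, rows with none
    are left empty. ``scheme`` and ``params`` record provenance (weight form,
    radius, distance floor).
    """

    row_ids: list[str]
    col_ids: list[str]
    matrix: sp.csr_matrix
    scheme: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("weight matrix shape does not match id lists")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("weights must be nonnegative")

    @property
    def n_neighbors(self) -> np.ndarray:
        """Number of nonzero weights per row."""
        return np.diff(self.matrix.indptr)

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def row(self, row_id: str) -> dict[str, float]:
        """Neighbor-id -> weight mapping for one row (test/debug helper)."""
        i = self.row_ids.index(row_id)
        sl = slice(self.matrix.indptr[i], self.matrix.indptr[i + 1])
        return {
            self.col_ids[j]: w
            for j, w in zip(self.matrix.indices[sl], self.matrix.data[sl])
        }
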