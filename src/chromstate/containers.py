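"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """A sparse non-negative integer feature x cell count matrix.

    ``features`` are peak or gene identifiers (rows); ``cells`` are cell
    barcodes or sample identifiers (columns).
    """

    matrix: sp.csr_matrix
    features: list[str] = field(repr=False)
    cells: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        if not sp.issparse(self.matrix):
            self.matrix = sp.csr_matrix(np.asarray(self.matrix))
        else:
            self.matrix = self.matrix.tocsr()
        self.features = list(self.features)
        self.cells = list(self.cells)
        n_feat, n_cell = self.matrix.shape
        if n_feat != len(self.features):
            raise ValueError(
                f"matrix has {n_feat} rows but {len(self.features)} feature names"
            )
        if n_cell != len(self.cells):
            raise ValueError(
                f"matrix has {n_cell} columns but {len(self.cells)} cell names"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("count matrix must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total counts per cell (column sums)."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def feature_totals(self) -> np.ndarray:
        """Total counts per feature (row sums)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def to_frame(self) -> pd.DataFrame:
        """Densify into a features x cells DataFrame (small matrices only)."""
        return pd.DataFrame(
            self.matrix.toarray(), index=self.features, columns=self.cells
        )

    def subset_cells(self, cells: list[str]) -> "CountMatrix":
        pos = {c: i for i, c in enumerate(self.cells)}
        idx = [pos[c] for c in cells]
        return CountMatrix(self.matrix[:, idx], self.features, list(cells))


@dataclass(frozen=True)
class SignatureSet:
    """A named gene set used for per-cell or per-sample signature scoring.

    May be empty when derived from a marker table in which no gene passes the
    selection cutoffs; callers are warned at derivation time.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)
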