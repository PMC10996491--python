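"""Sparse cell-by-feature matrix containers and Matrix Market I/O.

Counts are stored cells x features (rows are cells) in CSR form. On disk
the 10x convention is used instead: ``matrix.mtx`` is features x cells,
with ``features.tsv`` and ``barcodes.tsv`` alongside.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["CellMatrix", "CountMatrix", "read_mtx_dir"]


class CellMatrix:
    """A cells x features matrix with string identifiers on both axes.

    Parameters
    ----------
    values
    	Dense or sparse array, cells in rows. Stored as CSR.
    cells, features
    	Unique identifiers; lengths must match the matrix shape.
    """

    _require_counts = False

    def __init__(self, values, cells: Sequence[str], features: Sequence[str]):
        if sp.issparse(values):
            mat = sp.csr_matrix(values)
        else:
            mat = sp.csr_matrix(np.asarray(values))
        cells = pd.Index(cells)
        features = pd.Index(features)
        if mat.shape != (len(cells), len(features)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(cells)} cells x {len(features)} features"
            )
        if cells.has_duplicates or features.has_duplicates:
            raise ValueError("duplicate cell or feature identifiers")
        if not np.all(np.isfinite(mat.data)):
            raise ValueError("matrix contains non-finite values")
        if self._require_counts:
            if mat.data.size and (np.any(mat.data < 0) or np.any(mat.data != np.round(mat.data))):
                raise ValueError("counts must be nonnegative integers")
            mat = mat.astype(np.int64)
        self.X = mat
        self.cells = cells
        self.features = features

    # -- basic properties -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def feature_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    def to_dense(self) -> np.ndarray:
        return self.X.toarray()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.cells, columns=self.features)

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.X.astype(np.float32),
            obs=pd.DataFrame(index=self.cells.astype(str)),
            var=pd.DataFrame(index=self.features.astype(str)),
        )

    # -- subsetting --------------------------------------------------------
    def _positions(self, index: pd.Index, ids: Iterable) -> np.ndarray:
        ids = list(ids)
        if ids and isinstance(ids[0], (bool, np.bool_)):
            mask = np.asarray(ids, dtype=bool)
            if mask.size != len(index):
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(mask)
        pos = index.get_indexer(ids)
        if np.any(pos < 0):
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"identifiers not found: {missing[:5]}")
        return pos

    def subset_cells(self, cells: Iterable) -> "CellMatrix":
        pos = self._positions(self.cells, cells)
        return type(self)(self.X[pos], self.cells[pos], self.features)

    def subset_features(self, features: Iterable) -> "CellMatrix":
        pos = self._positions(self.features, features)
        return type(self)(self.X[:, pos], self.cells, self.features[pos])

    # -- I/O ---------------------------------------------------------------
    def write_mtx_dir(self, path: str) -> None:
        """Write matrix.mtx (features x cells) + features.tsv + barcodes.tsv."""
        os.makedirs(path, exist_ok=True)
        mmwrite(os.path.join(path, "matrix.mtx"), sp.coo_matrix(self.X.T))
        pd.Series(self.features).to_csv(
            os.path.join(path, "features.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(self.cells).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}({self.n_cells} cells x {self.n_features} features)"


class CountMatrix(CellMatrix):
    """Raw nonnegative integer counts (genes or peaks)."""

    _require_counts = True


def read_mtx_dir(path: str, counts: bool = True) -> CellMatrix:
    """Read a 10x-style directory written by :meth:`CellMatrix.write_mtx_dir`."""
    mat = mmread(os.path.join(path, "matrix.mtx")).T.tocsr()
    features = pd.read_csv(
        os.path.join(path, "features.tsv"), sep="\t", header=None
    )[0].astype(str)
    cells = pd.read_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    cls = CountMatrix if counts else CellMatrix
    return cls(mat, cells, features)
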