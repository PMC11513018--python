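"""Readers and writers for 10x-style MTX triplets, dense CSV/TSV and labels.

Matrices are cells x features everywhere in the public API; MTX triplets on
disk follow the 10x convention of features in rows and are transposed on
read unless told otherwise.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .types import OmicsMatrix


def read_mtx_triplet(
    directory: str | Path,
    modality: str,
    features_in_rows: bool = True,
    matrix_name: str = "matrix.mtx",
    features_name: str = "features.tsv",
    barcodes_name: str = "barcodes.tsv",
) -> OmicsMatrix:
    """Load a MatrixMarket matrix plus features/barcodes TSVs."""
    directory = Path(directory)
    mat = sp.csr_matrix(sio.mmread(directory / matrix_name))
    features = pd.read_csv(directory / features_name, sep="\t", header=None)[0].to_numpy()
    barcodes = pd.read_csv(directory / barcodes_name, sep="\t", header=None)[0].to_numpy()
    if features_in_rows:
        mat = sp.csr_matrix(mat.T)
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(barcodes)} barcodes "
            f"x {len(features)} features"
        )
    return OmicsMatrix(mat, modality=modality, feature_names=features, cell_ids=barcodes)


def write_mtx_triplet(
    X: OmicsMatrix, directory: str | Path, features_in_rows: bool = True
) -> None:
    """Emit a 10x-style triplet (matrix.mtx + features.tsv + barcodes.tsv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(X.values)
    if features_in_rows:
        mat = mat.T
    sio.mmwrite(str(directory / "matrix.mtx"), mat)
    pd.Series(X.feature_names).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(X.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_dense(path: str | Path, modality: str) -> OmicsMatrix:
    """Dense CSV/TSV with cells in rows, a barcode index column and a
    feature-name header."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return OmicsMatrix(
        df.to_numpy(dtype=np.float64),
        modality=modality,
        feature_names=df.columns.to_numpy(),
        cell_ids=df.index.to_numpy(),
    )


def write_dense(X: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    pd.DataFrame(X.dense(), index=X.cell_ids, columns=X.feature_names).to_csv(
        path, sep=sep
    )


def load_matrix(path: str | Path, modality: str, features_in_rows: bool = True) -> OmicsMatrix:
    """Dispatch on path type: a directory means an MTX triplet, a file means
    dense CSV/TSV."""
    path = Path(path)
    if path.is_dir():
        return read_mtx_triplet(path, modality, features_in_rows=features_in_rows)
    return read_dense(path, modality)


def read_labels(path: str | Path) -> pd.Series:
    """Two-column (barcode,label) CSV -> Series indexed by barcode."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("labels file needs barcode and label columns")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())


def write_labels(cell_ids: np.ndarray, labels: np.ndarray, path: str | Path,
                 label_col: str = "label") -> None:
    pd.DataFrame({"barcode": cell_ids, label_col: labels}).to_csv(path, index=False)
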