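"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

Modality = str  # one of {"rna", "atac", "adt"}

_VALID_MODALITIES = ("rna", "atac", "adt")


@dataclass
class OmicsMatrix:
    """A cells x features matrix for one omics modality.

    ``values`` may be a dense ndarray or a scipy sparse matrix; rows are cells,
    columns are features, everywhere in the public API. Raw-count matrices are
    nonnegative; scaled matrices may contain negative values but never NaN/inf.
    """

    values: np.ndarray | sp.spmatrix
    modality: Modality
    feature_names: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.modality not in _VALID_MODALITIES:
            raise ValueError(
                f"modality must be one of {_VALID_MODALITIES}, got {self.modality!r}"
            )
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values, dtype=np.float64)
            if self.values.ndim != 2:
                raise ValueError("values must be a 2-D cells x features matrix")
        n, f = self.values.shape
        if self.feature_names is None:
            self.feature_names = np.array([f"feature_{j}" for j in range(f)])
        else:
            self.feature_names = np.asarray(self.feature_names, dtype=object)
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell_{i}" for i in range(n)])
        else:
            self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.feature_names) != f:
            raise ValueError(
                f"feature_names has length {len(self.feature_names)} but matrix has {f} columns"
            )
        if len(self.cell_ids) != n:
            raise ValueError(
                f"cell_ids has length {len(self.cell_ids)} but matrix has {n} rows"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        """Values as a dense float64 array (copy only if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return self.values

    def with_values(self, values: np.ndarray | sp.spmatrix, **kwargs) -> "OmicsMatrix":
        """A copy with new values (and optionally new metadata)."""
        return replace(self, values=values, **kwargs)

    def subset_features(self, idx: Sequence[int] | np.ndarray) -> "OmicsMatrix":
        idx = np.asarray(idx)
        values = self.values[:, idx]
        return OmicsMatrix(
            values=values,
            modality=self.modality,
            feature_names=self.feature_names[idx],
            cell_ids=self.cell_ids,
        )

    def check_finite(self) -> None:
        vals = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.modality} matrix contains non-finite values")
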