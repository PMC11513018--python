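"""Modality-specific preprocessing.

RNA: prevalence filter -> highly-variable genes -> log-normalise + scale.
ATAC: prevalence filter -> highly-variable peaks -> binarise + TF-IDF.
ADT: log-normalise + scale only (panels are small, 10-200 antibodies).

All steps preserve cell order and are deterministic.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .types import OmicsMatrix

TARGET_SUM = 1e4  # library-size normalisation target per cell
ZSCORE_CLIP = 10.0  # cap on absolute z-scores fed to the model


def filter_low_prevalence(X: OmicsMatrix, min_cell_fraction: float = 0.01) -> OmicsMatrix:
    """Drop features detected in fewer than `min_cell_fraction` of cells."""
    if not 0.0 <= min_cell_fraction < 1.0:
        raise ValueError(
            f"min_cell_fraction must be in [0, 1), got {min_cell_fraction}"
        )
    vals = X.values
    if sp.issparse(vals):
        n_detected = np.asarray((vals > 0).sum(axis=0)).ravel()
    else:
        n_detected = (vals > 0).sum(axis=0)
    keep = n_detected / X.n_cells >= min_cell_fraction
    if not keep.any():
        raise ValueError(
            f"no {X.modality} feature reaches prevalence {min_cell_fraction}; "
            "input is unusable"
        )
    return X.subset_features(np.flatnonzero(keep))


def _normed_log(values: np.ndarray) -> np.ndarray:
    totals = values.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        bad = np.flatnonzero(totals.ravel() == 0)
        raise ValueError(f"cells with zero total count: indices {bad.tolist()}")
    return np.log1p(values / totals * TARGET_SUM)


def select_hvg(X: OmicsMatrix, n_top: int = 3000) -> OmicsMatrix:
    """Keep the `n_top` most dispersed features.

    Dispersion is the per-feature variance of log1p(library-normalised)
    values; ties break toward the lower feature index, so selection is
    fully deterministic.
    """
    if n_top < 1:
        raise ValueError(f"n_top must be >= 1, got {n_top}")
    logged = _normed_log(X.dense())
    dispersion = logged.var(axis=0)
    n_keep = min(n_top, X.n_features)
    # stable sort on negated dispersion -> ties broken by feature index
    order = np.argsort(-dispersion, kind="stable")[:n_keep]
    return X.subset_features(order)


def lognorm_scale(X: OmicsMatrix) -> OmicsMatrix:
    """Library-size normalise, log1p, then z-score each feature.

    Counts are scaled per cell to TARGET_SUM, log(1+x)-transformed, and each
    feature is centred and scaled to unit variance. Constant features become
    all-zero columns; z-scores are clipped to +/- ZSCORE_CLIP.
    """
    values = X.dense()
    if np.any(values < 0):
        raise ValueError("lognorm_scale expects nonnegative counts")
    logged = _normed_log(values)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)  # constant features -> zero column
    z = (logged - mu) / sd_safe
    z = np.clip(z, -ZSCORE_CLIP, ZSCORE_CLIP)
    out = X.with_values(z)
    out.check_finite()
    return out


def binarize_tfidf(X: OmicsMatrix) -> OmicsMatrix:
    """Binarise peaks and weight by TF-IDF, treating cells as documents.

    TF is the row-normalised binary matrix; IDF_j = log(1 + n_cells/(1+df_j))
    where df_j counts cells with peak j open. The transform is idempotent
    under prior binarisation.
    """
    if X.modality != "atac":
        raise ValueError(f"binarize_tfidf expects atac data, got {X.modality!r}")
    values = X.dense()
    if np.any(values < 0):
        raise ValueError("binarize_tfidf expects nonnegative values")
    B = (values > 0).astype(np.float64)
    row_tot = B.sum(axis=1, keepdims=True)
    if np.any(row_tot == 0):
        bad = np.flatnonzero(row_tot.ravel() == 0)
        raise ValueError(f"cells with no open peaks: indices {bad.tolist()}")
    tf = B / row_tot
    df = B.sum(axis=0)
    idf = np.log(1.0 + X.n_cells / (1.0 + df))
    out = X.with_values(tf * idf)
    out.check_finite()
    return out


def preprocess_modality(
    X: OmicsMatrix,
    min_cell_fraction: float = 0.01,
    n_top: int = 3000,
) -> OmicsMatrix:
    """Apply the full preprocessing chain appropriate to `X.modality`."""
    if X.modality == "rna":
        return lognorm_scale(select_hvg(filter_low_prevalence(X, min_cell_fraction), n_top))
    if X.modality == "atac":
        return binarize_tfidf(select_hvg(filter_low_prevalence(X, min_cell_fraction), n_top))
    if X.modality == "adt":
        return lognorm_scale(X)
    raise ValueError(f"unknown modality {X.modality!r}")
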