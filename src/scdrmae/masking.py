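"""Masked-data generation: feature shuffling, Bernoulli masks, and the
convex corruption x = X (1-M) + Xs M.

The corrupted matrix keeps real (shuffled-in) values wherever the mask is
set, so the model must learn cross-feature dependencies to tell corrupted
entries apart from genuine signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import OmicsMatrix

# clip range for per-feature empirical dropout probabilities
_EMPIRICAL_CLIP = (0.05, 0.9)


@dataclass
class MaskedTriple:
    """Original matrix X, shuffled variant Xs, mask M and corrupted input x."""

    original: OmicsMatrix
    shuffled: OmicsMatrix
    mask: np.ndarray
    corrupted: OmicsMatrix
    mask_prob: np.ndarray


def shuffle_features(X: OmicsMatrix, seed: int) -> OmicsMatrix:
    """Independently permute each feature column's values across cells."""
    values = X.dense()
    n = X.n_cells
    rng = np.random.default_rng(seed)
    out = np.empty_like(values)
    for j in range(X.n_features):
        out[:, j] = values[rng.permutation(n), j]
    return X.with_values(out)


def mask_probabilities(
    X: OmicsMatrix, mask_rate: float = 0.3, mode: str = "constant"
) -> np.ndarray:
    """Per-feature corruption probabilities P.

    `constant` uses `mask_rate` for every feature; `empirical` uses each
    feature's observed zero-fraction (a proxy for its dropout propensity),
    clipped to [0.05, 0.9].
    """
    if mode == "constant":
        if not 0.0 <= mask_rate <= 1.0:
            raise ValueError(f"mask_rate must be in [0, 1], got {mask_rate}")
        return np.full(X.n_features, mask_rate)
    if mode == "empirical":
        zero_frac = (X.dense() == 0).mean(axis=0)
        return np.clip(zero_frac, *_EMPIRICAL_CLIP)
    raise ValueError(f"unknown mask-probability mode {mode!r}")


def sample_mask(n_cells: int, mask_prob: np.ndarray, seed: int) -> np.ndarray:
    """Draw M_ij ~ Bernoulli(P_j) independently."""
    mask_prob = np.asarray(mask_prob, dtype=np.float64)
    if np.any(mask_prob < 0) or np.any(mask_prob > 1):
        raise ValueError("mask probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random((n_cells, mask_prob.size)) < mask_prob).astype(np.int8)


def apply_mask(X: OmicsMatrix, Xs: OmicsMatrix, M: np.ndarray) -> MaskedTriple:
    """Combine original and shuffled matrices through the binary mask.

    corrupted = X * (1 - M) + Xs * M, exactly (an algebraic identity, so
    integer inputs survive bit-for-bit).
    """
    M = np.asarray(M)
    if X.shape != Xs.shape or X.shape != M.shape:
        raise ValueError(
            f"shape mismatch: X {X.shape}, Xs {Xs.shape}, M {M.shape}"
        )
    if not np.isin(M, (0, 1)).all():
        raise ValueError("mask entries must be 0 or 1")
    Mf = M.astype(np.float64)
    corrupted = X.dense() * (1.0 - Mf) + Xs.dense() * Mf
    return MaskedTriple(
        original=X,
        shuffled=Xs,
        mask=M.astype(np.int8),
        corrupted=X.with_values(corrupted),
        mask_prob=Mf.mean(axis=0),
    )


def make_masked_input(
    X: OmicsMatrix, mask_prob: np.ndarray, seed: int
) -> MaskedTriple:
    """Shuffle, sample a mask and combine — one fresh corruption pass."""
    ss = np.random.SeedSequence(seed)
    s_shuf, s_mask = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    Xs = shuffle_features(X, seed=s_shuf)
    M = sample_mask(X.n_cells, mask_prob, seed=s_mask)
    triple = apply_mask(X, Xs, M)
    triple.mask_prob = np.asarray(mask_prob, dtype=np.float64)
    return triple
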