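"""Multi-omics integration and clustering refinement.

Concatenates the per-modality latents, passes them through a single-head
self-attention transform over cells, re-injects the RNA latent through a
residual concatenation, and defines the pairwise Student-t soft assignment
Q, its sharpened target P, and the KL self-training loss between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, concat
from .mae_model import LatentRep

ATTENTION_DIM = 128  # width of the concatenated latent [Z_rna, Z_other]
_Q_FLOOR = 1e-12  # clamp under the KL logarithm


@dataclass
class FusedEmbedding:
    """Concatenated latent Z, attention output Zbar, residual concat Zhat."""

    Z: np.ndarray
    Zbar: np.ndarray
    Zhat: np.ndarray


@dataclass
class PairwiseAssignment:
    """Row-stochastic pairwise similarity with a zero diagonal."""

    Q: np.ndarray
    P: np.ndarray | None = None


class AttentionParams:
    """Square Q/K/V maps of width d plus an output bias."""

    def __init__(self, d: int = ATTENTION_DIM, seed: int = 0):
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(d)
        self.d = d
        self.W1 = Tensor(rng.normal(scale=scale, size=(d, d)), requires_grad=True)
        self.W2 = Tensor(rng.normal(scale=scale, size=(d, d)), requires_grad=True)
        self.W3 = Tensor(rng.normal(scale=scale, size=(d, d)), requires_grad=True)
        self.b = Tensor(np.zeros((1, d)), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.W1, self.W2, self.W3, self.b]


def _row_softmax(scores: Tensor) -> Tensor:
    # shift by the (constant) row max for numerical stability
    shifted = scores - scores.data.max(axis=1, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=1, keepdims=True)


def fuse_t(Z_rna: Tensor, Z_other: Tensor, params: AttentionParams) -> tuple[Tensor, Tensor, Tensor]:
    """Tensor-level fusion; returns (Z, Zbar, Zhat) with gradients attached."""
    if Z_rna.shape[0] != Z_other.shape[0]:
        raise ValueError(
            f"cell-count mismatch: {Z_rna.shape[0]} vs {Z_other.shape[0]}"
        )
    Z = concat([Z_rna, Z_other], axis=1)
    if Z.shape[1] != params.d:
        raise ValueError(
            f"concatenated width {Z.shape[1]} does not match attention width {params.d}"
        )
    K = Z @ params.W1
    Qm = Z @ params.W2
    V = Z @ params.W3
    A = _row_softmax((Qm @ K.T) / np.sqrt(params.d))
    Zbar = A @ V + params.b
    Zhat = concat([Z_rna, Zbar], axis=1)
    return Z, Zbar, Zhat


def fuse(Z_rna: LatentRep, Z_other: LatentRep, params: AttentionParams) -> FusedEmbedding:
    Z, Zbar, Zhat = fuse_t(Tensor(Z_rna.values), Tensor(Z_other.values), params)
    return FusedEmbedding(Z=Z.data, Zbar=Zbar.data, Zhat=Zhat.data)


def soft_assign_t(Zhat: Tensor) -> Tensor:
    """Student-t (df=1) pairwise soft assignment with zero diagonal.

    q_ij = (1 + ||z_i - z_j||^2)^-1 normalised over j != i per row.
    """
    n = Zhat.shape[0]
    if n < 2:
        raise ValueError("soft assignment needs at least 2 cells")
    sq = (Zhat**2).sum(axis=1, keepdims=True)
    D = sq + sq.T - 2.0 * (Zhat @ Zhat.T)
    D = D.clamp(lo=0.0)  # guard tiny negative round-off on the diagonal
    kernel = 1.0 / (1.0 + D)
    off = 1.0 - np.eye(n)
    kernel = kernel * off
    return kernel / kernel.sum(axis=1, keepdims=True)


def soft_assign(Zhat: FusedEmbedding | np.ndarray) -> PairwiseAssignment:
    arr = Zhat.Zhat if isinstance(Zhat, FusedEmbedding) else np.asarray(Zhat)
    return PairwiseAssignment(Q=soft_assign_t(Tensor(arr)).data)


def target_distribution(Q: PairwiseAssignment | np.ndarray) -> PairwiseAssignment:
    """Sharpened self-training target P.

    p_ij = (q_ij^2 / f_j) / sum_{l != i} (q_il^2 / f_l) with column mass
    f_j = sum_i q_ij; squaring concentrates each row on its dominant
    neighbours while the 1/f_j factor discounts globally popular cells.
    """
    q = Q.Q if isinstance(Q, PairwiseAssignment) else np.asarray(Q)
    f = q.sum(axis=0)
    f = np.where(f > 0, f, 1.0)
    W = q**2 / f
    np.fill_diagonal(W, 0.0)
    P = W / W.sum(axis=1, keepdims=True)
    return PairwiseAssignment(Q=q, P=P)


def kl_loss(P: np.ndarray | PairwiseAssignment, Q: Tensor | np.ndarray | PairwiseAssignment) -> Tensor:
    """KL(P || Q) = sum_ij p_ij log(p_ij / q_ij), with 0 log 0 := 0."""
    p = P.P if isinstance(P, PairwiseAssignment) else np.asarray(P)
    if isinstance(Q, PairwiseAssignment):
        Q = Q.Q
    q = Q if isinstance(Q, Tensor) else Tensor(np.asarray(Q, dtype=np.float64))
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: P {p.shape}, Q {q.shape}")
    log_p = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    q_safe = q.clamp(lo=_Q_FLOOR)
    # 0 log 0 terms vanish because p multiplies both log factors
    return (Tensor(p * log_p) - q_safe.log() * p).sum()
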