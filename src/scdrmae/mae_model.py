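"""Twin masked autoencoders: encoder, mask decoder, reconstruction decoder,
and the mask-prediction / weighted-reconstruction losses.

One instance handles one modality. The encoder stack is
Dropout -> Linear(f, 256) -> LayerNorm -> Mish -> Linear(256, 64) ->
LayerNorm -> Linear(64, 64); the mask decoder is a single affine map with a
sigmoid; the reconstruction decoder is a single affine map over the
concatenation [mask prediction, latent] with a linear output (inputs are
z-scored and may be negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, concat
from .types import OmicsMatrix

LATENT_DIM = 64
HIDDEN_DIM = 256
MASK_PROB_EPS = 1e-7  # clamp for predicted mask probabilities


@dataclass
class LatentRep:
    """n_cells x 64 low-dimensional representation of one modality."""

    values: np.ndarray
    modality: str


@dataclass
class MaskPrediction:
    """Per-entry probability that the input entry was corrupted."""

    probs: np.ndarray


@dataclass
class ReconWeights:
    """Reconstruction-loss weights for corrupted vs untouched entries."""

    w_masked: float = 2.0
    w_unmasked: float = 1.0

    def __post_init__(self) -> None:
        if self.w_masked <= 0 or self.w_unmasked <= 0:
            raise ValueError("reconstruction weights must be positive")


class _Linear:
    def __init__(self, rng: np.random.Generator, fan_in: int, fan_out: int):
        scale = np.sqrt(2.0 / fan_in)
        self.W = Tensor(rng.normal(scale=scale, size=(fan_in, fan_out)), requires_grad=True)
        self.b = Tensor(np.zeros(fan_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class _LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, dim)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, dim)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        centred = x - mu
        var = (centred**2).mean(axis=1, keepdims=True)
        return centred / (var + self.eps) ** 0.5 * self.gamma + self.beta

    @property
    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class MaskedAutoencoder:
    """Encoder + mask decoder + reconstruction decoder for one modality."""

    def __init__(
        self,
        n_features: int,
        modality: str,
        seed: int = 0,
        input_dropout: float = 0.1,
    ):
        rng = np.random.default_rng(seed)
        self.modality = modality
        self.n_features = n_features
        self.input_dropout = input_dropout
        self._dropout_rng = np.random.default_rng(seed + 1)

        self.enc1 = _Linear(rng, n_features, HIDDEN_DIM)
        self.ln1 = _LayerNorm(HIDDEN_DIM)
        self.enc2 = _Linear(rng, HIDDEN_DIM, LATENT_DIM)
        self.ln2 = _LayerNorm(LATENT_DIM)
        self.enc3 = _Linear(rng, LATENT_DIM, LATENT_DIM)
        self.mask_head = _Linear(rng, LATENT_DIM, n_features)
        self.decoder = _Linear(rng, n_features + LATENT_DIM, n_features)

    @property
    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in (self.enc1, self.ln1, self.enc2, self.ln2, self.enc3,
                      self.mask_head, self.decoder):
            out.extend(layer.params)
        return out

    # -- forward passes -------------------------------------------------------

    def encode_t(self, x: Tensor, train_mode: bool) -> Tensor:
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"input has {x.shape[1]} features, model expects {self.n_features}"
            )
        if train_mode and self.input_dropout > 0:
            keep = (
                self._dropout_rng.random(x.shape) >= self.input_dropout
            ).astype(np.float64)
            x = x * (keep / (1.0 - self.input_dropout))
        h = self.ln1(self.enc1(x)).mish()
        z = self.ln2(self.enc2(h))
        return self.enc3(z)

    def predict_mask_t(self, Z: Tensor) -> Tensor:
        return self.mask_head(Z).sigmoid().clamp(MASK_PROB_EPS, 1.0 - MASK_PROB_EPS)

    def decode_t(self, Mpred: Tensor, Z: Tensor) -> Tensor:
        if Mpred.shape[0] != Z.shape[0]:
            raise ValueError("mask prediction and latent must cover the same cells")
        return self.decoder(concat([Mpred, Z], axis=1))

    # -- ndarray-facing API ---------------------------------------------------

    def encode(self, x: OmicsMatrix | np.ndarray, train_mode: bool = False) -> LatentRep:
        arr = x.dense() if isinstance(x, OmicsMatrix) else np.asarray(x)
        out = self.encode_t(Tensor(arr), train_mode=train_mode)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite latent representation")
        return LatentRep(values=out.data, modality=self.modality)

    def predict_mask(self, Z: LatentRep) -> MaskPrediction:
        return MaskPrediction(probs=self.predict_mask_t(Tensor(Z.values)).data)

    def decode(self, Mpred: MaskPrediction, Z: LatentRep) -> np.ndarray:
        return self.decode_t(Tensor(Mpred.probs), Tensor(Z.values)).data


# -- losses -------------------------------------------------------------------


def mask_loss(M: np.ndarray, Mpred: Tensor | np.ndarray) -> Tensor:
    """Mean binary cross-entropy between the true and predicted masks.

    Implemented as a single fused graph node for speed; the vector-Jacobian
    product is d/dp[-(m log p + (1-m) log(1-p))] = (p - m) / (p (1-p)),
    scaled by the mean.
    """
    Mp = Mpred if isinstance(Mpred, Tensor) else Tensor(np.asarray(Mpred, dtype=np.float64))
    M = np.asarray(M, dtype=np.float64)
    if M.shape != Mp.shape:
        raise ValueError(f"shape mismatch: mask {M.shape}, prediction {Mp.shape}")
    p = np.clip(Mp.data, MASK_PROB_EPS, 1.0 - MASK_PROB_EPS)
    size = M.size
    value = -(M * np.log(p) + (1.0 - M) * np.log1p(-p)).sum() / size

    def backward(g):
        interior = (Mp.data > MASK_PROB_EPS) & (Mp.data < 1.0 - MASK_PROB_EPS)
        Mp._accum(g * interior * (p - M) / (p * (1.0 - p) * size))

    return Tensor._make(value, (Mp,), backward)


def recon_loss(
    X: np.ndarray,
    Xrec: Tensor | np.ndarray,
    M: np.ndarray,
    w: ReconWeights,
) -> Tensor:
    """Weighted mean squared error, up-weighting corrupted entries."""
    Xr = Xrec if isinstance(Xrec, Tensor) else Tensor(np.asarray(Xrec, dtype=np.float64))
    X = np.asarray(X, dtype=np.float64)
    M = np.asarray(M, dtype=np.float64)
    if X.shape != Xr.shape or X.shape != M.shape:
        raise ValueError(
            f"shape mismatch: X {X.shape}, Xrec {Xr.shape}, M {M.shape}"
        )
    W = np.where(M == 1, w.w_masked, w.w_unmasked)
    diff = Xr.data - X
    value = (W * diff**2).sum() / X.size

    def backward(g):
        Xr._accum(g * 2.0 * W * diff / X.size)

    return Tensor._make(value, (Xr,), backward)
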