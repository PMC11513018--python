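"""End-to-end optimisation of the twin autoencoders and attention fusion.

Two phases: reconstruction pretraining (mask-prediction + weighted
reconstruction losses, fresh corruption every epoch), then KL-refined
fine-tuning in which the pairwise self-training target P is refreshed at a
fixed interval and gradients from all three terms flow through encoders and
attention alike. Each epoch sweeps the data in shuffled minibatches for the
autoencoder losses and takes one pairwise-KL step on the anchor set; above
`full_batch_max` cells the anchor set is a seeded subsample so the pairwise
objective stays tractable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np
import pandas as pd

from ._autograd import Adam, Tensor
from .fusion_cluster import (
    ATTENTION_DIM,
    AttentionParams,
    FusedEmbedding,
    fuse,
    fuse_t,
    kl_loss,
    soft_assign_t,
    target_distribution,
)
from .mae_model import MaskedAutoencoder, ReconWeights, mask_loss, recon_loss
from .masking import make_masked_input, mask_probabilities
from .types import OmicsMatrix

# hyperparameter presets (epochs, learning rate)
PROFILES: dict[str, dict[str, float]] = {
    "default": {"epochs": 100, "lr": 0.002},
    "small": {"epochs": 20, "lr": 0.001},
    "cellline": {"epochs": 50, "lr": 0.001},
    "pbmc10k": {"epochs": 20, "lr": 0.002},
}


@dataclass
class RunConfig:
    """Hyperparameters for one training run."""

    k: int = 4
    epochs: int = 100
    lr: float = 0.002
    mask_rate: float = 0.3
    mask_mode: str = "constant"  # or "empirical"
    w_masked: float = 2.0
    w_unmasked: float = 1.0
    kl_weight: float = 1.0
    kl_start_epoch: int | None = None  # defaults to epochs // 2
    p_update_interval: int = 20
    input_dropout: float = 0.1
    seed: int = 0
    device: str = "cpu"
    batch_size: int = 128
    full_batch_max: int = 10_000
    anchor_cells: int = 2048

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must be in [0, 1]")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be nonnegative")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def kl_start(self) -> float:
        return self.epochs // 2 if self.kl_start_epoch is None else self.kl_start_epoch

    @classmethod
    def from_profile(cls, profile: str, **overrides) -> "RunConfig":
        if profile not in PROFILES:
            raise ValueError(
                f"unknown profile {profile!r}; choose from {sorted(PROFILES)}"
            )
        params = dict(PROFILES[profile])
        params.update(overrides)
        return cls(**params)  # type: ignore[arg-type]


@dataclass
class FitResult:
    """Trained parameters, final embedding and per-epoch loss history."""

    rna_model: MaskedAutoencoder
    other_model: MaskedAutoencoder
    attention: AttentionParams
    embedding: FusedEmbedding
    history: pd.DataFrame
    config: RunConfig

    def save(self, path) -> None:
        """Serialise all parameters and the config to one .npz checkpoint."""
        arrays = {}
        for tag, model in (("rna", self.rna_model), ("other", self.other_model)):
            for i, p in enumerate(model.params):
                arrays[f"{tag}_{i}"] = p.data
        for i, p in enumerate(self.attention.params):
            arrays[f"attn_{i}"] = p.data
        arrays["meta"] = np.frombuffer(
            json.dumps(
                {
                    "config": asdict(self.config),
                    "rna_features": self.rna_model.n_features,
                    "other_features": self.other_model.n_features,
                    "other_modality": self.other_model.modality,
                }
            ).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "FitResult":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]))
        config = RunConfig(**meta["config"])
        rna_model = MaskedAutoencoder(
            meta["rna_features"], "rna", input_dropout=config.input_dropout
        )
        other_model = MaskedAutoencoder(
            meta["other_features"], meta["other_modality"],
            input_dropout=config.input_dropout,
        )
        attention = AttentionParams(d=ATTENTION_DIM)
        for tag, model in (("rna", rna_model), ("other", other_model)):
            for i, p in enumerate(model.params):
                p.data = data[f"{tag}_{i}"]
        for i, p in enumerate(attention.params):
            p.data = data[f"attn_{i}"]
        return cls(
            rna_model=rna_model,
            other_model=other_model,
            attention=attention,
            embedding=None,  # recomputed on demand via embed()
            history=pd.DataFrame(),
            config=config,
        )

    def embed(self, rna: OmicsMatrix, other: OmicsMatrix) -> FusedEmbedding:
        """Fused embedding of (preprocessed) inputs in eval mode."""
        z_r = self.rna_model.encode(rna, train_mode=False)
        z_o = self.other_model.encode(other, train_mode=False)
        return fuse(z_r, z_o, self.attention)


def _epoch_seed(base: int, epoch: int, stream: int) -> int:
    return int((base + 1_000_003 * epoch + 7919 * stream) % 2**31)


def fit(
    rna: OmicsMatrix,
    other: OmicsMatrix,
    config: RunConfig,
    log_fn: Callable[[str], None] | None = None,
) -> FitResult:
    """Train the full model on preprocessed paired matrices."""
    if rna.n_cells != other.n_cells:
        raise ValueError("modalities must cover the same cells")
    rna.check_finite()
    other.check_finite()
    n = rna.n_cells

    ss = np.random.SeedSequence(config.seed)
    s_rna, s_other, s_attn, s_mask, s_anchor = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)
    )

    rna_model = MaskedAutoencoder(
        rna.n_features, "rna", seed=s_rna, input_dropout=config.input_dropout
    )
    other_model = MaskedAutoencoder(
        other.n_features, other.modality, seed=s_other,
        input_dropout=config.input_dropout,
    )
    attention = AttentionParams(d=ATTENTION_DIM, seed=s_attn)
    params = rna_model.params + other_model.params + attention.params
    opt = Adam(params, lr=config.lr)
    weights = ReconWeights(config.w_masked, config.w_unmasked)

    P_rna = mask_probabilities(rna, config.mask_rate, config.mask_mode)
    P_other = mask_probabilities(other, config.mask_rate, config.mask_mode)
    X_rna = rna.dense()
    X_other = other.dense()

    # cells entering the pairwise KL objective
    if n > config.full_batch_max:
        anchor = np.random.default_rng(s_anchor).choice(
            n, size=min(config.anchor_cells, n), replace=False
        )
    else:
        anchor = np.arange(n)

    target_P: np.ndarray | None = None
    batch_rng = np.random.default_rng(_epoch_seed(s_mask, 0, 2))
    rows = []
    for epoch in range(config.epochs):
        t_rna = make_masked_input(rna, P_rna, seed=_epoch_seed(s_mask, epoch, 0))
        t_other = make_masked_input(other, P_other, seed=_epoch_seed(s_mask, epoch, 1))
        Xc_rna = t_rna.corrupted.dense()
        Xc_other = t_other.corrupted.dense()

        # minibatch sweep over the fresh corruption of this epoch
        perm = batch_rng.permutation(n)
        mask_sum = recon_sum = 0.0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            z_r = rna_model.encode_t(Tensor(Xc_rna[idx]), train_mode=True)
            z_o = other_model.encode_t(Tensor(Xc_other[idx]), train_mode=True)
            mp_r = rna_model.predict_mask_t(z_r)
            mp_o = other_model.predict_mask_t(z_o)
            rec_r = rna_model.decode_t(mp_r, z_r)
            rec_o = other_model.decode_t(mp_o, z_o)

            l_mask = mask_loss(t_rna.mask[idx], mp_r) + mask_loss(
                t_other.mask[idx], mp_o
            )
            l_recon = recon_loss(X_rna[idx], rec_r, t_rna.mask[idx], weights) + recon_loss(
                X_other[idx], rec_o, t_other.mask[idx], weights
            )
            batch_total = l_mask + l_recon
            if not np.isfinite(batch_total.data):
                raise FloatingPointError(
                    f"non-finite mask/reconstruction loss at epoch {epoch}"
                )
            opt.zero_grad()
            batch_total.backward()
            opt.step()
            mask_sum += float(l_mask.data)
            recon_sum += float(l_recon.data)
            n_batches += 1

        # pairwise KL refinement on the anchor set, one step per epoch
        kl_active = epoch >= config.kl_start and config.kl_weight > 0
        if kl_active:
            z_r = rna_model.encode_t(Tensor(Xc_rna[anchor]), train_mode=True)
            z_o = other_model.encode_t(Tensor(Xc_other[anchor]), train_mode=True)
            _, _, zhat = fuse_t(z_r, z_o, attention)
            q = soft_assign_t(zhat)
            refresh = (epoch - config.kl_start) % config.p_update_interval == 0
            if target_P is None or refresh:
                target_P = target_distribution(q.data).P
            l_kl = kl_loss(target_P, q)
            if not np.isfinite(l_kl.data):
                raise FloatingPointError(f"non-finite kl loss at epoch {epoch}")
            kl_step = config.kl_weight * l_kl
            opt.zero_grad()
            kl_step.backward()
            opt.step()
            kl_value = float(l_kl.data)
        else:
            kl_value = 0.0

        rows.append(
            {
                "epoch": epoch,
                "loss_mask": mask_sum / n_batches,
                "loss_recon": recon_sum / n_batches,
                "loss_kl": kl_value,
                "loss_total": mask_sum / n_batches
                + recon_sum / n_batches
                + config.kl_weight * kl_value,
            }
        )
        if log_fn is not None:
            r = rows[-1]
            log_fn(
                f"epoch={epoch} L_M={r['loss_mask']:.4f} "
                f"L_R={r['loss_recon']:.4f} L_kl={r['loss_kl']:.4f} "
                f"total={r['loss_total']:.4f}"
            )

    result = FitResult(
        rna_model=rna_model,
        other_model=other_model,
        attention=attention,
        embedding=None,  # set below
        history=pd.DataFrame(rows),
        config=config,
    )
    result.embedding = result.embed(rna, other)
    return result


def impute(
    fit_result: FitResult, rna: OmicsMatrix, other: OmicsMatrix
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Reconstruct both modalities from their uncorrupted inputs.

    The encoder runs in eval mode on the clean (preprocessed) matrices; the
    decoder output is the denoised/imputed matrix in scaled-data space.
    """
    out = []
    for model, X in ((fit_result.rna_model, rna), (fit_result.other_model, other)):
        if X.n_features != model.n_features:
            raise ValueError(
                f"{X.modality} width {X.n_features} does not match the trained "
                f"model ({model.n_features})"
            )
        z = model.encode(X, train_mode=False)
        mp = model.predict_mask(z)
        rec = model.decode(mp, z)
        out.append(X.with_values(rec))
    return out[0], out[1]
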