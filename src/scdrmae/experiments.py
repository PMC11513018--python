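"""Reference experiments on the bundled synthetic fixtures.

Each function regenerates its data, runs the pipeline and returns measured
quantities; they are shared by the test battery and the reproduction
script. Problem sizes are desk-scale (500 cells, a few hundred features)
so a full experiment finishes in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from . import pipeline, synthdata
from .evaluation import clustering_metrics, kmeans_cluster
from .masking import make_masked_input, mask_probabilities
from .training import RunConfig, fit, impute

# the mask-learnability probe trains far longer than the clustering runs:
# at 500 cells an epoch is only ~8 gradient updates, and the mask decoder
# needs several thousand updates before entry-level detection emerges
MASK_PROBE_EPOCHS = 800
MASK_PROBE_BATCH = 64


def cluster_recovery(seeds=range(5), dropout_rate: float = 0.3, epochs: int = 100,
                     base_seed: int = 0) -> list[float]:
    """Full-pipeline ARI on the standard well-separated fixture, per seed."""
    aris = []
    for s in seeds:
        ds = synthdata.standard_fixture(dropout_rate=dropout_rate, seed=base_seed + s)
        res = pipeline.run(
            ds.rna, ds.other,
            RunConfig(k=4, epochs=epochs, seed=base_seed + s),
            truth=ds.labels,
        )
        aris.append(res.metrics.ari)
    return aris


def unseparable_ari(seed: int = 0, epochs: int = 100) -> float:
    """Pipeline ARI on a fixture with no cluster signal (should be ~0)."""
    ds = synthdata.unseparable_fixture(seed=seed)
    res = pipeline.run(
        ds.rna, ds.other, RunConfig(k=4, epochs=epochs, seed=seed), truth=ds.labels
    )
    return res.metrics.ari


def dropout_sweep(rates=(0.0, 0.3, 0.6, 0.9), seeds=range(5), base_seed: int = 0,
                  profile: str = "small") -> dict[float, list[float]]:
    """ARI of the full pipeline at increasing dropout on the standard
    fixture; the short preset keeps the 20-run sweep fast."""
    out: dict[float, list[float]] = {}
    for rate in rates:
        out[rate] = []
        for s in seeds:
            ds = synthdata.standard_fixture(dropout_rate=rate, seed=base_seed + s)
            res = pipeline.run(
                ds.rna, ds.other,
                RunConfig.from_profile(profile, k=4, seed=base_seed + s),
                truth=ds.labels,
            )
            out[rate].append(res.metrics.ari)
    return out


def imputation_benefit(seeds=range(20), dropout_rate: float = 0.6,
                       base_seed: int = 0, epochs: int = 100) -> dict[str, list[float]]:
    """K-means ARI on the RNA matrix before vs after model imputation.

    The weakly separated fixture is used so that dropout actually hurts the
    corrupted baseline; both matrices are clustered identically. The model
    is trained on the reconstruction objective alone: the KL refinement
    optimises the embedding for cluster compactness at the expense of
    reconstruction calibration, and imputation reads the decoder output.
    """
    corrupted, imputed = [], []
    for s in seeds:
        seed = base_seed + s
        ds = synthdata.imputation_fixture(dropout_rate=dropout_rate, seed=seed)
        res = pipeline.run(
            ds.rna, ds.other,
            RunConfig(k=4, epochs=epochs, seed=seed, kl_weight=0.0),
            truth=ds.labels,
        )
        rna_imp, _ = impute(res.fit, res.rna_processed, res.other_processed)
        a_corr = clustering_metrics(
            ds.labels, kmeans_cluster(res.rna_processed.dense(), 4, seed=seed).labels
        ).ari
        a_imp = clustering_metrics(
            ds.labels, kmeans_cluster(rna_imp.dense(), 4, seed=seed).labels
        ).ari
        corrupted.append(a_corr)
        imputed.append(a_imp)
    return {"corrupted": corrupted, "imputed": imputed}


def mask_auroc(seed: int = 0, mask_rate: float = 0.3) -> float:
    """Train on the mask-probe fixture, then score a held-out fresh mask.

    The probe trains the reconstruction phase only (the KL refinement
    compacts embeddings toward cluster prototypes and discards the
    entry-level signal this probe measures) and is evaluated on the
    low-dimensional protein panel.
    """
    ds = synthdata.mask_probe_fixture(seed=seed)
    from .preprocess import preprocess_modality

    rna = preprocess_modality(ds.rna)
    other = preprocess_modality(ds.other)
    cfg = RunConfig(
        k=8, epochs=MASK_PROBE_EPOCHS, batch_size=MASK_PROBE_BATCH,
        mask_rate=mask_rate, kl_weight=0.0, seed=seed,
    )
    res = fit(rna, other, cfg)
    P = mask_probabilities(other, mask_rate)
    fresh = make_masked_input(other, P, seed=seed + 987_654)
    z = res.other_model.encode(fresh.corrupted, train_mode=False)
    probs = res.other_model.predict_mask(z).probs
    return float(roc_auc_score(fresh.mask.ravel(), probs.ravel()))
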