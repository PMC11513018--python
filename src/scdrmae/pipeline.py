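"""Library-level composition of the full workflow:
preprocess -> mask/train -> fuse -> K-means -> metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocess
from .evaluation import ClusterResult, MetricReport, clustering_metrics, kmeans_cluster
from .training import FitResult, RunConfig, fit
from .types import OmicsMatrix


@dataclass
class PipelineResult:
    fit: FitResult
    clusters: ClusterResult
    metrics: MetricReport | None
    rna_processed: OmicsMatrix
    other_processed: OmicsMatrix


def run(
    rna_raw: OmicsMatrix,
    other_raw: OmicsMatrix,
    config: RunConfig,
    truth: np.ndarray | None = None,
    min_cell_fraction: float = 0.01,
    n_top: int = 3000,
    log_fn=None,
) -> PipelineResult:
    """Run the complete pipeline on raw count matrices.

    `truth` enables the evaluation step; `config.k` sets the number of
    clusters for the K-means readout.
    """
    rna_p = preprocess.preprocess_modality(rna_raw, min_cell_fraction, n_top)
    other_p = preprocess.preprocess_modality(other_raw, min_cell_fraction, n_top)
    fit_result = fit(rna_p, other_p, config, log_fn=log_fn)
    clusters = kmeans_cluster(fit_result.embedding, k=config.k, seed=config.seed)
    metrics = None
    if truth is not None:
        metrics = clustering_metrics(truth, clusters.labels)
    return PipelineResult(
        fit=fit_result,
        clusters=clusters,
        metrics=metrics,
        rna_processed=rna_p,
        other_processed=other_p,
    )
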