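"""Clustering readout and evaluation.

K-means on the fused embedding; ARI via the pair-count closed form, NMI and
AMI from the contingency table with the hypergeometric expected mutual
information; per-cluster marker ranking by the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import false_discovery_control, norm, rankdata
from sklearn.cluster import KMeans

from .fusion_cluster import FusedEmbedding
from .types import OmicsMatrix


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    seed: int


@dataclass
class MetricReport:
    """Agreement between a predicted and a reference partition.

    ``pair_counts`` = (a, b, c, d): over all unordered cell pairs, together
    in both partitions / together only in truth / together only in the
    prediction / separate in both.
    """

    ari: float
    nmi: float
    ami: float
    pair_counts: tuple[int, int, int, int]

    def as_dict(self) -> dict[str, float]:
        return {"ari": self.ari, "nmi": self.nmi, "ami": self.ami}


def kmeans_cluster(
    Zhat: FusedEmbedding | np.ndarray, k: int, seed: int = 0, n_init: int = 20
) -> ClusterResult:
    """Lloyd's algorithm with k-means++ seeding, best of `n_init` restarts."""
    X = Zhat.Zhat if isinstance(Zhat, FusedEmbedding) else np.asarray(Zhat)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of cells ({X.shape[0]})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterResult(labels=labels, k=k, seed=seed)


# -- agreement metrics --------------------------------------------------------


def _contingency(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    C = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(C, (ti, pi), 1)
    return C


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) // 2


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_information(C: np.ndarray) -> float:
    n = C.sum()
    outer = C.sum(axis=1, keepdims=True) * C.sum(axis=0, keepdims=True)
    nz = C > 0
    vals = C[nz] / n * np.log(C[nz] * n / outer[nz])
    return float(vals.sum())


def _expected_mi(C: np.ndarray) -> float:
    """Expected MI of two partitions with these margins under the
    hypergeometric model of random labelings."""
    n = int(C.sum())
    a = C.sum(axis=1)
    b = C.sum(axis=0)
    gln = gammaln
    total = 0.0
    log_n_fact = gln(n + 1)
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term1 = nij / n * (np.log(nij) + np.log(n) - np.log(ai) - np.log(bj))
            log_pmf = (
                gln(ai + 1)
                + gln(bj + 1)
                + gln(n - ai + 1)
                + gln(n - bj + 1)
                - log_n_fact
                - gln(nij + 1)
                - gln(ai - nij + 1)
                - gln(bj - nij + 1)
                - gln(n - ai - bj + nij + 1)
            )
            total += float((term1 * np.exp(log_pmf)).sum())
    return total


def clustering_metrics(truth: np.ndarray, pred: np.ndarray) -> MetricReport:
    """ARI, NMI and AMI between a reference and a predicted labeling.

    ARI uses the pair-count closed form 2(ad - bc) / [(a+b)(b+d) + (a+c)(c+d)];
    NMI = 2 MI / (H(U) + H(V)); AMI subtracts the hypergeometric expected MI
    and normalises by the arithmetic mean of the entropies. All metrics are
    invariant to relabeling of either partition.
    """
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.shape != pred.shape:
        raise ValueError(
            f"label vectors differ in length: {truth.shape[0]} vs {pred.shape[0]}"
        )
    n = truth.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to compare partitions")

    C = _contingency(truth, pred)
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    total_pairs = n * (n - 1) // 2
    a = int(_comb2(C).sum())
    ab = int(_comb2(row).sum())  # pairs together in truth
    ac = int(_comb2(col).sum())  # pairs together in prediction
    b = ab - a
    c = ac - a
    d = total_pairs - a - b - c

    denom = (a + b) * (b + d) + (a + c) * (c + d)
    ari = 1.0 if denom == 0 else 2.0 * (a * d - b * c) / denom

    hu = _entropy(row)
    hv = _entropy(col)
    mi = _mutual_information(C)
    nmi = 1.0 if hu + hv == 0 else 2.0 * mi / (hu + hv)

    emi = _expected_mi(C)
    ami_denom = 0.5 * (hu + hv) - emi
    ami = 1.0 if abs(ami_denom) < 1e-15 else (mi - emi) / ami_denom

    # guard round-off excursions outside the defined ranges
    return MetricReport(
        ari=float(np.clip(ari, -1.0, 1.0)),
        nmi=float(np.clip(nmi, 0.0, 1.0)),
        ami=float(np.clip(ami, -1.0, 1.0)),
        pair_counts=(a, b, c, d),
    )


# -- marker ranking -----------------------------------------------------------


def _ranksum_z(values: np.ndarray, in_group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sample Wilcoxon rank-sum z over feature columns.

    Normal approximation with tie correction; positive z means the feature
    is larger inside the group. Returns (z, two-sided p).
    """
    n, f = values.shape
    n1 = int(in_group.sum())
    n2 = n - n1
    ranks = rankdata(values, axis=0)
    R1 = ranks[in_group].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    tie_term = np.empty(f)
    for j in range(f):
        _, counts = np.unique(values[:, j], return_counts=True)
        tie_term[j] = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (R1 - mu) / sigma, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    return z, p


def rank_markers(
    X: OmicsMatrix, labels: np.ndarray, top_n: int = 3
) -> pd.DataFrame:
    """Top differential features per cluster by Wilcoxon rank-sum.

    Each cluster is tested one-vs-rest per feature; features are ranked by
    the greater-in-cluster one-sided z statistic (ties broken by feature
    index) and the two-sided p-value is reported together with a
    Benjamini-Hochberg adjusted column (per cluster; ranking is unaffected).
    Clusters with fewer than 2 cells are skipped with a warning.
    """
    labels = np.asarray(labels).ravel()
    if labels.shape[0] != X.n_cells:
        raise ValueError("labels length must equal the cell count")
    values = X.dense()
    rows = []
    for cluster in np.unique(labels):
        in_group = labels == cluster
        if in_group.sum() < 2 or (~in_group).sum() < 1:
            warnings.warn(
                f"cluster {cluster} has fewer than 2 cells; skipped", stacklevel=2
            )
            continue
        z, p = _ranksum_z(values, in_group)
        p_adj = false_discovery_control(p, method="bh")
        order = np.lexsort((np.arange(len(z)), -z))[:top_n]
        for rank, j in enumerate(order, start=1):
            rows.append(
                {
                    "cluster": cluster,
                    "rank": rank,
                    "feature": X.feature_names[j],
                    "statistic": float(z[j]),
                    "p": float(p[j]),
                    "p_adj": float(p_adj[j]),
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "rank", "feature", "statistic", "p", "p_adj"])
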