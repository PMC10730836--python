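"""Two-cluster consensus subtyping on a signature gene set."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class SignatureGeneSet:
    """Marker genes defining the two subtypes; sets must be disjoint."""

    basal_markers: list[str]
    classical_markers: list[str]

    def __post_init__(self) -> None:
        if not self.basal_markers or not self.classical_markers:
            raise ValueError("both marker sets must be non-empty")
        overlap = set(self.basal_markers) & set(self.classical_markers)
        if overlap:
            raise ValueError(f"marker sets overlap: {sorted(overlap)}")

    @property
    def all_genes(self) -> list[str]:
        return list(self.basal_markers) + list(self.classical_markers)


@dataclass
class ConsensusResult:
    consensus_matrix: pd.DataFrame  # samples x samples co-assignment frequency
    final_labels: pd.Series  # sample -> cluster {1, 2}
    n_resamples: int
    seed: int | None
    degenerate: bool = False


@dataclass
class SubtypeAssignment:
    labels: pd.Series  # sample -> {"basal-like", "classical"}
    cluster_marker_means: pd.DataFrame  # cluster x (basal, classical) mean z-expr
    unlabeled: bool = False


def consensus_cluster(
    expr: pd.DataFrame,
    k: int = 2,
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int | None = None,
) -> ConsensusResult:
    """Consensus clustering of samples by repeated subsampled k-means.

    ``expr`` is genes x samples on the signature gene set.  Genes are z-scored
    across samples; each resample draws ceil(frac * n) samples without
    replacement, clusters them with k-means, and co-assignment counts are
    accumulated and normalized by co-sampling counts.  Final labels come from
    average-linkage hierarchical clustering of (1 - consensus) cut at k.
    Deterministic given ``seed``.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    samples = list(expr.columns)
    n = len(samples)

    sd = expr.std(axis=1, ddof=1)
    dropped = sd[sd == 0].index
    if len(dropped):
        logger.warning("dropping %d zero-variance genes: %s", len(dropped), list(dropped)[:5])
    expr = expr.loc[sd > 0]
    if expr.shape[0] == 0:
        consensus = pd.DataFrame(np.ones((n, n)), index=samples, columns=samples)
        labels = pd.Series(1, index=samples)
        return ConsensusResult(consensus, labels, n_resamples, seed, degenerate=True)

    z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1, ddof=1), axis=0)
    x = z.values.T  # samples x genes

    rng = np.random.default_rng(seed)
    m = math.ceil(subsample_frac * n)
    co_assign = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(n_clusters=k, n_init=2, random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(x[idx])
        co_sample[np.ix_(idx, idx)] += 1
        for c in range(k):
            members = idx[lab == c]
            co_assign[np.ix_(members, members)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_assign / np.maximum(co_sample, 1), 0.0)
    consensus = (consensus + consensus.T) / 2
    np.fill_diagonal(consensus, 1.0)
    consensus = np.clip(consensus, 0.0, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    lk = linkage(squareform(dist, checks=False), method="average")
    labels = pd.Series(fcluster(lk, t=k, criterion="maxclust"), index=samples)

    degenerate = labels.nunique() < k
    cm = pd.DataFrame(consensus, index=samples, columns=samples)
    return ConsensusResult(cm, labels, n_resamples, seed, degenerate=degenerate)


def assign_subtype_labels(
    result: ConsensusResult,
    expr: pd.DataFrame,
    signature: SignatureGeneSet,
) -> SubtypeAssignment:
    """Name the two clusters: the one with higher mean standardized
    basal-marker expression is basal-like, the other classical."""
    missing = [g for g in signature.all_genes if g not in expr.index]
    if missing:
        raise ValueError(f"signature genes absent from expression: {missing[:5]}")
    clusters = sorted(result.final_labels.unique())
    if len(clusters) != 2:
        raise ValueError(f"expected 2 clusters, found {len(clusters)}")

    sub = expr.loc[signature.all_genes]
    sd = sub.std(axis=1, ddof=1).replace(0, np.nan)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)

    means = {}
    for c in clusters:
        cols = result.final_labels.index[result.final_labels == c]
        means[c] = {
            "basal": float(z.loc[signature.basal_markers, cols].mean().mean()),
            "classical": float(z.loc[signature.classical_markers, cols].mean().mean()),
        }
    marker_means = pd.DataFrame(means).T

    diff = marker_means.loc[clusters[0], "basal"] - marker_means.loc[clusters[1], "basal"]
    if diff == 0 or np.isnan(diff):
        labels = pd.Series("unlabeled", index=result.final_labels.index)
        return SubtypeAssignment(labels, marker_means, unlabeled=True)
    basal_cluster = clusters[0] if diff > 0 else clusters[1]
    labels = result.final_labels.map(
        lambda c: "basal-like" if c == basal_cluster else "classical"
    )
    return SubtypeAssignment(labels, marker_means, unlabeled=False)
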