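"""Resampling consensus clustering, CDF/delta-area K selection, and
nearest-centroid projection.

Tumor samples are clustered repeatedly on random subsets of samples and
signature genes with k-means (Euclidean distance); the consensus matrix
records, for every sample pair, the proportion of co-clustering runs among
runs in which both were drawn.  The number of clusters K is chosen from the
relative change in the area under the empirical CDF of consensus values, and
final labels come from average-linkage hierarchical clustering of the
consensus dissimilarity.  Discovered clusters are projected onto replication
cohorts by nearest centroid under Spearman rank correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusParams",
    "ConsensusKResult",
    "ConsensusResult",
    "CentroidModel",
    "consensus_cluster",
    "consensus_sweep",
    "consensus_cdf_auc",
    "cdf_and_delta",
    "select_k",
    "cluster_genes_onepass",
    "centroid_fit",
    "centroid_predict",
]


@dataclass(frozen=True)
class ConsensusParams:
    """Protocol parameters: k-means base clusterer, 80% sample/gene resampling."""

    k_max: int = 12
    reps: int = 5000
    p_item: float = 0.8
    p_feature: float = 0.8
    k_genes: int = 4
    n_init: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for name in ("p_item", "p_feature"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class ConsensusKResult:
    """Consensus matrix and final labels for one candidate K."""

    k: int
    consensus: np.ndarray          # n x n in [0, 1], symmetric, unit diagonal
    labels: np.ndarray             # in {1..k}
    samples: tuple

    def labels_series(self) -> pd.Series:
        return pd.Series(self.labels, index=list(self.samples), name="cluster")


@dataclass
class ConsensusResult:
    """Sweep over K = 2..k_max with CDF areas and the selected K."""

    by_k: dict
    auc: dict
    delta: dict
    k_selected: int

    @property
    def selected(self) -> ConsensusKResult:
        return self.by_k[self.k_selected]


@dataclass
class CentroidModel:
    """Per-cluster mean standardized expression over the signature genes."""

    centroids: pd.DataFrame        # genes x clusters
    cohort: str = ""

    @property
    def genes(self) -> pd.Index:
        return self.centroids.index

    @property
    def clusters(self) -> list:
        return list(self.centroids.columns)


def _assert_consensus_valid(M: np.ndarray) -> None:
    if not np.allclose(M, M.T, atol=1e-12):
        raise AssertionError("consensus matrix is not symmetric")
    if not np.allclose(np.diag(M), 1.0):
        raise AssertionError("consensus matrix diagonal is not 1")
    if M.min() < -1e-12 or M.max() > 1 + 1e-12:
        raise AssertionError("consensus entries outside [0, 1]")


def consensus_cluster(
    X: ExpressionMatrix, k: int, params: ConsensusParams = ConsensusParams()
) -> ConsensusKResult:
    """Consensus matrix and labels for one K.

    Each repetition subsamples ceil(p_item*n) samples and ceil(p_feature*g)
    genes, runs k-means (k-means++ init, ``n_init`` restarts, a
    repetition-indexed RNG substream), and accumulates co-cluster and
    co-sampling counts; the consensus is their ratio.  Final labels cut an
    average-linkage dendrogram of (1 - consensus) at ``k``.
    """
    if X.state != "standardized":
        raise ValueError("consensus clustering expects standardized expression")
    n = X.n_samples
    g = len(X.genes)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, got {n}")
    data = X.values.to_numpy().T  # samples x genes
    n_item = int(np.ceil(params.p_item * n))
    n_feat = int(np.ceil(params.p_feature * g))

    conn = np.zeros((n, n))
    co = np.zeros((n, n))
    for rep in range(params.reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(k, rep))
        )
        items = np.sort(rng.choice(n, size=n_item, replace=False))
        feats = rng.choice(g, size=n_feat, replace=False) if n_feat < g else np.arange(g)
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=params.n_init,
            random_state=int(rng.integers(2**31)),
        )
        lab = km.fit_predict(data[np.ix_(items, feats)])
        co[np.ix_(items, items)] += 1
        for c in range(k):
            members = items[lab == c]
            conn[np.ix_(members, members)] += 1

    never = (co == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} sample pair(s) never co-sampled; "
            "their consensus is set to 0 (increase reps)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(co > 0, conn / np.where(co > 0, co, 1), 0.0)
    np.fill_diagonal(M, 1.0)
    M = (M + M.T) / 2.0
    _assert_consensus_valid(M)

    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ConsensusKResult(k=k, consensus=M, labels=labels, samples=tuple(X.samples))


def consensus_cdf_auc(M: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle consensus entries.

    With sorted distinct values u_0 < ... < u_m augmented by {0, 1}:
    AUC = sum_j (u_j - u_{j-1}) * CDF(u_{j-1}).
    """
    vals = M[np.triu_indices(M.shape[0], k=1)]
    grid = np.unique(np.concatenate([[0.0], vals, [1.0]]))
    cdf = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
    return float(np.sum(np.diff(grid) * cdf[:-1]))


def cdf_and_delta(matrices: dict) -> tuple:
    """(AUC per K, relative delta-area per K) for consecutive K values.

    delta(k_min) = AUC(k_min); delta(K) = (AUC(K) - AUC(K-1)) / AUC(K-1).
    """
    ks = sorted(matrices)
    if len(ks) < 2:
        raise ValueError("need consensus matrices for at least two K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    auc = {k: consensus_cdf_auc(matrices[k]) for k in ks}
    delta = {ks[0]: auc[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        if auc[prev] <= 0:
            delta[k] = float("inf") if auc[k] > 0 else 0.0
        else:
            delta[k] = (auc[k] - auc[prev]) / auc[prev]
    return auc, delta


def select_k(delta: dict, threshold: float = 0.03, override: int | None = None) -> int:
    """Largest K whose relative delta-area meets ``threshold``.

    ``override`` forces a K (logged), mirroring selection by visual
    inspection of the consensus matrices.  If no K passes, returns the
    smallest candidate with a warning.
    """
    if override is not None:
        logger.info("select_k: manual override K=%d (delta rule ignored)", override)
        if override not in delta:
            raise ValueError(f"override K={override} has no consensus result")
        return int(override)
    passing = [k for k, d in delta.items() if d >= threshold]
    if not passing:
        k0 = min(delta)
        warnings.warn(
            f"no K reached delta-area >= {threshold}; falling back to K={k0}", stacklevel=2
        )
        return int(k0)
    return int(max(passing))


def consensus_sweep(
    X: ExpressionMatrix,
    params: ConsensusParams = ConsensusParams(),
    threshold: float = 0.03,
    k_override: int | None = None,
) -> ConsensusResult:
    """Run consensus clustering for K = 2..k_max and select K."""
    k_max = min(params.k_max, X.n_samples - 1)
    by_k = {k: consensus_cluster(X, k, params) for k in range(2, k_max + 1)}
    auc, delta = cdf_and_delta({k: r.consensus for k, r in by_k.items()})
    k_sel = select_k(delta, threshold=threshold, override=k_override)
    return ConsensusResult(by_k=by_k, auc=auc, delta=delta, k_selected=k_sel)


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 1..k in order of first appearance (deterministic)."""
    mapping: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_genes_onepass(
    X: ExpressionMatrix, sample_labels, k_genes: int = 4, seed: int = 0, n_init: int = 10
) -> pd.Series:
    """One-pass k-means of genes (samples fixed in their clusters), K fixed.

    Sample cluster membership is not re-estimated; it only fixes the columns
    over which gene profiles are compared.  Labels are renumbered 1..k by
    first appearance so runs are reproducible under a fixed seed.
    """
    if X.state != "standardized":
        raise ValueError("gene clustering expects standardized expression")
    if k_genes > len(X.genes):
        raise ValueError("k_genes exceeds the number of genes")
    order = np.argsort(np.asarray(sample_labels), kind="stable")
    data = X.values.to_numpy()[:, order]
    km = KMeans(n_clusters=k_genes, init="k-means++", n_init=n_init, random_state=int(seed))
    labels = _relabel_first_appearance(km.fit_predict(data))
    return pd.Series(labels, index=X.genes, name="gene_cluster")


def centroid_fit(X: ExpressionMatrix, labels, cohort: str = "") -> CentroidModel:
    """Per-cluster mean standardized expression (one centroid per cluster)."""
    if X.state != "standardized":
        raise ValueError("centroids are fitted on standardized expression")
    lab = pd.Series(np.asarray(labels), index=X.samples)
    cols = {}
    for c in sorted(lab.unique()):
        members = lab.index[lab == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        cols[c] = X.values[members].mean(axis=1)
    return CentroidModel(centroids=pd.DataFrame(cols), cohort=cohort)


def centroid_predict(
    X_new: ExpressionMatrix, model: CentroidModel, max_gene_loss: float = 0.25
) -> pd.Series:
    """Assign each sample to the centroid with maximal Spearman correlation.

    Genes are intersected and order-aligned; losing more than
    ``max_gene_loss`` of the centroid genes is an error, and rank correlation
    needs at least 3 shared genes.  Ties between clusters break toward the
    lowest cluster index (logged).
    """
    shared = model.genes.intersection(X_new.genes)
    lost = 1.0 - len(shared) / len(model.genes)
    if len(shared) < 3:
        raise ValueError("fewer than 3 genes shared with the centroid model")
    if lost > max_gene_loss:
        raise ValueError(
            f"{lost:.0%} of centroid genes absent from the cohort (max {max_gene_loss:.0%})"
        )
    if lost > 0:
        logger.info("centroid_predict: %.1f%% of centroid genes dropped", 100 * lost)
    C = model.centroids.loc[shared].to_numpy()
    V = X_new.values.loc[shared].to_numpy()
    c_ranks = np.apply_along_axis(rankdata, 0, C)
    v_ranks = np.apply_along_axis(rankdata, 0, V)

    def _standardize(A):
        A = A - A.mean(axis=0, keepdims=True)
        norm = np.linalg.norm(A, axis=0, keepdims=True)
        norm[norm == 0] = 1.0
        return A / norm

    corr = _standardize(v_ranks).T @ _standardize(c_ranks)  # samples x clusters
    best = np.argmax(corr, axis=1)  # argmax takes the first (lowest) index on ties
    ties = (corr == corr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info("centroid_predict: %d tie(s) broken toward lowest cluster index", int(ties.sum()))
    clusters = np.asarray(model.clusters)
    return pd.Series(clusters[best], index=X_new.samples, name="cluster")
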