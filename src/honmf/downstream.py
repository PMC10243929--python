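"""Clustering from the consensus similarity, feature ranking, associations.

Samples are clustered either by Louvain communities of the KNN graph of S
(k = n // 2, the default) or by spectral clustering when an exact cluster
count is required. Discriminative features are ranked by the Laplacian
score of S: lower scores mark features that vary smoothly with the learned
sample structure. Cross-kingdom association edges are Pearson correlations
of S-smoothed feature vectors, thresholded on absolute value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering

from .affinity import SimilarityMatrix, knn_graph
from .datasets import AbundanceMatrix, ClusterLabels, MultiOmicsDataset
from .hypergraph import _canonical_rank

__all__ = [
    "cluster_samples",
    "laplacian_score",
    "FeatureScore",
    "select_top_features",
    "smoothed_correlation",
    "AssociationEdge",
    "association_network",
    "edges_to_frame",
    "write_graphml",
]


def _relabel_by_rank_order(groups: list[list[int]], n: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(sorted(groups, key=min)):
        labels[list(members)] = lab
    return labels


def cluster_samples(
    S: SimilarityMatrix,
    seed: int = 0,
    method: str = "louvain",
    k_clusters: int | None = None,
    knn_k: int | None = None,
    resolution: float = 1.0,
) -> ClusterLabels:
    """Cluster samples from the consensus similarity.

    ``louvain`` (default): Louvain communities on the KNN graph of S with
    ``k = n // 2`` neighbours. ``spectral_k``: spectral clustering of S into
    exactly ``k_clusters`` (Louvain cannot be forced to a given count).
    Labels are contiguous ints ordered by each cluster's first sample.
    """
    n = S.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to cluster")
    if method == "spectral_k":
        if k_clusters is None:
            raise ValueError("spectral_k requires k_clusters")
        sc = SpectralClustering(
            n_clusters=k_clusters, affinity="precomputed", random_state=seed,
            assign_labels="kmeans",
        )
        raw = sc.fit_predict(S.values)
        groups = [list(np.where(raw == c)[0]) for c in np.unique(raw)]
        return ClusterLabels(_relabel_by_rank_order(groups, n), list(S.sample_ids))
    if method != "louvain":
        raise ValueError(f"unknown method {method!r}")

    off = S.values[~np.eye(n, dtype=bool)]
    if np.allclose(off, off[0], rtol=0, atol=1e-12):
        warnings.warn("similarity matrix has no structure; returning a single cluster")
        return ClusterLabels(np.zeros(n, dtype=int), list(S.sample_ids))

    k = knn_k if knn_k is not None else max(1, n // 2)
    W = knn_graph(S, k).values
    # canonical node order (see hypergraph module) for permutation equivariance
    order = _canonical_rank(S.values)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(W, 1))
    edges = sorted(
        (min(int(rank[i]), int(rank[j])), max(int(rank[i]), int(rank[j])), float(W[i, j]))
        for i, j in zip(iu, ju)
    )
    g.add_weighted_edges_from(edges)
    comms = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=seed)
    groups = [[int(order[r]) for r in c] for c in comms]
    return ClusterLabels(_relabel_by_rank_order(groups, n), list(S.sample_ids))


def laplacian_score(f: np.ndarray, S: SimilarityMatrix) -> float:
    """Laplacian score of one feature on the sample-similarity graph.

    With D = diag(row sums of S), L = D - S and the D-weighted centering
    f~ = f - (f^T D 1 / 1^T D 1) 1, the score is

        SC(f) = (f~^T L f~) / (f~^T D f~).

    Low scores mark features aligned with the graph structure. Constant
    features have no defined score and return +inf (never selected).
    """
    f = np.asarray(f, dtype=float)
    n = S.n_samples
    if f.shape != (n,):
        raise ValueError(f"feature vector must have length {n}")
    d = S.values.sum(axis=1)
    dtot = d.sum()
    ft = f - (f @ d) / dtot
    denom = float(ft @ (d * ft))
    if denom <= 1e-300 or np.allclose(f, f[0]):
        warnings.warn("constant feature: Laplacian score undefined, returning +inf")
        return float("inf")
    L = np.diag(d) - S.values
    return float(ft @ L @ ft) / denom


@dataclass
class FeatureScore:
    feature_id: str
    modality: str
    score: float
    rank: int


def select_top_features(
    X: AbundanceMatrix, S: SimilarityMatrix, top_k: int
) -> list[FeatureScore]:
    """Rank features by ascending Laplacian score and return the best top_k.

    Zero-variance features are excluded from the ranking (their score is
    undefined). Ties resolve to the lower feature index.
    """
    if X.sample_ids != S.sample_ids:
        raise ValueError("abundance matrix and similarity matrix must share samples")
    scored = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(X.n_features):
            f = X.values[i]
            if np.allclose(f, f[0]):
                continue
            scored.append((laplacian_score(f, S), i))
    if top_k > len(scored):
        raise ValueError(f"top_k={top_k} exceeds {len(scored)} scorable features")
    scored.sort(key=lambda t: (t[0], t[1]))
    return [
        FeatureScore(X.feature_ids[i], X.name, float(sc), r + 1)
        for r, (sc, i) in enumerate(scored[:top_k])
    ]


def smoothed_correlation(a: np.ndarray, b: np.ndarray, S: SimilarityMatrix) -> float:
    """Pearson correlation of similarity-smoothed feature vectors.

    Each feature (a row vector over samples) is propagated through the
    consensus similarity, a_hat = a S and b_hat = b S, before correlating;
    the smoothing suppresses sample-level noise so that only associations
    consistent with the learned structure survive. A constant smoothed
    vector has no defined correlation and returns 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = S.n_samples
    if a.shape != (n,) or b.shape != (n,):
        raise ValueError(f"feature vectors must have length {n}")
    ah = a @ S.values
    bh = b @ S.values
    if np.std(ah) == 0 or np.std(bh) == 0:
        warnings.warn("constant smoothed feature: correlation undefined, returning 0")
        return 0.0
    return float(np.clip(np.corrcoef(ah, bh)[0, 1], -1.0, 1.0))


@dataclass
class AssociationEdge:
    feature_a: str
    modality_a: str
    feature_b: str
    modality_b: str
    corr: float

    @property
    def sign(self) -> str:
        return "positive" if self.corr > 0 else "negative"


def association_network(
    dataset: MultiOmicsDataset,
    S: SimilarityMatrix,
    per_modality_top: list[int],
    threshold: float = 0.5,
) -> tuple[list[AssociationEdge], dict[tuple[str, str], pd.DataFrame]]:
    """Cross-modality association edges among top-ranked features.

    Selects the ``per_modality_top[i]`` best features of each modality by
    Laplacian score, computes smoothed correlations for every cross-modality
    pair, and keeps edges with ``|corr| > threshold`` (default 0.5). Also
    returns the full pairwise correlation matrix for each modality pair
    (heat-map material), regardless of the threshold.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    if len(per_modality_top) != dataset.n_modalities:
        raise ValueError("one top-count per modality required")
    selected = []
    for m, top in enumerate(per_modality_top):
        feats = select_top_features(dataset.modalities[m], S, top)
        X = dataset.modalities[m]
        idx = {fid: i for i, fid in enumerate(X.feature_ids)}
        selected.append([(fs.feature_id, X.values[idx[fs.feature_id]]) for fs in feats])

    edges: list[AssociationEdge] = []
    matrices: dict[tuple[str, str], pd.DataFrame] = {}
    names = dataset.modality_names
    for a_mod in range(dataset.n_modalities):
        for b_mod in range(a_mod + 1, dataset.n_modalities):
            rows = [fid for fid, _ in selected[a_mod]]
            cols = [fid for fid, _ in selected[b_mod]]
            C = np.empty((len(rows), len(cols)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for ia, (_, fa) in enumerate(selected[a_mod]):
                    for ib, (_, fb) in enumerate(selected[b_mod]):
                        C[ia, ib] = smoothed_correlation(fa, fb, S)
            matrices[(names[a_mod], names[b_mod])] = pd.DataFrame(C, index=rows, columns=cols)
            for ia, ra in enumerate(rows):
                for ib, cb in enumerate(cols):
                    if abs(C[ia, ib]) > threshold:
                        edges.append(
                            AssociationEdge(ra, names[a_mod], cb, names[b_mod], float(C[ia, ib]))
                        )
    return edges, matrices


def edges_to_frame(edges: list[AssociationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_a": e.feature_a,
                "modality_a": e.modality_a,
                "feature_b": e.feature_b,
                "modality_b": e.modality_b,
                "corr": e.corr,
                "sign": e.sign,
            }
            for e in edges
        ],
        columns=["feature_a", "modality_a", "feature_b", "modality_b", "corr", "sign"],
    )


def write_graphml(edges: list[AssociationEdge], path) -> None:
    """Export the association network for graph viewers."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.feature_a, modality=e.modality_a)
        g.add_node(e.feature_b, modality=e.modality_b)
        g.add_edge(e.feature_a, e.feature_b, corr=e.corr, sign=e.sign)
    nx.write_graphml(g, path)
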