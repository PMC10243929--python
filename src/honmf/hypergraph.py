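"""Hypergraphs over samples: community hyperedges, kernel weights, Laplacians.

A hyperedge groups an arbitrary set of samples; here hyperedges are Louvain
communities of the KNN graph of a modality's affinity matrix, so the
regularizer can penalize disagreement of the latent factors across a whole
community at once rather than only along pairwise edges. The hypergraph
Laplacian is

    L = D_v - P W D_e^{-1} P^T

with incidence P, diagonal hyperedge weights W, vertex degrees
d_v = sum_e w_e P[v, e] and hyperedge degrees delta_e = sum_v P[v, e].
The quadratic form Tr(H^T L H) equals the weighted within-hyperedge
pairwise disagreement (1/2) sum_e sum_{i,j in e} (w_e / delta_e) ||h_i - h_j||^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

from .affinity import SimilarityMatrix, knn_graph
from .datasets import AbundanceMatrix

__all__ = [
    "Hypergraph",
    "HypergraphLaplacian",
    "build_hyperedges_louvain",
    "hyperedge_weight",
    "build_hypergraph",
    "hypergraph_laplacian",
    "hypergraph_regularizer",
    "simple_graph_laplacian",
    "write_hyperedges",
]


@dataclass
class Hypergraph:
    """Incidence matrix P (vertices x hyperedges) with positive weights w."""

    incidence: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        P = self.incidence
        if P.ndim != 2:
            raise ValueError("incidence must be 2-D (vertices x hyperedges)")
        if not np.isin(P, (0.0, 1.0)).all():
            raise ValueError("incidence entries must be 0/1")
        if self.weights.shape != (P.shape[1],):
            raise ValueError("one weight per hyperedge required")
        if (self.weights <= 0).any():
            raise ValueError("hyperedge weights must be positive")
        if (P.sum(axis=0) < 2).any():
            raise ValueError("every hyperedge must contain at least 2 vertices")
        if (P.sum(axis=1) < 1).any():
            raise ValueError("every vertex must belong to at least one hyperedge")

    @property
    def n_vertices(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_hyperedges(self) -> int:
        return self.incidence.shape[1]

    @property
    def vertex_degrees(self) -> np.ndarray:
        return self.incidence @ self.weights

    @property
    def hyperedge_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=0)


@dataclass
class HypergraphLaplacian:
    """Symmetric PSD matrix with zero row sums (hypergraph or simple graph)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.values, dtype=float)
        if L.ndim != 2 or L.shape[0] != L.shape[1]:
            raise ValueError("Laplacian must be square")
        if np.abs(L - L.T).max() > 1e-10:
            raise ValueError("Laplacian must be symmetric within 1e-10")
        if np.abs(L.sum(axis=1)).max() > 1e-8:
            raise ValueError("Laplacian rows must sum to zero")
        self.values = L

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


def _canonical_rank(A: np.ndarray) -> np.ndarray:
    """Data-derived vertex order: descending row sum, ties by index.

    Community detection visits nodes in a seeded shuffle of the node list,
    so relabelling vertices by a data-derived rank makes the result
    equivariant under sample permutation (exactly, except on tied row sums).
    """
    n = A.shape[0]
    return np.lexsort((np.arange(n), -A.sum(axis=1)))


def build_hyperedges_louvain(
    A: SimilarityMatrix,
    knn_k: int | None = None,
    resolution: float = 1.0,
    seed: int = 0,
) -> list[list[int]]:
    """Louvain communities of the KNN graph of ``A``, as hyperedges.

    ``knn_k`` defaults to ``n // 2``. Singleton communities contribute
    nothing to the Laplacian, so each is merged into the community of its
    most similar other sample (ties to the lowest index). Hyperedges are
    returned as sorted vertex-index lists, ordered by smallest member.
    """
    n = A.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples")
    if knn_k is None:
        knn_k = max(1, n // 2)
    G_knn = knn_graph(A, knn_k)
    if not (G_knn.values > 0).any():
        raise ValueError("KNN graph has no edges; affinity matrix is all zero")

    order = _canonical_rank(A.values)  # order[r] = vertex with rank r
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    g = nx.Graph()
    g.add_nodes_from(range(n))  # node id = canonical rank
    iu, ju = np.nonzero(np.triu(G_knn.values, 1))
    edges = sorted(
        (min(int(rank[i]), int(rank[j])), max(int(rank[i]), int(rank[j])), float(G_knn.values[i, j]))
        for i, j in zip(iu, ju)
    )  # insertion in canonical order: adjacency iteration is permutation-stable
    g.add_weighted_edges_from(edges)
    comms = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=seed)
    # back to vertex indices
    comms = [sorted(int(order[r]) for r in c) for c in comms]

    # merge singletons into their most similar neighbour's community
    comms = sorted(comms, key=lambda c: c[0])
    changed = True
    while changed:
        changed = False
        for idx, c in enumerate(comms):
            if len(c) == 1:
                v = c[0]
                sims = A.values[v].copy()
                sims[v] = -np.inf
                target = int(np.argmax(sims))  # argmax ties -> lowest index
                for other in comms:
                    if target in other:
                        other.extend(c)
                        other.sort()
                        break
                comms.pop(idx)
                changed = True
                break
    return sorted(comms, key=lambda c: c[0])


def hyperedge_weight(X, vertices) -> float:
    """Total within-hyperedge Gaussian similarity.

    ``w_e = sum over unordered pairs {u, v} of exp(-d^2(u,v) / (2 sigma_e^2))``
    where ``sigma_e^2`` is the mean squared Euclidean distance over those
    pairs (computed on the sample columns of ``X``). If all members coincide
    the kernel limit is 1 per pair, so ``w_e`` equals the number of pairs.
    """
    vals = X.values if isinstance(X, AbundanceMatrix) else np.asarray(X, dtype=float)
    vertices = sorted(int(v) for v in vertices)
    if len(vertices) < 2:
        raise ValueError("a hyperedge needs at least 2 vertices")
    d2 = pdist(vals[:, vertices].T, metric="sqeuclidean")
    sig2 = d2.mean()
    if sig2 == 0:
        return float(len(d2))
    return float(np.exp(-d2 / (2.0 * sig2)).sum())


def build_hypergraph(X, hyperedges: list[list[int]], n_vertices: int | None = None) -> Hypergraph:
    """Assemble incidence and kernel weights for the given hyperedges."""
    vals = X.values if isinstance(X, AbundanceMatrix) else np.asarray(X, dtype=float)
    if n_vertices is None:
        n_vertices = vals.shape[1]
    P = np.zeros((n_vertices, len(hyperedges)))
    w = np.empty(len(hyperedges))
    for e, members in enumerate(hyperedges):
        P[list(members), e] = 1.0
        w[e] = hyperedge_weight(vals, members)
    return Hypergraph(P, w)


def hypergraph_laplacian(H: Hypergraph) -> HypergraphLaplacian:
    """L = D_v - P W D_e^{-1} P^T."""
    P, w = H.incidence, H.weights
    delta = H.hyperedge_degrees
    theta = (P * w) / delta @ P.T  # P W D_e^{-1} P^T
    L = np.diag(H.vertex_degrees) - theta
    L = 0.5 * (L + L.T)
    return HypergraphLaplacian(L)


def hypergraph_regularizer(Hmat: np.ndarray, L: HypergraphLaplacian) -> float:
    """Tr(H^T L H): within-hyperedge disagreement of the latent factors."""
    Hmat = np.asarray(Hmat, dtype=float)
    if Hmat.shape[0] != L.n_vertices:
        raise ValueError("factor matrix rows must match Laplacian vertices")
    return float(np.trace(Hmat.T @ L.values @ Hmat))


def simple_graph_laplacian(A: SimilarityMatrix, knn_k: int | None = None) -> HypergraphLaplacian:
    """Pairwise-graph Laplacian L = D - W on the KNN-sparsified affinity.

    The ablation variant that replaces the hypergraph with an ordinary
    graph, so only pairwise sample relations are penalized.
    """
    n = A.n_samples
    if knn_k is None:
        knn_k = max(1, n // 2)
    W = knn_graph(A, knn_k).values
    L = np.diag(W.sum(axis=1)) - W
    return HypergraphLaplacian(0.5 * (L + L.T))


def write_hyperedges(H: Hypergraph, sample_ids: list[str], path) -> None:
    """One line per hyperedge: weight, tab, tab-separated member sample IDs."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in range(H.n_hyperedges):
            members = np.nonzero(H.incidence[:, e])[0]
            ids = "\t".join(sample_ids[v] for v in members)
            fh.write(f"{H.weights[e]:.10g}\t{ids}\n")
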