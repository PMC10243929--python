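"""Gaussian-kernel sample affinities, KNN sparsification, and minimal SNF.

Per-modality sample similarities are Gaussian kernels on the (normalized)
composition profiles. A small similarity-network-fusion routine is included
solely to initialize the consensus matrix; it is not a standalone SNF tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datasets import AbundanceMatrix

__all__ = ["SimilarityMatrix", "gaussian_affinity", "knn_graph", "snf_fuse"]


@dataclass
class SimilarityMatrix:
    """Symmetric non-negative n-by-n sample affinity."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity values must be finite")
        if (self.values < 0).any():
            raise ValueError("similarity values must be non-negative")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("similarity matrix must be symmetric within 1e-10")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimilarityMatrix":
        return cls(df.to_numpy(float), list(df.index))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path) -> "SimilarityMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


def _as_columns(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, AbundanceMatrix):
        return X.values, list(X.sample_ids)
    X = np.asarray(X, dtype=float)
    return X, [f"s{j}" for j in range(X.shape[1])]


def gaussian_affinity(
    X,
    bandwidth_rule: str = "local_scaling",
    scale: float = 1.0,
    bandwidth: float | None = None,
    n_local: int = 7,
) -> SimilarityMatrix:
    """Gaussian-kernel affinity between sample columns of ``X``.

    ``A[u, v] = exp(-d^2(u, v) / (2 * sigma2_uv))`` with squared Euclidean
    distances between sample columns. The bandwidth is either an explicit
    ``sigma^2`` (``bandwidth``, overriding the rule) or derived by

    - ``"median_sqdist"`` / ``"mean_sqdist"``: one global sigma^2 equal to
      the median / mean off-diagonal squared distance;
    - ``"local_scaling"``: ``sigma2_uv = sigma_u * sigma_v`` where
      ``sigma_u`` is sample ``u``'s mean distance to its ``n_local``
      nearest neighbours (adaptive to local density, the convention of the
      network-fusion family this model builds on).

    ``scale`` multiplies sigma^2. The diagonal is exactly 1.
    """
    vals, sample_ids = _as_columns(X)
    n = vals.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if scale <= 0:
        raise ValueError("scale must be positive")
    D2 = squareform(pdist(vals.T, metric="sqeuclidean"))

    if bandwidth is not None:
        if bandwidth <= 0:
            raise ValueError("bandwidth (sigma^2) must be positive")
        sig2 = float(bandwidth) * scale
    else:
        off = D2[~np.eye(n, dtype=bool)]
        if np.all(off == 0):
            raise ValueError(
                "all samples are identical (every pairwise distance is 0); "
                "pass an explicit bandwidth to override"
            )
        if bandwidth_rule == "median_sqdist":
            sig2 = float(np.median(off)) * scale
        elif bandwidth_rule == "mean_sqdist":
            sig2 = float(np.mean(off)) * scale
        elif bandwidth_rule == "local_scaling":
            D = np.sqrt(D2)
            k = min(n_local, n - 1)
            # mean distance to the k nearest other samples
            part = np.sort(D + np.diag(np.full(n, np.inf)), axis=1)[:, :k]
            sigma = part.mean(axis=1)
            pos = sigma[sigma > 0]
            if pos.size == 0:
                raise ValueError("degenerate local scales; pass an explicit bandwidth")
            sigma = np.where(sigma > 0, sigma, pos.mean())
            sig2 = np.outer(sigma, sigma) * scale
        else:
            raise ValueError(f"unknown bandwidth_rule {bandwidth_rule!r}")
        if np.isscalar(sig2) and sig2 <= 0:
            raise ValueError("derived bandwidth is zero; pass an explicit bandwidth")

    A = np.exp(-D2 / (2.0 * sig2))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 1.0)
    return SimilarityMatrix(A, sample_ids)


def _topk_mask(values: np.ndarray, k: int) -> np.ndarray:
    """Row mask keeping each row's k largest off-diagonal entries.

    Ties at the k-th rank resolve to the lowest sample index (stable sort on
    descending similarity).
    """
    n = values.shape[0]
    W = values.astype(float).copy()
    np.fill_diagonal(W, -np.inf)
    order = np.argsort(-W, axis=1, kind="stable")
    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    mask[rows, order[:, :k].ravel()] = True
    return mask


def knn_graph(S: SimilarityMatrix, k: int) -> SimilarityMatrix:
    """Keep each sample's k strongest neighbours; symmetrize by union.

    An edge survives if either endpoint selects it, which keeps small graphs
    connected. Self-edges are removed. Retained edges keep their similarity
    values as weights.
    """
    n = S.n_samples
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    mask = _topk_mask(S.values, k)
    mask |= mask.T
    out = np.where(mask, S.values, 0.0)
    np.fill_diagonal(out, 0.0)
    return SimilarityMatrix(out, list(S.sample_ids))


def _row_stochastic_full(W: np.ndarray) -> np.ndarray:
    """SNF full-kernel normalization: off-diagonal mass 1/2 per row, diag 1/2."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rs = off.sum(axis=1)
    rs[rs == 0] = 1.0
    P = off / (2.0 * rs[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def _local_kernel(W: np.ndarray, k: int) -> np.ndarray:
    """Row-normalized KNN-restricted kernel (the SNF 'local' operator)."""
    mask = _topk_mask(W, k)
    loc = np.where(mask, W, 0.0)
    rs = loc.sum(axis=1)
    rs[rs == 0] = 1.0
    return loc / rs[:, None]


def snf_fuse(
    A_list: list[SimilarityMatrix],
    k_neighbors: int | None = None,
    iterations: int = 20,
) -> SimilarityMatrix:
    """Similarity-network fusion of per-modality affinities.

    Standard cross-diffusion: each modality's row-normalized kernel is
    propagated through its KNN-restricted local kernel against the average
    of the other modalities' kernels, for a fixed number of iterations; the
    fused matrix is the symmetrized average. With a single input the
    row-normalized symmetrized input is returned unchanged. Used here only
    to initialize the consensus similarity.
    """
    if not A_list:
        raise ValueError("need at least one similarity matrix")
    n = A_list[0].n_samples
    ids = list(A_list[0].sample_ids)
    for A in A_list[1:]:
        if A.n_samples != n or A.sample_ids != ids:
            raise ValueError("all similarity matrices must share the same samples")
    if k_neighbors is None:
        k_neighbors = max(3, n // 10)
    k_neighbors = min(k_neighbors, n - 1)

    P = [_row_stochastic_full(A.values) for A in A_list]
    if len(P) == 1:
        fused = 0.5 * (P[0] + P[0].T)
        return SimilarityMatrix(fused, ids)

    Sloc = [_local_kernel(A.values, k_neighbors) for A in A_list]
    for _ in range(iterations):
        new = []
        for v in range(len(P)):
            others = [P[u] for u in range(len(P)) if u != v]
            mean_others = np.mean(others, axis=0)
            Pv = Sloc[v] @ mean_others @ Sloc[v].T
            new.append(_row_stochastic_full(0.5 * (Pv + Pv.T)))
        P = new
    fused = np.mean(P, axis=0)
    fused = 0.5 * (fused + fused.T)
    return SimilarityMatrix(fused, ids)
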