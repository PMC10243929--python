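"""Clustering agreement metrics: NMI, ARI, and similarity-based silhouette.

NMI and ARI are computed from the contingency table of two partitions; the
silhouette works directly from a sample-similarity matrix by converting it
to a bounded distance d = 1 - S / max(S) (scale-invariant, the default) or
d = max(S) - S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .affinity import SimilarityMatrix
from .datasets import ClusterLabels

__all__ = ["nmi", "ari", "silhouette_from_similarity", "MetricReport", "evaluate"]


def _as_labels(x) -> np.ndarray:
    if isinstance(x, ClusterLabels):
        return x.labels
    return np.asarray(x, dtype=int)


def _contingency(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    gi, g_inv = np.unique(g, return_inverse=True)
    pi, p_inv = np.unique(p, return_inverse=True)
    C = np.zeros((len(gi), len(pi)), dtype=int)
    np.add.at(C, (g_inv, p_inv), 1)
    return C


def nmi(G, P) -> float:
    """Normalized mutual information between two partitions.

    Mutual information normalized by the geometric mean
    ``sqrt(H(G) * H(P))`` of the partition entropies (natural log). A
    single-cluster partition has zero entropy: NMI is then defined as 1 if
    both partitions are the identical trivial partition and 0 otherwise.
    """
    g, p = _as_labels(G), _as_labels(P)
    if g.shape != p.shape:
        raise ValueError("partitions must cover the same samples")
    C = _contingency(g, p)
    n = C.sum()
    pg = C.sum(axis=1) / n
    pp = C.sum(axis=0) / n
    hg = float(-(pg * np.log(pg)).sum())
    hp = float(-(pp * np.log(pp)).sum())
    if hg == 0.0 or hp == 0.0:
        same = C.shape == (1, 1)
        warnings.warn("single-cluster partition: NMI degenerate")
        return 1.0 if same else 0.0
    pij = C / n
    mask = pij > 0
    mi = float((pij[mask] * np.log(pij[mask] / np.outer(pg, pp)[mask])).sum())
    return float(np.clip(mi / np.sqrt(hg * hp), 0.0, 1.0))


def ari(G, P) -> float:
    """Adjusted Rand index via binomial sums over the contingency table."""
    g, p = _as_labels(G), _as_labels(P)
    if g.shape != p.shape:
        raise ValueError("partitions must cover the same samples")
    n = g.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    C = _contingency(g, p)
    sum_ij = comb(C, 2).sum()
    sum_i = comb(C.sum(axis=1), 2).sum()
    sum_j = comb(C.sum(axis=0), 2).sum()
    n2 = comb(n, 2)
    expected = sum_i * sum_j / n2
    max_index = 0.5 * (sum_i + sum_j)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def silhouette_from_similarity(
    S: SimilarityMatrix, labels, conversion: str = "scaled"
) -> float:
    """Mean silhouette coefficient from a similarity matrix and labels.

    Distances are ``1 - S / max(S)`` (``"scaled"``, invariant to positive
    rescaling of S) or ``max(S) - S`` (``"max_minus"``). Per sample,
    ``a_i`` is the mean within-cluster distance (self excluded) and ``b_i``
    the smallest mean distance to another cluster; the coefficient is
    ``1 - a_i/b_i`` if ``a_i < b_i``, ``0`` if equal, ``b_i/a_i - 1``
    otherwise. Singleton clusters contribute 0.
    """
    lab = _as_labels(labels)
    n = S.n_samples
    if lab.shape != (n,):
        raise ValueError("labels must match the similarity matrix")
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    smax = S.values.max()
    if smax <= 0:
        raise ValueError("similarity matrix has no positive entries")
    if conversion == "scaled":
        D = 1.0 - S.values / smax
    elif conversion == "max_minus":
        D = smax - S.values
    else:
        raise ValueError(f"unknown conversion {conversion!r}")

    scores = np.empty(n)
    for i in range(n):
        own = lab[i]
        same = (lab == own) & (np.arange(n) != i)
        if not same.any():
            warnings.warn("singleton cluster: silhouette set to 0 for its sample")
            scores[i] = 0.0
            continue
        a_i = D[i, same].mean()
        b_i = min(D[i, lab == c].mean() for c in uniq if c != own)
        if a_i < b_i:
            scores[i] = 1.0 - a_i / b_i
        elif a_i == b_i:
            scores[i] = 0.0
        else:
            scores[i] = b_i / a_i - 1.0
    return float(scores.mean())


@dataclass
class MetricReport:
    """Clustering quality summary; NMI/ARI require ground-truth labels."""

    mean_silhouette: float
    nmi: float | None = None
    ari: float | None = None

    def to_dict(self) -> dict:
        out = {"mean_silhouette": self.mean_silhouette}
        if self.nmi is not None:
            out["nmi"] = self.nmi
        if self.ari is not None:
            out["ari"] = self.ari
        return out


def evaluate(S: SimilarityMatrix, labels, truth=None) -> MetricReport:
    """Silhouette from S and the predicted labels, plus NMI/ARI vs truth."""
    sil = silhouette_from_similarity(S, labels)
    if truth is None:
        return MetricReport(mean_silhouette=sil)
    return MetricReport(mean_silhouette=sil, nmi=nmi(truth, labels), ari=ari(truth, labels))
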