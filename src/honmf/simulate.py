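"""Synthetic multi-modal microbiome data with planted sample clusters.

The generator emulates the shape of matched bacterial/fungal/viral
composition profiles: each modality carries a disjoint block of features
elevated in exactly one sample cluster, counts are drawn from a
negative-binomial (or truncated-Gaussian) noise model, and a fraction of
entries is zeroed to mimic the sparsity of shallow sequencing. Because the
same planted cluster drives one feature block in every modality,
cross-modality associations between block features exist by construction.
"""

from __future__ import annotations

import numpy as np

from .datasets import AbundanceMatrix, ClusterLabels, MultiOmicsDataset

__all__ = ["simulate_multiomics"]

_PREFIXES = ["B", "F", "V"]
_NAMES = ["bacteria", "fungi", "virus"]

#: baseline expected count of a background feature
BASELINE_MEAN = 5.0
#: at separation=1 a planted feature's mean is BASELINE_MEAN * (1 + BOOST)
BOOST = 8.0
#: negative-binomial dispersion (size parameter r; variance = mu + mu^2/r)
NB_DISPERSION = 10.0


def planted_feature_blocks(n_features: int, n_clusters: int) -> list[np.ndarray]:
    """Indices of the disjoint feature block elevated in each cluster.

    Blocks have size ``n_features // (n_clusters + 1)`` so that a trailing
    block of pure-noise features always remains.
    """
    block = n_features // (n_clusters + 1)
    if block < 1:
        raise ValueError(
            f"{n_features} features cannot host {n_clusters} planted blocks plus noise"
        )
    return [np.arange(c * block, (c + 1) * block) for c in range(n_clusters)]


def simulate_multiomics(
    n_samples: int,
    n_clusters: int,
    features_per_modality: list[int],
    separation: float = 1.0,
    noise_model: str = "negative_binomial",
    dropout_rate: float = 0.2,
    seed: int = 0,
) -> tuple[MultiOmicsDataset, ClusterLabels]:
    """Generate a matched multi-modal dataset with planted clusters.

    Parameters
    ----------
    n_samples
        Number of shared samples (``>= 3 * n_clusters``).
    n_clusters
        Number of planted sample clusters (``>= 2``).
    features_per_modality
        Feature count per modality; its length (2 or 3) sets the number of
        modalities.
    separation
        Effect size in ``(0, 1]``: a planted feature's expected abundance in
        its cluster is ``BASELINE_MEAN * (1 + separation * BOOST)`` versus
        ``BASELINE_MEAN`` elsewhere.
    noise_model
        ``"negative_binomial"`` (overdispersed counts, dispersion
        ``NB_DISPERSION``) or ``"gaussian"`` (truncated at zero).
    dropout_rate
        Probability in ``[0, 1)`` that an entry is independently zeroed,
        emulating structural zeros.
    seed
        Seed for the generator; identical arguments give bit-identical data.

    Returns
    -------
    (MultiOmicsDataset, ClusterLabels)
        The dataset and the planted ground-truth labels.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_samples < 3 * n_clusters:
        raise ValueError("need n_samples >= 3 * n_clusters")
    if not 0.0 < separation <= 1.0:
        raise ValueError("separation must lie in (0, 1]")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must lie in [0, 1)")
    if len(features_per_modality) not in (2, 3):
        raise ValueError("features_per_modality must list 2 or 3 modalities")
    if noise_model not in ("gaussian", "negative_binomial"):
        raise ValueError(f"unknown noise_model {noise_model!r}")

    rng = np.random.default_rng(seed)

    # near-equal cluster sizes; samples laid out in cluster order
    sizes = np.full(n_clusters, n_samples // n_clusters)
    sizes[: n_samples % n_clusters] += 1
    labels = np.repeat(np.arange(n_clusters), sizes)
    width = len(str(n_samples))
    sample_ids = [f"S{j + 1:0{width}d}" for j in range(n_samples)]

    modalities = []
    for m, p in enumerate(features_per_modality):
        blocks = planted_feature_blocks(p, n_clusters)
        mean = np.full((p, n_samples), BASELINE_MEAN)
        for c, feats in enumerate(blocks):
            mean[np.ix_(feats, np.where(labels == c)[0])] = BASELINE_MEAN * (
                1.0 + separation * BOOST
            )
        if noise_model == "negative_binomial":
            r = NB_DISPERSION
            counts = rng.negative_binomial(r, r / (r + mean)).astype(float)
        else:
            counts = np.clip(rng.normal(mean, 0.25 * mean + 0.5), 0.0, None)
        if dropout_rate > 0:
            counts[rng.random(counts.shape) < dropout_rate] = 0.0
        fw = len(str(p))
        feature_ids = [f"{_PREFIXES[m]}{i + 1:0{fw}d}" for i in range(p)]
        modalities.append(AbundanceMatrix(counts, feature_ids, sample_ids, _NAMES[m]))

    dataset = MultiOmicsDataset(modalities, _NAMES[: len(modalities)])
    return dataset, ClusterLabels(labels, sample_ids)
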