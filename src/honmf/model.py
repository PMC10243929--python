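"""Model and results objects for the hypergraph-regularized factorization.

Usage mirrors the modelling-object convention of statistical packages::

    ds, truth = simulate_multiomics(30, 3, [40, 30, 20], seed=0)
    res = HONMF(ds, k=3, seed=0).fit()
    labels = res.cluster_samples()
    print(res.summary())

``HONMF`` holds the data and configuration; ``fit()`` builds the
per-modality kernels and hypergraph Laplacians, initializes deterministically
(NNDSVD factors, identity mixing, SNF-fused consensus), resolves alpha and
gamma automatically unless given, and runs monotone multiplicative updates.
The returned :class:`HONMFResults` carries the consensus similarity and all
factors, plus the downstream operations (clustering, discriminative-feature
ranking, cross-kingdom association networks).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import core, downstream
from .affinity import SimilarityMatrix, gaussian_affinity, snf_fuse
from .core import HONMFConfig, HONMFState
from .datasets import AbundanceMatrix, ClusterLabels, MultiOmicsDataset
from .hypergraph import (
    build_hyperedges_louvain,
    build_hypergraph,
    hypergraph_laplacian,
    simple_graph_laplacian,
)

__all__ = ["HONMF", "HONMFResults"]


class HONMF:
    """Hypergraph-regularized orthogonal tri-factor NMF over 2-3 modalities.

    Parameters
    ----------
    dataset
        Matched multi-modal abundance data.
    k
        Number of latent factors (soft clusters), >= 2.
    alpha, gamma
        Consensus-fusion and hypergraph-regularization weights; ``"auto"``
        (default) selects both from the initialization so every term starts
        at a comparable magnitude.
    beta, eta
        Row-sum softness of S (default 1) and column-orthogonality pressure
        on the H_i (default 10).
    variant
        ``"honmf"`` (full model), ``"gonmf"`` (simple-graph Laplacian),
        or the ablations ``"no_alpha"``/``"no_gamma"``/``"no_eta"``.
    bandwidth_rule, log_c
        Kernel bandwidth rule for the per-modality affinities and optional
        ``log1p(c x)`` transform applied after relative-abundance closure.
    hyperedge_knn, resolution
        KNN sparsity (default ``n // 2``) and Louvain resolution used when
        building community hyperedges.
    """

    def __init__(
        self,
        dataset: MultiOmicsDataset,
        k: int,
        *,
        alpha: float | str = "auto",
        beta: float = 1.0,
        gamma: float | str = "auto",
        eta: float = 10.0,
        variant: str = "honmf",
        max_iter: int = 500,
        tol: float = 1e-6,
        seed: int = 0,
        bandwidth_rule: str = "local_scaling",
        log_c: float | None = None,
        hyperedge_knn: int | None = None,
        resolution: float = 1.0,
        snf_k: int | None = None,
        snf_iterations: int = 20,
    ) -> None:
        self.dataset = dataset
        self.config = HONMFConfig(
            k=k, alpha=alpha, beta=beta, gamma=gamma, eta=eta,
            max_iter=max_iter, tol=tol, seed=seed, variant=variant,
        )
        self.bandwidth_rule = bandwidth_rule
        self.log_c = log_c
        self.hyperedge_knn = hyperedge_knn
        self.resolution = resolution
        self.snf_k = snf_k
        self.snf_iterations = snf_iterations

    @classmethod
    def from_dataframes(
        cls, frames: list[pd.DataFrame], names: list[str] | None = None, **kwargs
    ) -> "HONMF":
        """Build the model from feature-by-sample DataFrames (shared columns)."""
        names = names or [f"modality{i + 1}" for i in range(len(frames))]
        mats = [AbundanceMatrix.from_frame(df, nm) for df, nm in zip(frames, names)]
        from .datasets import align_modalities

        return cls(align_modalities(mats, names), **kwargs)

    # -- pipeline pieces, exposed for inspection ---------------------------

    def normalized_modalities(self) -> list[AbundanceMatrix]:
        return [m.normalized(self.log_c) for m in self.dataset.modalities]

    def affinities(self) -> list[SimilarityMatrix]:
        return [gaussian_affinity(m, self.bandwidth_rule) for m in self.normalized_modalities()]

    def laplacians(self, A_list: list[SimilarityMatrix] | None = None):
        """Per-modality regularization Laplacians (None when gamma is off)."""
        cfg = self.config
        if cfg.variant == "no_gamma" or cfg.gamma == 0:
            return None
        A_list = A_list or self.affinities()
        if cfg.variant == "gonmf":
            return [simple_graph_laplacian(A, self.hyperedge_knn) for A in A_list]
        Xn = self.normalized_modalities()
        laps = []
        for i, (A, X) in enumerate(zip(A_list, Xn)):
            edges = build_hyperedges_louvain(
                A, self.hyperedge_knn, self.resolution, seed=cfg.seed + i
            )
            laps.append(hypergraph_laplacian(build_hypergraph(X, edges, A.n_samples)))
        return laps

    def fit(self) -> "HONMFResults":
        cfg = self.config
        A_sim = self.affinities()
        L_list = self.laplacians(A_sim)
        A_list = [A.values for A in A_sim]
        S0 = snf_fuse(A_sim, self.snf_k, self.snf_iterations).values
        init = core.initialize(A_list, cfg, S_init=S0)
        auto_a, auto_g = core.auto_select_params(A_list, L_list, init)
        alpha = auto_a if cfg.alpha == "auto" else cfg.alpha
        gamma = auto_g if cfg.gamma == "auto" else cfg.gamma
        if L_list is None:
            gamma = 0.0
        rcfg = cfg.resolved(alpha, gamma)
        state = core.iterate(init, A_list, L_list, rcfg)
        state.S = 0.5 * (state.S + state.S.T)
        return HONMFResults(self, rcfg, state, A_sim, L_list)


@dataclass
class HONMFResults:
    """Fitted factors, consensus similarity, and downstream analyses."""

    model: HONMF
    config: HONMFConfig
    state: HONMFState
    affinities: list[SimilarityMatrix]
    laplacians: list | None

    # -- estimates ---------------------------------------------------------

    @property
    def S(self) -> SimilarityMatrix:
        """Consensus sample-similarity matrix."""
        return SimilarityMatrix(self.state.S, self.model.dataset.sample_ids)

    @property
    def H(self) -> list[np.ndarray]:
        return self.state.H

    @property
    def G(self) -> list[np.ndarray]:
        return self.state.G

    @property
    def objective_trace(self) -> list[float]:
        return self.state.objective_trace

    @property
    def n_iter(self) -> int:
        return len(self.state.objective_trace) - 1

    @property
    def converged(self) -> bool:
        return self.n_iter < self.config.max_iter

    # -- diagnostics -------------------------------------------------------

    def fit_residuals(self) -> list[float]:
        """Per-modality relative tri-factorization residual
        ||A_i - H_i G_i H_i^T||_F / ||A_i||_F."""
        out = []
        for A, H, G in zip(self.affinities, self.H, self.G):
            num = np.linalg.norm(A.values - H @ G @ H.T)
            out.append(float(num / np.linalg.norm(A.values)))
        return out

    def orthogonality_gaps(self) -> list[float]:
        """||H_i^T H_i - I||_F per modality."""
        k = self.config.k
        return [float(np.linalg.norm(H.T @ H - np.eye(k))) for H in self.H]

    def consensus_gaps(self) -> list[float]:
        """||S - H_i H_i^T||_F per modality."""
        return [float(np.linalg.norm(self.state.S - H @ H.T)) for H in self.H]

    def summary(self) -> str:
        ds = self.model.dataset
        cfg = self.config
        lines = [
            "Hypergraph-regularized orthogonal NMF tri-factorization",
            "=" * 56,
            f"samples: {ds.n_samples}    modalities: {ds.n_modalities} "
            f"({', '.join(ds.modality_names)})",
            f"factors k: {cfg.k}    variant: {cfg.variant}",
            f"alpha: {cfg.alpha:.4g}    beta: {cfg.beta:.4g}    "
            f"gamma: {cfg.gamma:.4g}    eta: {cfg.eta:.4g}",
            f"iterations: {self.n_iter} (converged: {self.converged})",
            f"objective: {self.objective_trace[-1]:.6g} "
            f"(initial {self.objective_trace[0]:.6g})",
            "",
            f"{'modality':<12}{'fit resid':>12}{'orth gap':>12}{'consensus gap':>16}",
        ]
        for name, r, o, c in zip(
            ds.modality_names, self.fit_residuals(), self.orthogonality_gaps(),
            self.consensus_gaps(),
        ):
            lines.append(f"{name:<12}{r:>12.4f}{o:>12.4f}{c:>16.4f}")
        dev = float(np.abs(self.state.S.sum(axis=1) - 1).max())
        lines.append("")
        lines.append(f"max |row sum of S - 1|: {dev:.4f}")
        return "\n".join(lines)

    # -- downstream --------------------------------------------------------

    def cluster_samples(
        self,
        method: str = "louvain",
        k_clusters: int | None = None,
        seed: int | None = None,
    ) -> ClusterLabels:
        return downstream.cluster_samples(
            self.S,
            seed=self.config.seed if seed is None else seed,
            method=method,
            k_clusters=k_clusters,
        )

    def select_features(self, modality: int | str, top_k: int):
        X = self.model.dataset[modality]
        return downstream.select_top_features(X, self.S, top_k)

    def association_network(self, per_modality_top: list[int], threshold: float = 0.5):
        return downstream.association_network(
            self.model.dataset, self.S, per_modality_top, threshold
        )

    # -- persistence -------------------------------------------------------

    def save(self, outdir) -> None:
        """Write S, H_i, G_i, the objective trace, and a config echo."""
        import os

        os.makedirs(outdir, exist_ok=True)
        ds = self.model.dataset
        self.S.write_tsv(os.path.join(outdir, "S.tsv"))
        for name, H, G in zip(ds.modality_names, self.H, self.G):
            cols = [f"factor{j + 1}" for j in range(self.config.k)]
            pd.DataFrame(H, index=ds.sample_ids, columns=cols).to_csv(
                os.path.join(outdir, f"H_{name}.tsv"), sep="\t", index_label="sample_id"
            )
            pd.DataFrame(G, index=cols, columns=cols).to_csv(
                os.path.join(outdir, f"G_{name}.tsv"), sep="\t", index_label="factor"
            )
        pd.DataFrame(
            {"iteration": range(len(self.objective_trace)), "objective": self.objective_trace}
        ).to_csv(os.path.join(outdir, "objective_trace.tsv"), sep="\t", index=False)
        cfg = dataclasses.asdict(self.config)
        cfg["modalities"] = list(ds.modality_names)
        with open(os.path.join(outdir, "config.yaml"), "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)
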