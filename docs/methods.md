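# Methods

## Model

Given M ∈ {2, 3} matched feature-by-sample abundance tables, each modality
is first closed to relative abundance per sample (columns sum to 1; an
optional `log1p(c·x)` transform is available and off by default — sequencing
depth is arbitrary in composition profiles, and closure keeps the kernel
scale comparable across modalities). A Gaussian kernel on the sample
columns gives a per-modality affinity A_i with unit diagonal. The model
minimizes

J = Σ_i ‖A_i − H_i G_i H_iᵀ‖²_F + (α/2) Σ_i ‖S − H_i H_iᵀ‖²_F
  + η Σ_i ‖H_iᵀH_i − I‖²_F + β ‖S·1 − 1‖² + γ Σ_i Tr(H_iᵀ L⁽ⁱ⁾ H_i),
  H_i, G_i, S ≥ 0.

Interpretation of the terms: (1) each kernel is approximated by a symmetric
tri-factorization whose H_i acts as a soft cluster indicator; (2) every
modality's kernel H_iH_iᵀ is pulled toward one consensus similarity S, which
is the integration device — modalities keep their own latent factors instead
of sharing one, so batch- and kingdom-specific structure is not forced into
a common basis; (3) near-orthogonal columns keep the factorization
identifiable and sparse; (4) rows of S are softly normalized to 1 so S
behaves like a transition-kernel-scale similarity; (5) the hypergraph
Laplacian penalizes within-community disagreement of the factors.

## Hypergraph construction

Hyperedges of modality i are Louvain communities of the KNN graph
(k = ⌊n/2⌋ by default, matching the clustering convention below) of A_i.
Louvain runs on a graph whose nodes are relabelled by a data-derived
canonical rank (descending affinity row sum, ties by index) so the result
is equivariant under sample permutation; the community detection itself is
seeded. Singleton communities contribute nothing to the Laplacian and are
merged into the community of their most similar sample. Each hyperedge's
weight is the total pairwise Gaussian similarity among its members, with
the bandwidth set to the mean squared member distance (so w_e is the
"total similarity" of the community, between 0 and the number of pairs; if
all members coincide the kernel limit gives one per pair). The Laplacian is
L = D_v − P W D_e⁻¹ Pᵀ, equal to the half-sum pairwise form
(1/2) Σ_e Σ_{i,j∈e} (w_e/δ_e)‖h_i − h_j‖², which the test suite verifies by
brute force. The `gonmf` variant replaces L with the simple-graph Laplacian
D − W of the KNN-sparsified affinity.

## Initialization and parameter selection

H_i comes from an NNDSVD-style construction on the symmetric problem
min ‖A_i − HHᵀ‖²: the dominant non-negative part of each leading singular
vector, scaled by √(σ_j · m), with zeros filled at mean(A)/100 so
multiplicative updates are not locked at zero. G_i starts at the identity.
S starts from a minimal similarity-network-fusion pass over the A_i
(row-normalized full kernels, KNN-restricted local kernels with
k = max(3, ⌊n/10⌋), 20 cross-diffusion iterations, symmetrized average) —
SNF here is only an initializer, and its row scale (≈1) matches the β
penalty. Unless given, α and γ are set to the ratio of the initial
tri-factorization residual to the initial value of the term they weight, so
every term enters the optimization at a comparable magnitude; a degenerate
zero denominator falls back to 1 with a warning.

## Optimization

Block-coordinate multiplicative updates, one pass H_1..H_M → G_1..G_M → S
per iteration. For each block the gradient is split into its non-negative
parts ∇J = pos − neg and the factor is multiplied elementwise by
(neg/pos)^θ with θ backtracked from 1 by halving until the objective does
not increase (the multiplicative direction is a strict descent direction in
θ at θ = 0, so acceptance is guaranteed for small θ and the recorded trace
is non-increasing by construction; at a stationary point the ratio is 1 and
the block is unchanged). Denominators carry a 1e-12 floor; non-negativity
is preserved exactly; G_i remains symmetric because its update is a
congruence of symmetric matrices. Laplacians are split elementwise into
positive and negative parts, which coincides with the D − Θ structure.
Convergence is declared at relative objective change below `tol = 1e-6`
(default `max_iter = 500`); S is symmetrized once after the loop, not
during iteration (the β term keeps rows near 1 softly). H_i is not
re-normalized between iterations; the monotonicity audit in the test suite
is the guard on the derivation.

## Downstream analyses

- **Clustering**: Louvain on the KNN graph of S with k = ⌊n/2⌋ (default),
  seeded and canonically ordered as above; or spectral clustering of S when
  an exact cluster count is required (Louvain cannot be forced to a given
  k). A similarity matrix with no off-diagonal structure short-circuits to
  a single cluster with a warning. Labels are 0-based contiguous integers
  ordered by each cluster's first sample.
- **Feature ranking**: Laplacian score of S, SC(f) = (f̃ᵀLf̃)/(f̃ᵀDf̃) with
  D-weighted centering; scale- and shift-invariant; ascending order, ties
  to the lower feature index. Zero-variance features have no defined score
  and are excluded (reported as +inf sentinels where scored directly).
- **Associations**: features are row vectors, smoothed as â = a·S, and
  cross-modality pairs among the per-modality top-ranked features are kept
  at |corr| > 0.5 with their sign. Smoothing projects every feature onto
  the learned sample structure, which *amplifies* spurious correlations
  among features that were never discriminative — restricting the network
  to the Laplacian-score shortlist is therefore part of the method, not a
  convenience. The raw (un-normalized) final S is used for both the score
  and the smoothing.

## Evaluation metrics

NMI (natural log, geometric-mean normalization √(H(G)H(P)) — the standard
choice where the printed definition is ambiguous about the radical), ARI
via binomial sums over the contingency table, and a silhouette computed
directly from S by the distance d = 1 − S/max(S) (bounded and invariant to
positive rescaling of S; d = max(S) − S is exposed as an option since the
conversion is a convention, not part of the model). Degenerate cases:
single-cluster NMI is 0 (1 only when both partitions are the same trivial
partition); singleton-cluster silhouette contributes 0.

## Synthetic data generator

`simulate_multiomics` emulates matched multi-kingdom composition profiles:
near-equal planted sample clusters; per modality a disjoint block of
features elevated in exactly one cluster (block size p//(k+1), so a pure
noise block always remains — needed to measure selection precision and
association specificity); expected counts 5 at baseline and 5·(1 + 8·sep)
when elevated; negative-binomial counts with dispersion 10 (variance
μ + μ²/10, the overdispersion regime typical of amplicon counts) or
truncated-Gaussian noise; independent dropout zeroing (default 20 %)
mimicking sparse shallow sequencing. Because one planted cluster drives a
block in every modality, cross-kingdom associations exist by construction.
What it does **not** emulate: taxon–taxon compositional correlations,
library-size gradients, batch effects, phylogenetic structure, or realistic
rank-abundance tails — so passing tests demonstrate correct mechanics and
recoverability of planted structure, not performance on real microbiomes.

## Problem sizes and defaults used in the checks

The bundled checks run at n = 30 samples, 3 clusters, modalities of
40/30/20 features, k = 3, across a handful of seeds — small enough for the
full pipeline to run in seconds while leaving each cluster ~10 samples, a
size at which kernel affinities and Louvain communities are still
meaningful. The separation grid {0.2, 0.5, 1.0} spans weak to fully
separated planted signal; the ablation comparison runs at 0.4 where
clustering is not yet saturated for every variant.

## Known limitations

- Multiplicative updates converge to a stationary point of a non-convex
  objective; different initializations can give different factors. The
  deterministic NNDSVD/SNF initialization makes runs reproducible rather
  than globally optimal.
- Automatic α/γ are heuristic magnitude-matching rules; on data whose
  kernels are far from block structure they may need manual override.
- Exact permutation equivariance holds up to floating-point reassociation
  in matrix products (empirically ~1e-8 on the consensus matrix) and can
  break on exactly tied affinity row sums.
- With very strong dropout a sample column can lose all counts; the
  closure step rejects such samples rather than imputing.
- The silhouette's similarity-to-distance conversion and the SNF
  initializer's hyperparameters are documented conventions; results are
  insensitive to them in the tested regimes but they are conventions
  nonetheless.
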