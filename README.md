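# honmf

Integration of matched multi-kingdom microbiome profiles — bacterial, fungal
and viral composition tables measured on the **same samples** — by
hypergraph-regularized orthogonal non-negative matrix tri-factorization.
The package is aimed at microbiome researchers who have 2–3 abundance tables
over a shared sample set and want a single consensus view of sample
similarity that drives clustering, discriminative-taxon selection and
cross-kingdom association networks.

## The model

For each modality *i* with Gaussian-kernel sample affinity
*A<sub>i</sub>* ∈ ℝ₊ⁿˣⁿ, the model learns non-negative latent factors
*H<sub>i</sub>* (n×k), symmetric mixing matrices *G<sub>i</sub>* (k×k), and a
single consensus similarity *S* (n×n) by minimizing

```
J = Σᵢ ‖Aᵢ − Hᵢ Gᵢ Hᵢᵀ‖²_F            (tri-factor symmetric NMF fit)
  + (α/2) Σᵢ ‖S − Hᵢ Hᵢᵀ‖²_F          (graph fusion toward the consensus)
  + η Σᵢ ‖Hᵢᵀ Hᵢ − I‖²_F              (column orthogonality, η = 10)
  + β ‖S·1 − 1‖²                       (soft row-normalization of S, β = 1)
  + γ Σᵢ Tr(Hᵢᵀ L⁽ⁱ⁾ Hᵢ)              (hypergraph regularization)
```

subject to *H<sub>i</sub>, G<sub>i</sub>, S ≥ 0*. The Laplacian
*L⁽ⁱ⁾ = D<sub>v</sub> − P W D<sub>e</sub>⁻¹ Pᵀ* is built over a hypergraph
whose hyperedges are Louvain communities of each modality's KNN affinity
graph, so the regularizer penalizes disagreement of the latent factors
across whole sample communities (high-order relations), not just pairwise
edges. α and γ are selected automatically from the initialization
(NNDSVD factors, *G<sub>i</sub> = I*, SNF-fused *S*); optimization uses
monotone multiplicative updates with per-block backtracking. Replacing the
hypergraph Laplacian with a simple-graph Laplacian gives the `gonmf`
ablation variant; `no_alpha`/`no_gamma`/`no_eta` switch off single terms.

Downstream, the consensus *S* supports Louvain or spectral sample
clustering, discriminative-feature ranking by the Laplacian score
*SC(f) = (f̃ᵀLf̃)/(f̃ᵀDf̃)* of *S* (lower = more discriminative), and
cross-kingdom association edges defined by the Pearson correlation of
*S*-smoothed feature vectors (*â = a·S*), retained at |corr| > 0.5.

## Worked example

```python
from honmf import HONMF, simulate_multiomics, evaluate

# 30 samples, 3 planted clusters, three modalities (counts + dropout)
ds, truth = simulate_multiomics(30, 3, [40, 30, 20], separation=1.0, seed=0)

res = HONMF(ds, k=3, seed=0).fit()
print(res.summary())
labels = res.cluster_samples()                       # Louvain on KNN(S), k = n/2
rep = evaluate(res.S, labels, truth)
print(f"ARI = {rep.ari:.3f}  NMI = {rep.nmi:.3f}  silhouette = {rep.mean_silhouette:.3f}")

top = res.select_features("bacteria", 5)             # Laplacian-score ranking
edges, _ = res.association_network([10, 5, 5], threshold=0.5)
```

prints

```
Hypergraph-regularized orthogonal NMF tri-factorization
========================================================
samples: 30    modalities: 3 (bacteria, fungi, virus)
factors k: 3    variant: honmf
alpha: 0.2866    beta: 1    gamma: 4.246    eta: 10
iterations: 500 (converged: False)
objective: 40.9479 (initial 3357.03)

modality       fit resid    orth gap   consensus gap
bacteria          0.2486      0.4802          0.4822
fungi             0.2723      0.4934          0.5000
virus             0.3198      0.4848          0.4957

max |row sum of S - 1|: 0.0167

ARI = 1.000  NMI = 1.000  silhouette = 0.970
```

The consensus matrix recovers the three planted sample groups exactly
(ARI/NMI = 1); the per-modality residuals show how well each kernel is
explained by its k-factor decomposition, and the orthogonality / consensus
gaps quantify how close the factors are to a hard clustering shared across
kingdoms. The five top-ranked bacterial features all come from the planted
discriminative blocks, and the 80 retained association edges link features
driven by the same underlying sample cluster across kingdoms.

The same pipeline is available from the shell:

```bash
honmf simulate --n-samples 30 --n-clusters 3 --features 40,30,20 --seed 0 --out data/
honmf fit --modality data/bacteria.tsv --modality data/fungi.tsv \
          --modality data/virus.tsv --k 3 --seed 0 --out fit/
honmf cluster --s fit/S.tsv --out pred.tsv
honmf evaluate --s fit/S.tsv --labels pred.tsv --truth data/labels.tsv
honmf select-features --s fit/S.tsv --modality data/bacteria.tsv --top 10
honmf associations --s fit/S.tsv --modality data/bacteria.tsv \
          --modality data/fungi.tsv --modality data/virus.tsv --out edges.tsv
```

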