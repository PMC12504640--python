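# nichescope

Self-supervised spatial-domain discovery for spatial transcriptomics.

Organ-scale spatial transcriptomics (MERFISH, Slide-seqV2) measures, for
millions of cells, a transcript count vector, a 2D position, and a cell-type
call. A central analysis question is *parcellation*: which spatially
coherent tissue domains — cortical layers, nuclei, niches — do the cells
form? nichescope addresses this with a representation-learning workflow for
computational biologists who want fine-grained, data-driven domains without
hand-drawn references:

1. **Neighborhoods.** Every cell within a fixed-size box (side `w`, cell
   `j` neighbors reference `i` iff `max(|xi−xj|, |yi−yj|) ≤ w/2`, same
   section only) forms the reference cell's neighborhood.
2. **Masked-cell model.** A transformer encodes the neighbors (expression
   MLP ⊕ type embedding per cell, plus a register token), pools them with a
   learned attention query into one neighborhood vector `z ∈ R^d`, and a
   shallow decoder conditioned on the reference cell's *type* predicts the
   reference cell's raw counts `y` under a zero-inflated negative binomial,

       y_g ~ π_g δ₀ + (1 − π_g) · NB(μ_g = s·m_g, θ_g),   Σ_g m_g = 1,

   trained by minimizing the masked-cell negative log-likelihood. The
   reference's own expression is never an input, so `z` must summarize
   spatial context.
3. **Domains.** Neighborhood vectors for all cells, concatenated across
   sections, are clustered with minibatch-capable k-means (k-means||
   seeding, oversampling 3, `n_init=3`, `max_iter=1000`), optionally after
   Gaussian smoothing (σ = 12.01 µm) over the cell cloud. The number of
   domains can be scanned with a stability criterion: replicate clusterings
   compared by an Amari-type centroid dissimilarity
   `diss(D,D′) = (1/2K)(2K − Σ_k max_j C_kj − Σ_j max_k C_kj)`.
4. **Evaluation.** Spatial homogeneity (fraction of 100 nearest same-section
   neighbors sharing a cell's label), discreteness vs a reference
   parcellation, domain × cell-type composition matching (best-match and
   exclusive linear-sum-assignment Pearson r), NMI/ARI, marker genes
   (log2FC ≥ 1), linear probes (coordinates, donor), and cross-animal
   domain presence.

Everything runs on CPU: the model and its training loop are built on a
small reverse-mode autodiff core over numpy, with exact (bitwise)
invariance of a neighborhood's embedding to neighbor order and batch
composition. A ground-truth synthetic generator (spatially contiguous
domains, domain-specific type composition, type- and domain-dependent ZINB
counts) makes the entire pipeline testable without downloading an atlas.

## Worked example

Five-minute desk-scale run: generate a tissue with 5 planted banded
domains, train the reduced model, and recover the domains.

```python
import nichescope as ns

ds = ns.generate_dataset(ns.SyntheticConfig(seed=7))      # 2 x 2,500 cells, 5 domains
table = ds.table
index = ns.build_neighborhood_index(table, ns.NeighborhoodConfig(box_width=40.0))

model = ns.CellTransformer(ns.ModelConfig.small(table.n_types, table.n_genes), seed=7)
tr, te = ns.split_train_test(table, 0.8, seed=7)
result = ns.train(model, table, index, ns.TrainConfig.desk_scale(seed=7), tr, te)
print([round(v, 3) for v in result.test_nll])

emb = ns.compute_embeddings(model, table, index)
emb = ns.smooth_embeddings(emb, table, sigma=12.01)
emb = ns.spherize_embeddings(emb, n_components=5)
labels = ns.cluster_domains(emb, k=5, n_init=10, seed=0)
nmi, ari = ns.clustering_agreement(labels, ds.domain_labels)
print(f"ARI {ari:.3f}  NMI {nmi:.3f}")
print(f"homogeneity {ns.spatial_homogeneity(table, labels).dataset_mean:.3f}")
```

Output from this exact run:

```
[2.367, 2.313, 2.264, 2.241, 2.203]
ARI 0.962  NMI 0.948
homogeneity 0.921
```

The held-out masked-cell NLL (nats per gene) falls epoch over epoch to
2.203, below both the type-conditional (2.225) and global (2.398)
mean-expression baselines — the model has learned expression information
that lives in the spatial context, not just in the cell type. Clustering
the embeddings at the true k recovers the planted bands almost exactly
(ARI 0.96), and the detected domains are spatially smooth (92 % of each
cell's 100 nearest neighbors share its label).

A command-line interface mirrors the library:

```bash
nichescope simulate --out data/ --seed 7
nichescope train --data data/cells.h5ad --out ckpts/ --box-width 40 --embed-dim 64 \
    --encoder-layers 2 --decoder-layers 2 --epochs 5
nichescope embed --data data/cells.h5ad --checkpoint ckpts/epoch_004.npz \
    --out emb.npz --box-width 40 --smooth-sigma 12.01
nichescope cluster --embeddings emb.npz -k 5 --out labels.tsv
nichescope evaluate --data data/cells.h5ad --labels labels.tsv \
    --ref data/truth_labels.tsv --metrics homogeneity,agreement
```

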