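# Methods

## The model

nichescope learns a representation of a *cellular neighborhood* — every cell
within a fixed-size box centered on a reference cell — by training a small
transformer to predict the reference cell's raw transcript counts from its
context alone. Cell `j` neighbors reference `i` iff
`max(|xi−xj|, |yi−yj|) ≤ w/2` (Chebyshev rule); `w` is the full box side
length, 85 µm by default for MERFISH-scale panels and 50 µm for denser
assays. A config switch (`width_is_full=False`) reinterprets the value as
the half-width, since the literature is ambiguous about this convention.
Neighborhoods never cross tissue-section boundaries: sections are physically
separate pieces of tissue.

Each neighbor cell becomes a d-dimensional token by concatenating

* a two-layer GELU perceptron applied to its log1p counts (d/2 dims), and
* a learned embedding of its categorical cell type (d/2 dims).

The reference cell's own token is **excluded**; the model sees only context.
The neighborhood's tokens plus one learned *register token* pass through
pre-norm self-attention blocks restricted to the neighborhood (8 heads,
GELU MLPs with ratio 4, biases in the Q/K/V projections only — a bias there
stabilizes training; elsewhere it makes no measurable difference). Attention
pooling — multi-head cross-attention from a single learned query — collapses
the tokens into one d-vector, the *neighborhood representation*.

A shallow decoder then refines the pair (neighborhood vector, a second
type-specific mask embedding for the reference cell), with attention allowed
only within the pair. Linear heads on the masked-cell token emit the four
parameters of a zero-inflated negative binomial (ZINB) over the reference
cell's raw counts:

* `mean` — a probability simplex over genes (softmax), the expression profile;
* `scale` — a positive per-cell library-size factor, so `μ = scale · mean`;
* `dispersion` — per-gene θ, via softplus;
* `zero_inflation_logit` — per-gene logit of the extra zero mass π.

With π pinned to 0 (logit −∞) the likelihood reduces exactly to a plain
negative binomial; `likelihood="nb"` selects that variant. The NLL is
computed in log space with `logaddexp` at y = 0, so it is stable for extreme
logits and large θ.

Two deliberate parameterization choices:

* The mean head factorizes into simplex × scale. The standard count-model
  decomposition separates *what* a cell expresses from *how much* was
  captured, and matches a four-headed output naturally.
* The scale head uses a log link (`exp`), not softplus. Softplus has an
  additive gradient: starting near softplus(0) ≈ 0.7, reaching a library
  size of hundreds would take thousands of optimizer steps. The log link's
  multiplicative gradient covers orders of magnitude within an epoch; it is
  also the canonical count-GLM link. Dispersion keeps softplus (θ lives
  within one order of magnitude). The zero-inflation head bias is
  initialized to −3 (π ≈ 5 %): transcript zeros beyond NB sampling are rare,
  and starting at π = 0.5 wastes early optimization.

Ablations: `use_type_encoder=False` / `use_type_decoder=False` replace the
corresponding type-embedding table with a single shared embedding,
reproducing the "no cell type in the encoder/decoder" model variants; the
parameter count shrinks by exactly (C−1)·dim per disabled table.

## The autodiff core

The network and its training loop run on `nichescope._tensor`, a compact
reverse-mode automatic differentiation engine over numpy float64 arrays
(broadcasting arithmetic, matmul, reductions, gather/scatter, masked
softmax, layer norm, log-gamma, logaddexp). Two properties are designed in
rather than hoped for:

* **Exact permutation invariance.** Neighbor indices are canonically sorted
  at batch assembly and again before pooling, so reordering a caller's
  neighbor list cannot change even the last bit of the pooled vector.
* **Exact batch-composition invariance.** Every neighborhood is processed
  as its own unpadded sequence, and the decoder processes each reference
  pair separately. No computation ever mixes array extents across
  neighborhoods, so a neighborhood embeds bit-identically whether batched
  alone or with a thousand others. (A padded batched formulation is faster
  on GPUs but, with BLAS, padding changes summation micro-order by one ulp;
  at desk scale the loop is cheap and exactness is worth more.)

Gradients were verified against central finite differences end-to-end
(~1e-9 agreement through both transformer stacks and the ZINB loss).

## Training

Adam (β = 0.9/0.999, ε = 1e-8 — conventional, recorded in config) minimizes
the masked-cell ZINB NLL. The learning rate follows
`lr(t) = peak · min(t/w, sqrt(w/t))`: linear warmup over `w` steps to the
peak, then continuous inverse-square-root decay (the specific analytic form
is a recorded choice; the curve is continuous and peaks exactly at `w`).
Decoupled weight decay applies only to weight matrices (not norms, biases,
embeddings, or the pooling query) at its full rate from step 1 — it is not
warmed up and not scaled by the lr schedule. Each epoch visits every
training reference once in shuffled order; the held-out split is scored
(no gradients) at each epoch end; a NaN loss aborts with step, lr and batch
diagnostics. Runs are bit-reproducible given the config seed.

Full-scale defaults: 40 epochs, effective batch 256, warmup 500 steps, peak
1e-3, weight decay 5e-5, 80/20 random train/test split. The *desk-scale*
recipe (`TrainConfig.desk_scale()`), used by the integration tests and the
acceptance script, keeps the 5-epoch budget but uses batch 16, warmup 50
and peak 2e-3: a desk-scale run takes ≈1,250 optimizer steps in total, so a
500-step warmup would never reach peak, and more, smaller steps converge
further within the same cell-visit budget.

The reference baseline (`mean_expression_baseline_nll`) predicts each
held-out cell's counts as the training-split mean profile of its cell type
(or the global mean), with per-gene moment-matched NB dispersions. A
context-conditioned model must beat it to demonstrate that spatial context
carries expression information beyond type identity.

## Domain detection

Embeddings for all cells across all sections are concatenated and clustered
with k-means: Lloyd's algorithm with k-means||-style seeding (oversampling
factor 3, 5 rounds, weighted k-means++ reduction), `n_init=3`
restarts, `max_iter=1000`, convergence at relative inertia change < 1e-6.
Assignment and update run in memory-bounded chunks that are *exactly*
equivalent to full-batch steps. Empty clusters are re-seeded from the
current farthest point; inertia is asserted non-increasing on every
ordinary iteration.

Optional Gaussian smoothing before clustering operates on the point cloud
(kernel regression over same-section cells, self included, truncated at
3σ by default): σ = 12.01 µm follows the published operative value even
though the accompanying "40 µm FWHM" would imply σ ≈ 16.99 µm under the
Gaussian FWHM relation — the two are mutually inconsistent and both remain
settable.

`spherize_embeddings` (PCA whitening of the top components, a good default
being the k to be fit) is an optional preprocessing step that desk-scale
models need: a small model trained for 5 epochs concentrates >90 % of
embedding variance in one or two directions while still encoding domain
identity in weaker ones, and raw Euclidean k-means then quantizes the
dominant axis only. Full-scale models trained to their loss plateau spread
variance far more evenly, which is why plain k-means suffices there.

### Stability criterion

For each candidate k, 20 replicate clusterings (distinct seeds, each the
best of `n_init=3` starts — single-start replicates measure seeding luck
rather than solution multiplicity) yield centroid sets compared by the
Amari-type dissimilarity

    diss(D, D′) = (1/2K) · (2K − Σ_k max_j C_kj − Σ_j max_k C_kj),

where C is the K×K Pearson correlation matrix between centroids, computed
across embedding dimensions after centering each centroid vector. diss is
0 iff the sets coincide up to permutation and is bounded by 2; a constant
centroid makes the correlation undefined and raises an error naming it.
Instability at k is the mean diss over all unordered replicate pairs.

`select_k` min-max normalizes the mean-inertia and instability curves,
averages them, takes the second derivative by central differences on the
grid, and returns the first k where it changes sign (none → `None` with a
warning). Min-max normalization makes the two terms scale-free; this, and
mean-over-pairs as the instability aggregate, are recorded choices.

## Evaluation metrics

* **Spatial homogeneity** — per cell, the fraction of its 100 nearest
  same-section spatial neighbors (self excluded; clamped with a warning in
  sections smaller than the neighbor count) sharing its domain label;
  reported per cell, per domain, and as the dataset mean.
* **Discreteness** — a domain is discrete iff its mean homogeneity reaches
  the 20th percentile of a reference parcellation's per-domain values.
* **Composition matching** — domain × type row-normalized abundance
  matrices compared by Pearson correlation: best match per row
  (non-exclusive) or an exclusive one-to-one pairing via linear sum
  assignment (rectangular inputs matched over min(K) pairs, logged).
* **NMI/ARI** — standard, NMI with arithmetic normalization (recorded).
* **Linear probing** — OLS (SVD-based, minimum-norm under rank deficiency)
  from embeddings to coordinates, reporting median and mean per-cell
  Euclidean error (both, since either may be of interest); multinomial
  logistic regression for donor identity with per-donor accuracy. A single
  fit on all data, matching descriptive use; no cross-validation.
* **Spatial contribution** — per cell-type mean gain in Pearson correlation
  of predicted vs observed counts over a dataset-mean predictor;
  zero-variance observations are skipped and counted.
* **Marker genes** — per domain, genes with log2 fold change ≥ 1 between
  pseudocounted (+1) mean counts inside vs outside the domain.
* **Cross-animal consistency** — fraction of domains carrying ≥ `min_cells`
  (default 10, an exposed choice) cells in every animal.

## The synthetic generator

`generate_dataset` emulates the structure that makes niche detection
possible in real tissue: spatially contiguous domains (layered bands,
Voronoi territories, or grid blocks), domain-specific cell-type composition
(Dirichlet draws, concentration 0.5, mixed with 2 % uniform so every type
remains observable), and ZINB counts whose log-means add a type profile
(sd 1) and a domain effect (sd `expression_effect`, default 1.0 — a strong,
clearly recoverable signal). Counts are sampled as a gamma–Poisson mixture
with per-gene dispersions drawn log-uniformly in [0.5, 8] and Bernoulli
zeroing at rate 0.05; per-cell depth is lognormal around 300 counts
(sd 0.25 on the log scale). `generate_multi_animal` shares all geometry and
parameters across animals, samples each animal independently, and can plant
per-animal depth shifts or domain omissions.

Desk-scale defaults: 2 sections × 2,500 cells in a 150 × 1000 µm strip with
5 horizontal bands. The strip is deliberately narrow: each band is then
wide relative to the ~45 µm radius containing a cell's 100 nearest
neighbors, so the *true* labels score ≥ 0.9 homogeneity — boundary mixing,
not signal strength, is the ceiling on that metric. The integration
pipeline pairs this density (~0.017 cells/µm²) with a 40 µm box
(~25 neighbors per reference), the same density-matching reasoning that
leads to 50 µm boxes for bead-deconvolution data.

What the generator does **not** emulate: real anatomy or gene panels,
section-to-section geometry changes, segmentation errors, spatially graded
(rather than piecewise-constant) expression, batch effects beyond a scalar
depth shift, or registration noise. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated model, not
performance on any real atlas.

## Problem sizes

The test suite and acceptance script run everything at desk scale: 5,000
cells for the end-to-end experiment (reduced model d=64, 2+2 layers,
4 heads, 5 epochs), 600-cell fixtures for unit tests, and stability scans
over k = 2…10 with 20 replicates on 5,000 cells. These sizes were chosen so
the complete pipeline — data generation through evaluation — finishes in a
few minutes on a single CPU core while leaving the planted structure
clearly recoverable.

## Known limitations

* No GPU path; the numpy autodiff core is exact but not fast. Scaling to
  millions of cells requires porting the model to a tensor framework.
* k-means semantics at desk scale depend on the spherize preprocessing (see
  above); the stability scan is demonstrated on smoothed neighborhood
  composition vectors, whose cluster structure is crisp at this scale.
* The stability-based choice of k is a heuristic; on small grids the second
  derivative of a noisy curve can shift the selection by one or two grid
  points.
* Checkpoints store raw float64 weights; no versioned migration beyond a
  config-shape check.
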