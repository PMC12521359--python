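# Methods

`schicembed` is a benchmarking-oriented toolkit for single-cell Hi-C (scHi-C)
embedding. This note documents the models and procedures it implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Data model

All backends consume per-cell **contact tables**: cis contacts binned at a
fixed resolution with canonical `bin1 <= bin2` keys and positive integer
counts. Input positions are treated as 1-based (the pairs-file convention);
bins are 0-based half-open intervals `[bin*res, (bin+1)*res)`. Intra-bin
contacts (`bin1 == bin2`) are retained and contribute to stratum 0. Trans
(inter-chromosomal) contacts are dropped at read time; every method here is
cis-only. Duplicate records are summed on read; no PCR-duplicate logic is
applied (inputs are assumed deduplicated upstream).

Three derived representations are used:

* **dense per-chromosome matrices** (substrate of the normalization /
  smoothing / imputation operators),
* **strata** — the first k diagonals of each chromosome matrix, stratum `s`
  holding all contacts at genomic distance `s` bins,
* **cell x locus-pair feature matrices** over the observed vocabulary of
  binned pairs inside a distance window.

The default distance ceiling for strata-based methods is 20 Mb
(`n_strata = floor(20 Mb / resolution)`), wide enough to cover both the
loop-scale (< 2 Mb) and compartment-scale (> 2 Mb) regimes that the
distance-truncation experiments contrast.

## Quality control

A cell is dropped iff it has *fewer than* 5,000 cis contacts (the threshold
is configurable; stricter 50k/100k variants are plain parameter changes), or
if any chromosome of length x Mb carries fewer than x contacts. `x` is
`ceil(length / 1 Mb)`; the report records the first failing rule per cell.
The threshold counts table counts as given (no attempt to distinguish raw
reads from deduplicated contacts).

Mitotic-like cells are flagged from the (f_local, f_mitotic) scatter, where
f_local is the fraction of >25 kb contacts that fall in 25 kb–2 Mb and
f_mitotic the fraction in 2–12 Mb. A 2-sigma covariance ellipse summarizes
the scatter; the line through the configurable cutoff point (default
(0.15, 0.35)) and the ellipse center splits the plane, and the
high-local/low-mitotic side is labelled G-S. We use the cutoff-to-center
line rather than a line parallel to the ellipse's major axis because, on
cell-cycle-like data, the major axis runs *along* the G-S-to-mitotic cluster
axis, so a parallel line separates nothing. Degenerate scatters
(rank-deficient covariance) raise an error advising a manual threshold.

## Preprocessing operators

All operators are decoupled from the backends and chainable:

* `truncate_distance(min_bp, max_bp)` — keep contacts with
  `min_bp <= d < max_bp`; idempotent; composing two truncations equals
  truncating to the window intersection.
* `vc_sqrt_norm` — `out_ij = m_ij / sqrt(r_i r_j)` with `r` the row sums;
  zero-coverage rows stay zero.
* `box_filter(w)` — exact mean over a `(2w+1)^2` window, clipped at matrix
  edges (summed-area-table implementation); `w=0` is the identity.
* `random_walk(p, tol, max_iter)` — restart-style graph diffusion: with
  row-stochastic `P` (zero rows become self-loops), iterate
  `R <- p R P + (1-p) I` from `R = I` until `max|dR| < tol` (default 1e-6)
  or 30 iterations; the fixed point is `(1-p)(I - pP)^{-1}` and serves as
  the test oracle. The restart probability defaults to 0.5; no
  per-iteration renormalization beyond the initial row-stochasticity is
  applied. Output is symmetrized `(R + R^T)/2`.
* `idf_transform` — column `j` scaled by `log(1 + N/(1 + n_j))`, `n_j` the
  number of cells with the feature. The +1 smoothing avoids division by
  zero; the weight is strictly decreasing in `n_j` and the zero pattern is
  unchanged.
* `select_features(q_low, q_high, top_n)` — drop features whose total falls
  below the `q_low` or above the `1-q_high` quantile of feature totals
  (defaults 0.5% each), then keep the `top_n` strongest by mean signal
  (default 500,000; synthetic runs configure much smaller values), ties
  broken by feature-key order.
* `zscore_strata` — each stratum vector is centered and scaled to unit
  *population* (1/n) variance; zero-variance strata map to zero vectors.

## Embedding backends

All backends are scikit-learn-style estimators (`fit` / `fit_transform`,
fitted `embedding_`), restricted to a `[min_bp, max_bp)` distance window.
PCA steps center but do not scale features; component signs are fixed
deterministically (largest-magnitude loading positive).

* **BinCoveragePCA** (1D baseline): per-bin coverage vectors (each contact
  increments both endpoint bins; intra-bin contacts increment twice),
  normalized to sum 1, then PCA.
* **SCHiCluster**: per chromosome, VC-sqrt -> box filter (w=1) -> random
  walk -> binarize the strongest 20% of entries (ties at the threshold
  included; `top_frac=None` disables binarization, which reduces the chain
  to a 2D PCA of the processed matrices — used as a regression guard);
  per-chromosome PCA (20 components by default — the cited method does not
  state the count) concatenated, then a final PCA. The chain runs in
  float32; at the 1e-6 convergence tolerance this does not change results
  at the precision the method uses them.
* **InnerProductMDS**: per chromosome and stratum, the inner product of
  z-scored strata divided by the stratum length — the Pearson correlation
  of the raw strata. Uniform stratum weighting gives the inner-product
  variant; weights `N_s * sigma_i * sigma_j` computed on the *raw* strata
  give the stratum-adjusted correlation coefficient (fastHiCRep) variant,
  in which distal strata with surviving variance carry more weight.
  Chromosomes are aggregated by the median (mean available). Cell-cell
  similarities map to distances `d = sqrt(2(1-s))` and classical
  (Torgerson) MDS: double-center `-D^2/2`, top eigenpairs, coordinates
  `V sqrt(lambda)`; negative eigenvalues truncate at zero and missing
  positive dimensions pad with zero columns (with a warning).
* **SpectralIDF**: locus-pair features -> quantile/top-N selection -> IDF
  -> cosine similarity `S` of L2-normalized rows -> symmetric normalization
  `D^{-1/2} S D^{-1/2}` -> eigendecomposition; the leading trivial
  eigenvector is dropped and the next `d` eigenvectors, *weighted by their
  eigenvalues*, are the coordinates. The eigenvalue weighting follows the
  cited spectral tool's convention; without it, near-degenerate noise
  dimensions (per-cell depth variation) dominate Euclidean K-means even
  when the informative dimension separates the populations.
* **CisTopicLDA**: a "word" is a binned locus pair, a "document" a cell.
  Collapsed Gibbs sampling with symmetric priors `alpha = 50/T`,
  `beta = 0.1` (300 iterations by default); the embedding is the smoothed
  per-cell topic distribution (no further PCA — the topic proportions are
  already low-dimensional and sufficient for K-means). The hot loop is a
  numba kernel with a pure-python fallback.
* **InsulationPCA**: insulation of bin `i` is the total signal in the
  square window bridging it (rows `i-w..i-1` by columns `i+1..i+w`,
  default `w=10`), log2-normalized by the chromosome mean over defined
  bins; bins with empty or edge-truncated windows are treated as undefined
  and set to 0 after normalization. The boundary-sensitive delta vector
  (mean over `delta_w` bins downstream minus upstream, default 3) is
  concatenated across chromosomes and reduced by PCA.

## The convolutional Gaussian-mixture variational embedder

The deep backend models a cell's **band image** — the first k strata of all
chromosomes stacked into a k x L array (chromosomes side by side, one zero
column between them) — with the generative model
`p(x, z, c) = p(x|z) p(z|c) p(c)`: a categorical cluster assignment, a
cluster-specific diagonal-Gaussian latent, and a Poisson observation model
(Bernoulli available for very sparse data).

Architecture: four encoder blocks of two 3x3 convolutions (filters
4, 8, 16, 32), the second convolution of each block with stride 2 along
both axes while the strata axis allows it (the genome axis is always
strided); a dense layer maps the final feature maps to the latent mean and
log-variance. The decoder mirrors this with nearest-neighbour upsampling
followed by two convolutions per block (filters 32, 16, 8, 4) and a final
1x1 convolution onto the output parameters. Upsample-plus-convolution is
used as the learned upsampler instead of transposed convolutions; it is the
standard resize-convolution equivalent and keeps the hand-written backward
passes simple enough to verify by finite differences (which the test suite
does). The network is trained with Adam (learning rate 3e-4, decoupled
weight decay 1e-4 by default) in float32; ELBO values are accumulated in
float64.

Sequencing depth is a nuisance axis, so the model carries an explicit
per-cell library-size factor (cell total over the mean training total): the
encoder sees `log1p` of depth-normalized images while the Poisson rate is
rescaled back per cell. Without this, the leading latent dimensions encode
coverage rather than architecture.

Training maximizes the ELBO: Poisson negative log-likelihood plus
`KL(q(z,c|x) || p(z,c))`, with `q(c|x)` computed from the posterior mean of
`q(z|x)` by Bayes' rule under the current mixture. Gradients flow both at
fixed responsibilities and *through* the responsibility softmax; the latter
term is the winner-take-all pressure that lets surplus mixture components
lose their prior mass as training sharpens. The first 40% of epochs (by
default) are a reconstruction-only warm-up, after which the mixture is
initialized by fitting a diagonal Gaussian mixture to the warm latents and
trained with its own, larger Adam step (3e-2) — latent blobs must be formed
before mixture consolidation starts, and the mixture must consolidate faster
than the network drifts for surplus components to empty within a desk-scale
budget;
with a single unit-variance component the bound reduces exactly to the
standard VAE ELBO (verified against an independently coded oracle).

Desk-scale defaults: latent dimension 10, an overparameterized mixture
(more components than expected populations — unused components end with
near-zero weight as responsibilities sharpen), 120 epochs, batch size 64.
At the reduced training volumes used here (hundreds of cells rather than
the thousands-of-cells x ~1000-epoch regime the method targets), the
bundled evaluation scripts raise the network learning rate to 1e-3 to reach
convergence within budget.

## Evaluation stack

Embedding quality is scored by clustering with K-means (10 restarts,
seeded; k fixed to the ground-truth class count so all backends produce
comparable partitions) and computing:

* **ARI** — chance-corrected pair-counting agreement,
* **NMI** — mutual information normalized by the arithmetic mean of the
  two label entropies, clipped to [0, 1],
* **ASW** — mean silhouette width under cosine distance, using the
  ground-truth labels,
* **AvgBIO** — the mean of ARI, NMI and ASW with ASW rescaled from
  [-1, 1] to [0, 1] so all three terms share a scale. The raw-ASW average
  is reported alongside, since the rescaling convention is not canonical.

ARI/NMI/ASW are computed via scikit-learn; the test suite checks them
against independent brute-force pair-counting and direct-formula oracles on
exhaustive small instances. The repeat harness reruns stochastic stages
with seeds `base_seed + i` (default 5 repeats) and reports mean ± SEM.
Deterministic backends are embedded once and only the clustering is
repeated. The benchmark summary ranks methods per dataset by percentile
rank (1 = best, ties share the mean position), takes each method's median
across datasets, and selects the best variant (e.g. resolution) per dataset
group by mean ARI.

## Diagnostics

* **Per-strata similarity map**: for each stratum, z-scored inner products
  between all cell pairs per chromosome, median across chromosomes, then
  each cell's median similarity to all *other* cells (self excluded);
  columns are min-max normalized (constant columns map to 0). This
  localizes cell-cell heterogeneity along the distance axis.
* **Fraction scatter**: per-cell (f_local, f_mitotic), separating
  interphase from mitotic-like cells.
* **Compartment PC1**: a pseudo-bulk chromosome matrix is normalized to
  observed/expected by distance (expected = per-stratum mean, unsmoothed —
  adequate at synthetic depths), converted to a bin-bin Pearson correlation
  matrix, and reduced to its first principal component. The sign is
  oriented against a supplied reference track (the generator's ground
  truth); histone-mark-based orientation is out of scope for synthetic
  data. The result is invariant to global depth scaling.
* **IDF stratum profile**: the mean IDF weight per stratum over the
  complete locus-pair universe of the window (pairs unobserved in every
  cell carry the maximal, df = 0, weight). On decay-only data this profile
  rises with distance — the distance bias of IDF weighting. The
  monotonicity property is asserted over the first 40 strata (0–4 Mb at
  100 kb): beyond that, the expected per-stratum increment falls below the
  binomial sampling noise of document frequencies at any desk-scale cell
  count, so a strict per-stratum check is not meaningful there.

## Synthetic data generator

Each population is a probability model over cis contacts:
`E_ij = (1 + d_ij)^(-alpha) * c_ij * l_ij`, with a power-law decay
(`alpha = 1` by default, in the range observed for interphase Hi-C), a
compartment factor `c` equal to `1 + kappa` for same-compartment and
`1 - kappa` for cross-compartment pairs at distances >= 2 Mb (1 below), and
loop boosts `l = lambda` at short-range anchor pairs. A mitotic shift `m`
reallocates a fraction `m` of probability mass into the 2–12 Mb band,
emulating condensed M-phase chromosomes. Cells are exact-depth multinomial
draws; depths are lognormal with median 20,000 cis contacts and sigma 0.35
(a realistic 2–3x spread), floored at 5,001 so generated cells pass QC by
construction (QC is tested separately with injected violations).

Compartment tracks are random ±1 assignments in 1 Mb blocks, drawn
independently per population: two independent tracks disagree on about half
of all pair relations, which is what creates contrast (a globally
sign-flipped checkerboard would leave every pair relation — and hence the
expected map — unchanged). Default geometry is 2 chromosomes x 400 bins at
100 kb, so 2 Mb = 20 bins and the 2–12 Mb band exists inside each
chromosome. No trans contacts are generated.

Presets (each with an explicit ground-truth sidecar):

* `compartment-contrast` — two populations differing only in compartment
  tracks (kappa = 0.4): separable from long-range contacts only.
* `loop-contrast` — two populations sharing compartments (kappa = 0.3) and
  differing only in 30 loop anchors per chromosome at 3.5x enrichment.
  The boost sits deliberately in the subtle regime typical of chromatin
  loops (2–6x focal enrichment): strong enough that short-range contacts
  separate the populations, fine enough that compartment-biased smoothing
  (random walk) erases part of the contrast — the regime the preset exists
  to represent.
* `cell-cycle-like` — a G-S-like and a mitotic-like population
  (m = 0.5) with shared compartments and loops.
* `mixed-tissue` — three populations with independent compartment tracks
  (kappa = 0.4) and distinct loop sets (5x), a multi-signal "tissue" that
  every backend can resolve at full depth (used for the downsampling
  stress test).
* `three-population-small` — three strongly contrasted populations
  (kappa = 0.5, 6x loops) on small 64-bin chromosomes, sized for training
  the convolutional embedder on one CPU.
* `power-law` — a single featureless decay-only population (null model for
  the IDF bias analysis).

What the generator does **not** emulate: TAD-scale nested domains, locus-
and GC-dependent coverage biases, trans contacts, allele effects, protocol
chimeras, or realistic polymer physics. Passing tests therefore show that
each method responds to controlled distance-scale structure as expected —
not that it will reach any particular score on real tissue.

## Problem sizes and numerical choices

The bundled evaluation scripts run at desk scale: 50–100 cells per
population for the conventional backends, 300 cells for the deep embedder,
5 seeded repeats for headline comparisons (2 for the downsampling grid),
and 60 Gibbs iterations for the topic model inside the grid. Tolerances:
random-walk convergence 1e-6 (closed-form agreement tested at 1e-5), MDS
eigenvalue truncation at 1e-12, ELBO oracle agreement at 1e-6. Degenerate
inputs (all-zero matrices, zero-variance strata, empty distance windows,
rank-deficient fraction scatters) are handled explicitly as documented
above rather than producing NaNs.

## Known limitations

* The deep embedder runs on a self-contained numpy core; it is intended
  for desk-scale experiments, not atlas-scale training.
* Classical MDS and the similarity backends build N x N matrices; memory
  is quadratic in cell count.
* The mixture-collapse behavior of the deep embedder (surplus components
  emptying) strengthens with training volume; at the reduced volumes used
  here the surplus weights are small but need the bundled training length
  to fall below 1%.
* Louvain/Leiden resolution matching, hypergraph and tensor backends, gene
  scores, and multi-modal integration are out of scope.
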