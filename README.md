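# schicembed

Single-cell Hi-C (scHi-C) embedding toolkit: decoupled preprocessing,
seven embedding backends, a clustering-evaluation stack, distance-scale
diagnostics, and a multiscale synthetic contact-map generator with known
ground truth.

## Who this is for

scHi-C experiments measure pairwise genomic contacts in individual cells.
Placing cells in a low-dimensional space ("embedding") is the first step of
almost every analysis, but methods differ enormously in which *genomic
distance scale* they listen to: Mb-scale A/B compartments, sub-Mb loops, or
the 2–12 Mb band typical of mitotic chromosomes. `schicembed` is for
computational biologists who want to (i) embed scHi-C data with any of the
standard approaches behind one interface, (ii) understand *why* a method
succeeds or fails on a given dataset by toggling individual preprocessing
steps, and (iii) validate all of it against simulations where the generating
structure is known exactly.

## What is inside

**Preprocessing** (chainable, independent of the backend): distance
truncation, vanilla-coverage square-root normalization, box-filter
smoothing, random-walk-with-restart imputation `R = (1-p)(I - pP)^{-1}`,
inverse-document-frequency weighting `log(1 + N/(1+n_j))`, quantile/top-N
feature selection, per-stratum z-scoring.

**Backends** (scikit-learn estimator style — `fit_transform(cells)`,
fitted `embedding_`):

| class | idea |
|---|---|
| `BinCoveragePCA` | 1D bin-coverage baseline + PCA |
| `SCHiCluster` | VC-sqrt → box filter → random walk → top-20% binarize → PCA |
| `InnerProductMDS` | z-scored strata Pearson similarities + classical MDS (`weights="scc"` gives the stratum-adjusted-correlation variant) |
| `SpectralIDF` | locus-pair features → IDF → normalized spectral embedding of cosine similarity |
| `CisTopicLDA` | topic model over locus pairs (collapsed Gibbs) |
| `InsulationPCA` | insulation-score delta vectors + PCA |
| `vade.Va3DE` | convolutional variational embedder with a Gaussian-mixture latent prior over stacked strata "band images" |

**Evaluation**: K-means (k = true class count), ARI, NMI, cosine-distance
ASW, the AvgBIO composite, a seeded repeat harness (mean ± SEM), and a
median-percentile-rank benchmark summary.

**Diagnostics**: per-strata similarity heatmaps (which distances carry the
heterogeneity), local/mitotic contact-fraction scatters, pseudo-bulk
compartment PC1, and the IDF-weight-per-stratum profile.

**Synthetic data**: populations defined by power-law decay, A/B compartment
checkerboards acting beyond 2 Mb, short-range loop sets, and a mitotic
2–12 Mb band shift; cells are exact-depth multinomial draws with lognormal
depth variation. Presets: `compartment-contrast`, `loop-contrast`,
`cell-cycle-like`, `mixed-tissue`, `three-population-small`, `power-law`.

See `docs/methods.md` for models, parameters, and numerical choices.

## Worked example

```python
import pandas as pd
import schicembed as se
from schicembed.synthetic import preset, generate_dataset

# two populations that differ only in their A/B compartments
cells, labels, truth = generate_dataset(
    preset("compartment-contrast", seed=1, cells_per_pop=50))
truth_codes = pd.factorize(labels)[0]

# embed from long-range (>2 Mb) contacts only, then from short-range only
long_range = se.InnerProductMDS(n_components=2, min_bp=2e6).fit_transform(cells)
short_range = se.InnerProductMDS(n_components=2, max_bp=2e6).fit_transform(cells)

from schicembed.evaluation import evaluate_embedding
print(evaluate_embedding(long_range, truth_codes))
print(evaluate_embedding(short_range, truth_codes))
```

Output (seed 1):

```
{'ari': 1.0, 'nmi': 1.0, 'asw': 0.7859, 'avgbio': 0.9643, 'avgbio_raw_asw': 0.9286}
{'ari': -0.0083, 'nmi': 0.0012, 'asw': -0.0072, 'avgbio': 0.1631, 'avgbio_raw_asw': -0.0048}
```

The populations are perfectly separable from compartment-scale (>2 Mb)
contacts (ARI 1.0) and indistinguishable from loop-scale contacts alone —
the compartment checkerboard is the only difference between them, and the
embedding finds it exactly where it lives on the distance axis.

The same workflow runs from the shell:

```bash
schicembed simulate --preset compartment-contrast --seed 1 --outdir sim/
schicembed embed --data sim/ --backend innerproduct --min-bp 2e6 --outdir emb/
schicembed eval --embedding emb/embedding.tsv --labels sim/labels.tsv --outdir eval/
```

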