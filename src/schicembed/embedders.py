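"""Embedding backends: cells in, N x d coordinates out.

Six conventional backends share a scikit-learn estimator contract
(``fit`` / ``fit_transform``, fitted ``embedding_`` attribute, parameters via
``get_params``/``set_params``), the same pattern as
:class:`sklearn.manifold.MDS`:

* :class:`BinCoveragePCA` — 1D bin-coverage vectors + PCA (baseline);
* :class:`SCHiCluster` — VC-sqrt, box filter, random-walk imputation,
  top-fraction binarization, per-chromosome then global PCA;
* :class:`InnerProductMDS` — z-scored strata inner products (optionally
  stratum-adjusted weights, the fastHiCRep variant) + classical MDS;
* :class:`SpectralIDF` — locus-pair features, quantile/top-N selection, IDF
  weighting, normalized spectral decomposition of the cosine similarity;
* :class:`CisTopicLDA` — latent Dirichlet allocation over locus pairs via
  collapsed Gibbs sampling; embedding is the per-cell topic distribution;
* :class:`InsulationPCA` — insulation-score delta vectors + PCA.

All backends consume a list of :class:`~schicembed.contacts.ContactTable`
and restrict contacts to a genomic distance window ``[min_bp, max_bp)``.
Module-level ``embed_*`` functions are thin wrappers returning
:class:`Embedding` records with full provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from ._lda import run_gibbs
from .contacts import ContactTable
from .transforms import (DEFAULT_MAX_DISTANCE_BP, box_filter,
                         build_feature_matrix, extract_strata, idf_transform,
                         random_walk, select_features, vc_sqrt_norm)

__all__ = [
    "Embedding",
    "SimilarityMatrix",
    "BinCoveragePCA",
    "SCHiCluster",
    "InnerProductMDS",
    "SpectralIDF",
    "CisTopicLDA",
    "InsulationPCA",
    "classical_mds",
    "similarity_innerproduct",
    "embed_1d_pca",
    "embed_schicluster",
    "embed_mds",
    "embed_spectral_idf",
    "embed_lda",
    "embed_insulation",
    "BACKENDS",
]


@dataclass
class Embedding:
    """N cells x d coordinates plus provenance."""

    cell_ids: list[str]
    coords: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        d = self.coords.shape[1]
        df = pd.DataFrame(self.coords, columns=[f"dim_{i+1}" for i in range(d)])
        df.insert(0, "cell_id", self.cell_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Embedding":
        df = pd.read_csv(path, sep="\t")
        return cls(df["cell_id"].tolist(),
                   df.drop(columns="cell_id").to_numpy(float))


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    kind: str
    cell_ids: list[str] = field(default_factory=list)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|x| entry positive per column."""
    out = coords.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def _pca(x: np.ndarray, d: int, random_state: int = 0) -> np.ndarray:
    if d >= x.shape[0]:
        raise ValueError(f"n_components={d} must be < number of cells {x.shape[0]}")
    solver = "full" if min(x.shape) <= 200 else "randomized"
    pca = PCA(n_components=d, svd_solver=solver, random_state=random_state)
    return _fix_signs(pca.fit_transform(x))


def _strata_range(resolution: int, min_bp: float, max_bp: float,
                  n_bins: int) -> tuple[int, int]:
    """Stratum indices [s_min, s_max) covered by a bp distance window."""
    s_min = int(np.ceil(min_bp / resolution))
    s_max = int(np.ceil(max_bp / resolution)) if np.isfinite(max_bp) else n_bins
    return s_min, min(s_max, n_bins)


class _ContactEmbedder(BaseEstimator):
    """Shared plumbing: fit_transform convention and distance window."""

    _stochastic = False  # True when refitting with a new seed changes the fit

    def fit_transform(self, cells: Sequence[ContactTable], y=None) -> np.ndarray:
        self.fit(cells)
        return self.embedding_

    def _check_cells(self, cells: Sequence[ContactTable]) -> list[ContactTable]:
        cells = list(cells)
        if len(cells) < 2:
            raise ValueError("need at least 2 cells")
        return cells


class BinCoveragePCA(_ContactEmbedder):
    """1D baseline: per-bin contact coverage, normalized, then PCA.

    Each contact increments both endpoint bins (an intra-bin contact
    increments its bin twice), so the raw coverage vector sums to twice the
    cell's total cis count.  Vectors are normalized to sum 1 before PCA.
    """

    def __init__(self, n_components: int = 2, min_bp: float = 0,
                 max_bp: float = np.inf, random_state: int = 0):
        self.n_components = n_components
        self.min_bp = min_bp
        self.max_bp = max_bp
        self.random_state = random_state

    @staticmethod
    def coverage_vector(cell: ContactTable, min_bp: float = 0,
                        max_bp: float = np.inf) -> np.ndarray:
        offsets = {}
        total = 0
        for chrom in cell.chroms:
            offsets[chrom] = total
            total += cell.n_bins(chrom)
        cov = np.zeros(total)
        d = cell.distances_bp()
        sub = cell.data[(d >= min_bp) & (d < max_bp)]
        off = sub["chrom"].map(offsets).to_numpy()
        c = sub["count"].to_numpy().astype(float)
        np.add.at(cov, off + sub["bin1"].to_numpy(), c)
        np.add.at(cov, off + sub["bin2"].to_numpy(), c)
        return cov

    def fit(self, cells: Sequence[ContactTable], y=None):
        cells = self._check_cells(cells)
        x = np.stack([self.coverage_vector(c, self.min_bp, self.max_bp)
                      for c in cells])
        sums = x.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        x = x / sums
        self.cell_ids_ = [c.cell_id for c in cells]
        self.embedding_ = _pca(x, self.n_components, self.random_state)
        return self


class SCHiCluster(_ContactEmbedder):
    """Imputation-based embedding: VC-sqrt, box filter, random walk, PCA.

    Per chromosome the chain normalizes each cell matrix (VC_SQRT), smooths
    with a box filter, imputes with a random walk with restart, binarizes the
    strongest ``top_frac`` of entries, and runs PCA on the flattened binary
    matrices; the per-chromosome PCs are concatenated and reduced once more.
    ``top_frac=None`` skips binarization (the chain then degenerates to a 2D
    PCA of the processed matrices).
    """

    def __init__(self, n_components: int = 2, pcs_per_chrom: int = 20,
                 top_frac: float | None = 0.2, box_width: int = 1,
                 use_random_walk: bool = True, restart_p: float = 0.5,
                 rw_tol: float = 1e-6, rw_max_iter: int = 30,
                 min_bp: float = 0, max_bp: float = np.inf,
                 random_state: int = 0):
        self.n_components = n_components
        self.pcs_per_chrom = pcs_per_chrom
        self.top_frac = top_frac
        self.box_width = box_width
        self.use_random_walk = use_random_walk
        self.restart_p = restart_p
        self.rw_tol = rw_tol
        self.rw_max_iter = rw_max_iter
        self.min_bp = min_bp
        self.max_bp = max_bp
        self.random_state = random_state

    def _process(self, cell: ContactTable, chrom: str) -> np.ndarray:
        m = cell.to_dense(chrom, dtype=np.float32)
        if self.min_bp > 0 or np.isfinite(self.max_bp):
            n = m.shape[0]
            d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
            bp = d * cell.resolution
            m = np.where((bp >= self.min_bp) & (bp < self.max_bp), m,
                         np.float32(0.0))
        m = vc_sqrt_norm(m)
        if self.box_width > 0:
            m = box_filter(m, self.box_width)
        if self.use_random_walk:
            m = random_walk(m, self.restart_p, self.rw_tol, self.rw_max_iter)
        if self.top_frac is not None:
            thr = np.quantile(m, 1.0 - self.top_frac)
            m = ((m >= thr) & (m > 0)).astype(np.float32)
        return m

    def fit(self, cells: Sequence[ContactTable], y=None):
        cells = self._check_cells(cells)
        blocks = []
        for chrom in cells[0].chroms:
            if cells[0].n_bins(chrom) < 2:
                warnings.warn(f"chromosome {chrom} has < 2 bins; skipped")
                continue
            flat = np.stack([self._process(c, chrom).ravel() for c in cells])
            n_pc = min(self.pcs_per_chrom, len(cells) - 1, flat.shape[1])
            blocks.append(_pca(flat, n_pc, self.random_state))
        if not blocks:
            raise ValueError("no usable chromosomes")
        concat = np.hstack(blocks)
        d = min(self.n_components, concat.shape[1])
        self.cell_ids_ = [c.cell_id for c in cells]
        self.embedding_ = _pca(concat, d, self.random_state)
        return self


def similarity_innerproduct(cells: Sequence[ContactTable],
                            n_strata: int | None = None,
                            weights: str = "uniform",
                            chrom_agg: str = "median",
                            min_bp: float = 0,
                            max_bp: float = DEFAULT_MAX_DISTANCE_BP,
                            use_random_walk: bool = False,
                            restart_p: float = 0.5) -> SimilarityMatrix:
    """Pairwise cell similarity from z-scored strata inner products.

    Per chromosome and stratum ``s``, similarity between cells i and j is the
    inner product of their z-scored stratum vectors divided by the stratum
    length — the Pearson correlation of the raw strata.  Strata are combined
    by a uniform mean (InnerProduct) or weighted by ``N_s * sigma_i sigma_j``
    computed on the raw strata (the stratum-adjusted correlation coefficient,
    fastHiCRep).  Chromosomes are aggregated by ``chrom_agg``.
    """
    cells = list(cells)
    n = len(cells)
    res = cells[0].resolution
    if weights not in ("uniform", "scc"):
        raise ValueError("weights must be 'uniform' or 'scc'")
    per_chrom = []
    for chrom in cells[0].chroms:
        m = cells[0].n_bins(chrom)
        s_min, s_max = _strata_range(res, min_bp, max_bp, m)
        if n_strata is not None:
            s_max = min(s_max, s_min + n_strata)
        if s_max > m:
            warnings.warn(f"{chrom}: clipping strata to {m} bins")
            s_max = m
        if s_max <= s_min:
            continue
        if use_random_walk:
            mats = [random_walk(c.to_dense(chrom), restart_p) for c in cells]
            strata = [[np.diagonal(mat, s).copy() for s in range(s_min, s_max)]
                      for mat in mats]
        else:
            strata = [[st for st in extract_strata(c, s_max, [chrom])[chrom][s_min:]]
                      for c in cells]
        num = np.zeros((n, n))
        den = np.zeros((n, n))
        for si in range(s_max - s_min):
            vecs = np.stack([strata[i][si] for i in range(n)])
            length = vecs.shape[1]
            if length < 2:
                continue
            sd = vecs.std(axis=1)
            mean = vecs.mean(axis=1)
            z = np.where(sd[:, None] > 0,
                         (vecs - mean[:, None]) / np.where(sd[:, None] > 0,
                                                           sd[:, None], 1.0),
                         0.0)
            r = (z @ z.T) / length
            if weights == "uniform":
                num += r
                den += 1.0
            else:
                w = length * np.outer(sd, sd)
                num += w * r
                den += w
        sim = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        per_chrom.append(sim)
    if not per_chrom:
        raise ValueError("distance window leaves no strata on any chromosome")
    stack = np.stack(per_chrom)
    agg = np.median(stack, axis=0) if chrom_agg == "median" else stack.mean(axis=0)
    agg = (agg + agg.T) / 2
    kind = "inner-product" if weights == "uniform" else "scc-weighted"
    return SimilarityMatrix(agg, kind, [c.cell_id for c in cells])


def classical_mds(similarity: np.ndarray, n_components: int) -> np.ndarray:
    """Torgerson MDS of ``d_ij = sqrt(2 (1 - s_ij))``.

    Negative eigenvalues are truncated at zero; missing positive dimensions
    are padded with zero columns (with a warning).
    """
    s = np.clip(np.asarray(similarity, dtype=float), -1.0, 1.0)
    d2 = 2.0 * (1.0 - s)
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals[:n_components] > 1e-12).sum())
    if n_pos < n_components:
        warnings.warn(f"only {n_pos} positive eigenvalues; padding "
                      f"{n_components - n_pos} zero dimensions")
    coords = np.zeros((n, n_components))
    if n_pos:
        coords[:, :n_pos] = evecs[:, :n_pos] * np.sqrt(evals[:n_pos])
    return _fix_signs(coords)


class InnerProductMDS(_ContactEmbedder):
    """Strata inner-product similarity (uniform or SCC weights) + classical MDS."""

    def __init__(self, n_components: int = 2, n_strata: int | None = None,
                 weights: str = "uniform", chrom_agg: str = "median",
                 min_bp: float = 0, max_bp: float = DEFAULT_MAX_DISTANCE_BP,
                 use_random_walk: bool = False, restart_p: float = 0.5):
        self.n_components = n_components
        self.n_strata = n_strata
        self.weights = weights
        self.chrom_agg = chrom_agg
        self.min_bp = min_bp
        self.max_bp = max_bp
        self.use_random_walk = use_random_walk
        self.restart_p = restart_p

    def fit(self, cells: Sequence[ContactTable], y=None):
        cells = self._check_cells(cells)
        sim = similarity_innerproduct(
            cells, self.n_strata, self.weights, self.chrom_agg,
            self.min_bp, self.max_bp, self.use_random_walk, self.restart_p)
        self.similarity_ = sim
        self.cell_ids_ = sim.cell_ids
        self.embedding_ = classical_mds(sim.values, self.n_components)
        return self


class SpectralIDF(_ContactEmbedder):
    """Feature selection + IDF weighting + normalized spectral embedding.

    Builds the cell x locus-pair matrix, drops quantile outliers, keeps the
    ``top_n`` strongest features, applies the inverse-document-frequency
    weighting, and decomposes the symmetrically normalized cosine similarity;
    the leading (trivial) eigenvector is discarded.
    """

    def __init__(self, n_components: int = 2, min_bp: float = 0,
                 max_bp: float = DEFAULT_MAX_DISTANCE_BP,
                 q_low: float = 0.005, q_high: float = 0.005,
                 top_n: int = 500_000, use_idf: bool = True):
        self.n_components = n_components
        self.min_bp = min_bp
        self.max_bp = max_bp
        self.q_low = q_low
        self.q_high = q_high
        self.top_n = top_n
        self.use_idf = use_idf

    def fit(self, cells: Sequence[ContactTable], y=None):
        cells = self._check_cells(cells)
        fm = build_feature_matrix(cells, self.min_bp, self.max_bp)
        fm = select_features(fm, self.q_low, self.q_high, self.top_n)
        if self.use_idf:
            fm = idf_transform(fm)
        x = fm.matrix.toarray()
        norms = np.linalg.norm(x, axis=1)
        empty = np.flatnonzero(norms == 0)
        if empty.size:
            names = [cells[i].cell_id for i in empty]
            raise ValueError(f"cells with empty feature rows after selection: {names}")
        xn = x / norms[:, None]
        s = xn @ xn.T
        d = s.sum(axis=1)
        dinv = 1.0 / np.sqrt(d)
        s_norm = s * dinv[:, None] * dinv[None, :]
        evals, evecs = np.linalg.eigh((s_norm + s_norm.T) / 2)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        self.cell_ids_ = [c.cell_id for c in cells]
        self.similarity_ = SimilarityMatrix(s, "cosine", self.cell_ids_)
        self.eigenvalues_ = evals[1:self.n_components + 1]
        # eigenvalue weighting down-weights noise dimensions for clustering
        self.embedding_ = _fix_signs(evecs[:, 1:self.n_components + 1]
                                     * self.eigenvalues_)
        return self


class CisTopicLDA(_ContactEmbedder):
    """Topic model over locus pairs; embedding = per-cell topic distribution.

    The collapsed Gibbs sampler makes the fit seed-dependent.

    A "word" is a binned locus pair, a "document" is a cell; topics are
    learned by collapsed Gibbs sampling with symmetric priors
    ``alpha = 50 / T`` (default) and ``beta = 0.1``.
    """

    _stochastic = True

    def __init__(self, n_topics: int = 10, alpha: float | None = None,
                 beta: float = 0.1, n_iter: int = 300,
                 min_bp: float = 0, max_bp: float = DEFAULT_MAX_DISTANCE_BP,
                 random_state: int = 0):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iter = n_iter
        self.min_bp = min_bp
        self.max_bp = max_bp
        self.random_state = random_state

    def fit(self, cells: Sequence[ContactTable], y=None):
        cells = self._check_cells(cells)
        fm = build_feature_matrix(cells, self.min_bp, self.max_bp)
        coo = fm.matrix.tocoo()
        if coo.nnz == 0:
            raise ValueError("empty vocabulary")
        reps = coo.data.astype(np.int64)
        doc = np.repeat(coo.row, reps)
        word = np.repeat(coo.col, reps)
        alpha = self.alpha if self.alpha is not None else 50.0 / self.n_topics
        n_dt = run_gibbs(doc, word, len(cells), fm.matrix.shape[1],
                         self.n_topics, alpha, self.beta, self.n_iter,
                         self.random_state)
        theta = n_dt + alpha
        theta = theta / theta.sum(axis=1, keepdims=True)
        self.cell_ids_ = [c.cell_id for c in cells]
        self.embedding_ = theta
        return self


class InsulationPCA(_ContactEmbedder):
    """Insulation-score delta vectors as cell representations, then PCA.

    Insulation of bin i sums contacts in the square window bridging i
    (rows i-w..i-1 by columns i+1..i+w), is log2-normalized by the
    chromosome mean, and converted to a boundary-sensitive delta: the mean
    over the ``delta_w`` bins downstream minus the mean upstream.
    """

    def __init__(self, n_components: int = 2, window: int = 10,
                 delta_w: int = 3, min_bp: float = 0, max_bp: float = np.inf,
                 random_state: int = 0):
        self.n_components = n_components
        self.window = window
        self.delta_w = delta_w
        self.min_bp = min_bp
        self.max_bp = max_bp
        self.random_state = random_state

    def _delta_vector(self, cell: ContactTable, chrom: str) -> np.ndarray:
        w = self.window
        mat = cell.to_dense(chrom)
        if self.min_bp > 0 or np.isfinite(self.max_bp):
            nb = mat.shape[0]
            dd = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
            bp = dd * cell.resolution
            mat = np.where((bp >= self.min_bp) & (bp < self.max_bp), mat, 0.0)
        m = mat.shape[0]
        pad = np.zeros((m + 1, m + 1))
        pad[1:, 1:] = np.cumsum(np.cumsum(mat, axis=0), axis=1)
        ins = np.full(m, np.nan)
        for i in range(w, m - w):
            r0, r1 = i - w, i          # rows i-w .. i-1
            c0, c1 = i + 1, i + w + 1  # cols i+1 .. i+w
            ins[i] = pad[r1, c1] - pad[r0, c1] - pad[r1, c0] + pad[r0, c0]
        defined = np.isfinite(ins) & (ins > 0)
        norm = np.zeros(m)
        if defined.any():
            norm[defined] = np.log2(ins[defined] / ins[defined].mean())
        dv = np.zeros(m)
        for i in range(m):
            right = norm[i + 1: min(i + 1 + self.delta_w, m)]
            left = norm[max(i - self.delta_w, 0): i]
            if right.size and left.size:
                dv[i] = right.mean() - left.mean()
        return dv

    def fit(self, cells: Sequence[ContactTable], y=None):
        cells = self._check_cells(cells)
        parts = []
        for chrom in cells[0].chroms:
            if cells[0].n_bins(chrom) < 2 * self.window + 1:
                warnings.warn(f"chromosome {chrom} shorter than 2w+1 bins; skipped")
                continue
            parts.append(np.stack([self._delta_vector(c, chrom) for c in cells]))
        if not parts:
            raise ValueError("no chromosome long enough for the insulation window")
        x = np.hstack(parts)
        self.cell_ids_ = [c.cell_id for c in cells]
        self.embedding_ = _pca(x, self.n_components, self.random_state)
        return self


# ---------------------------------------------------------------------------
# functional wrappers with provenance


def _wrap(est: _ContactEmbedder, cells, backend: str, seed=None) -> Embedding:
    coords = est.fit_transform(cells)
    meta = {"backend": backend, "params": est.get_params(),
            "resolution": cells[0].resolution, "seed": seed}
    return Embedding(est.cell_ids_, coords, meta)


def embed_1d_pca(cells, d: int = 2, **kw) -> Embedding:
    return _wrap(BinCoveragePCA(n_components=d, **kw), cells, "1d-pca")


def embed_schicluster(cells, d: int = 2, pcs_per_chrom: int = 20,
                      top_frac: float | None = 0.2, **kw) -> Embedding:
    est = SCHiCluster(n_components=d, pcs_per_chrom=pcs_per_chrom,
                      top_frac=top_frac, **kw)
    return _wrap(est, cells, "schicluster")


def embed_mds(similarity: SimilarityMatrix, d: int = 2) -> Embedding:
    coords = classical_mds(similarity.values, d)
    return Embedding(similarity.cell_ids, coords,
                     {"backend": f"mds[{similarity.kind}]"})


def embed_spectral_idf(cells, d: int = 2, **kw) -> Embedding:
    return _wrap(SpectralIDF(n_components=d, **kw), cells, "spectral-idf")


def embed_lda(cells, d: int = 10, seed: int = 0, **kw) -> Embedding:
    est = CisTopicLDA(n_topics=d, random_state=seed, **kw)
    return _wrap(est, cells, "lda", seed=seed)


def embed_insulation(cells, d: int = 2, **kw) -> Embedding:
    return _wrap(InsulationPCA(n_components=d, **kw), cells, "insulation")


BACKENDS = {
    "1d-pca": BinCoveragePCA,
    "schicluster": SCHiCluster,
    "innerproduct": InnerProductMDS,
    "fasthicrep": lambda **kw: InnerProductMDS(weights="scc", **kw),
    "spectral-idf": SpectralIDF,
    "lda": CisTopicLDA,
    "insulation": InsulationPCA,
}
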