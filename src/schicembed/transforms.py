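"""Decoupled preprocessing operators chained before any embedding backend.

Each operator is a plain function over one of three substrates:

* :class:`~schicembed.contacts.ContactTable` — distance truncation;
* dense per-chromosome matrices (``CellMatrix``) — VC-sqrt normalization,
  box-filter smoothing, random-walk-with-restart imputation;
* strata vectors / cell x locus-pair feature matrices — z-scoring, IDF
  weighting, feature selection.

A :class:`TransformChain` records an ordered list of named steps so that
every embedding can carry its preprocessing provenance verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .contacts import ContactTable

__all__ = [
    "truncate_distance",
    "vc_sqrt_norm",
    "box_filter",
    "random_walk",
    "extract_strata",
    "zscore_strata",
    "FeatureMatrix",
    "build_feature_matrix",
    "idf_transform",
    "select_features",
    "TransformChain",
    "DEFAULT_MAX_DISTANCE_BP",
]

# Global default distance ceiling for strata extraction (20 Mb window).
DEFAULT_MAX_DISTANCE_BP = 20_000_000


def truncate_distance(cell: ContactTable, min_bp: float = 0,
                      max_bp: float = np.inf) -> ContactTable:
    """Keep only contacts with ``min_bp <= distance < max_bp``."""
    if not (0 <= min_bp < max_bp):
        raise ValueError("need 0 <= min_bp < max_bp")
    d = cell.distances_bp()
    mask = (d >= min_bp) & (d < max_bp)
    if not mask.any():
        warnings.warn(f"distance window [{min_bp}, {max_bp}) removes every "
                      f"contact of cell {cell.cell_id}")
    return cell.replace(cell.data[mask].reset_index(drop=True))


def vc_sqrt_norm(m: np.ndarray) -> np.ndarray:
    """Vanilla-coverage square-root normalization.

    ``out_ij = m_ij / sqrt(r_i r_j)`` with r the row sums; zero-coverage rows
    stay zero.  Symmetry and nonnegativity are preserved.
    """
    m = np.asarray(m)
    if (m < 0).any():
        raise ValueError("vc_sqrt_norm expects a nonnegative matrix")
    dtype = m.dtype if np.issubdtype(m.dtype, np.floating) else np.float64
    r = m.sum(axis=1, dtype=dtype)
    inv = np.zeros_like(r)
    nz = r > 0
    inv[nz] = 1.0 / np.sqrt(r[nz])
    return m * inv[:, None] * inv[None, :]


def box_filter(m: np.ndarray, w: int = 1) -> np.ndarray:
    """Mean filter over a (2w+1)^2 window, clipped at the matrix edges."""
    m = np.asarray(m)
    if not np.issubdtype(m.dtype, np.floating):
        m = m.astype(np.float64)
    if w < 0:
        raise ValueError("window radius must be >= 0")
    if w == 0:
        return m.copy()
    n = m.shape[0]
    if w >= n:
        raise ValueError(f"window radius {w} >= matrix size {n}")
    # summed-area table with edge clipping -> exact window means
    pad = np.zeros((n + 1, n + 1), dtype=m.dtype)
    pad[1:, 1:] = np.cumsum(np.cumsum(m, axis=0), axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - w, 0)
    hi = np.minimum(idx + w, n - 1) + 1
    s = (pad[np.ix_(hi, hi)] - pad[np.ix_(lo, hi)]
         - pad[np.ix_(hi, lo)] + pad[np.ix_(lo, lo)])
    area = (hi - lo)[:, None] * (hi - lo)[None, :]
    return s / area


def random_walk(m: np.ndarray, restart_p: float = 0.5, tol: float = 1e-6,
                max_iter: int = 30, return_iterations: bool = False):
    """Random walk with restart on the contact graph.

    With row-stochastic ``P = D^-1 m`` (zero rows become self-loops) iterate
    ``R <- p R P + (1 - p) I`` from ``R = I`` until ``max|dR| < tol``; the
    fixed point is ``(1 - p)(I - p P)^-1``.  Returns the symmetrized
    ``(R + R^T) / 2``.
    """
    m = np.asarray(m)
    if not np.issubdtype(m.dtype, np.floating):
        m = m.astype(np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("random_walk expects a square matrix")
    if not (0 < restart_p < 1):
        raise ValueError("restart_p must be in (0, 1)")
    n = m.shape[0]
    r = m.sum(axis=1)
    p_mat = np.divide(m, r[:, None], out=np.zeros_like(m),
                      where=r[:, None] > 0)
    zero = r == 0
    if zero.any():
        p_mat[zero, zero] = 1.0
    eye = np.eye(n, dtype=m.dtype)
    r_mat = eye.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new = restart_p * (r_mat @ p_mat) + (1 - restart_p) * eye
        delta = np.abs(new - r_mat).max()
        r_mat = new
        if delta < tol:
            break
    out = (r_mat + r_mat.T) / 2
    if return_iterations:
        return out, n_iter
    return out


def extract_strata(cell: ContactTable, n_strata: int,
                   chroms: Sequence[str] | None = None) -> dict[str, list[np.ndarray]]:
    """First ``n_strata`` diagonals of each chromosome's contact matrix.

    Stratum ``s`` of a chromosome with M bins is a vector of length ``M - s``.
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    out: dict[str, list[np.ndarray]] = {}
    for chrom in (chroms or cell.chroms):
        m = cell.n_bins(chrom)
        k = min(n_strata, m)
        strata = [np.zeros(m - s) for s in range(k)]
        sub = cell.data[cell.data["chrom"] == chrom]
        b1 = sub["bin1"].to_numpy()
        s_idx = sub["bin2"].to_numpy() - b1
        c = sub["count"].to_numpy().astype(float)
        within = s_idx < k
        for s in range(k):
            sel = within & (s_idx == s)
            if sel.any():
                np.add.at(strata[s], b1[sel], c[sel])
        out[chrom] = strata
    return out


def zscore_strata(strata: dict[str, list[np.ndarray]]) -> dict[str, list[np.ndarray]]:
    """Center/scale each stratum vector to mean 0, population variance 1.

    Zero-variance strata map to all-zero vectors.
    """
    out: dict[str, list[np.ndarray]] = {}
    for chrom, vecs in strata.items():
        zs = []
        for v in vecs:
            sd = v.std()  # population (1/n) standard deviation
            zs.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
        out[chrom] = zs
    return out


@dataclass
class FeatureMatrix:
    """N cells x F locus-pair features, CSR sparse, with explicit keys."""

    matrix: sp.csr_matrix
    keys: pd.DataFrame  # chrom, bin1, bin2 per feature column
    cell_ids: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def document_frequency(self) -> np.ndarray:
        """Number of cells with a nonzero entry per feature."""
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel()

    def replace(self, matrix=None, keys=None) -> "FeatureMatrix":
        return FeatureMatrix(matrix if matrix is not None else self.matrix,
                             keys if keys is not None else self.keys,
                             self.cell_ids)


def build_feature_matrix(cells: Sequence[ContactTable],
                         min_bp: float = 0,
                         max_bp: float = DEFAULT_MAX_DISTANCE_BP) -> FeatureMatrix:
    """Cell x locus-pair occurrence matrix over the observed vocabulary.

    The vocabulary is the union of (chrom, bin1, bin2) pairs observed in any
    cell inside the distance window, ordered by key.
    """
    frames = []
    for i, cell in enumerate(cells):
        d = cell.distances_bp()
        sub = cell.data[(d >= min_bp) & (d < max_bp)].copy()
        sub["cell"] = i
        frames.append(sub)
    cat = pd.concat(frames, ignore_index=True)
    if cat.empty:
        raise ValueError("no contacts inside the distance window")
    key = pd.MultiIndex.from_frame(cat[["chrom", "bin1", "bin2"]])
    codes, uniques = pd.factorize(key, sort=True)
    mat = sp.coo_matrix((cat["count"].to_numpy().astype(float),
                         (cat["cell"].to_numpy(), codes)),
                        shape=(len(cells), len(uniques))).tocsr()
    keys = pd.DataFrame(list(uniques), columns=["chrom", "bin1", "bin2"])
    return FeatureMatrix(mat, keys, [c.cell_id for c in cells])


def idf_weights(n_cells: int, doc_freq: np.ndarray) -> np.ndarray:
    """Smoothed inverse document frequency ``log(1 + N / (1 + n_j))``."""
    return np.log1p(n_cells / (1.0 + doc_freq))


def idf_transform(x: FeatureMatrix) -> FeatureMatrix:
    """Scale each feature column by its inverse document frequency.

    Rare features are up-weighted; the zero pattern is unchanged.
    """
    w = idf_weights(x.n_cells, x.document_frequency())
    mat = x.matrix @ sp.diags(w)
    return x.replace(matrix=mat.tocsr())


def select_features(x: FeatureMatrix, q_low: float = 0.005,
                    q_high: float = 0.005, top_n: int = 500_000) -> FeatureMatrix:
    """Quantile-filter feature totals, then keep the top_n by mean signal.

    Features whose total count falls below the ``q_low`` quantile or above
    the ``1 - q_high`` quantile of feature totals are dropped; of the rest
    the ``top_n`` with strongest mean signal are kept (ties broken by feature
    key order, i.e. first occurrence wins).
    """
    if not (0 <= q_low < 1 - q_high <= 1):
        raise ValueError("need 0 <= q_low < 1 - q_high <= 1")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    totals = np.asarray(x.matrix.sum(axis=0)).ravel()
    keep = np.ones(totals.size, dtype=bool)
    if q_low > 0:
        keep &= totals >= np.quantile(totals, q_low)
    if q_high > 0:
        keep &= totals <= np.quantile(totals, 1 - q_high)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("quantile filter removed every feature")
    if idx.size > top_n:
        mean_signal = totals[idx] / x.n_cells
        order = np.argsort(-mean_signal, kind="stable")  # stable -> key-order ties
        idx = np.sort(idx[order[:top_n]])
    return x.replace(matrix=x.matrix[:, idx].tocsr(),
                     keys=x.keys.iloc[idx].reset_index(drop=True))


@dataclass
class TransformChain:
    """Ordered, named preprocessing steps; recorded in embedding provenance."""

    steps: list[tuple[str, dict]] = field(default_factory=list)

    def add(self, name: str, **params) -> "TransformChain":
        self.steps.append((name, params))
        return self

    def describe(self) -> str:
        return " -> ".join(
            f"{name}({', '.join(f'{k}={v}' for k, v in p.items())})"
            for name, p in self.steps) or "raw"
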