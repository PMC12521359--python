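"""Interpretation tools: per-strata similarity maps, fraction scatter, compartment PC1.

These diagnostics explain *which genomic distances* drive an embedding: the
per-strata similarity heatmap localizes cell-cell heterogeneity along the
distance axis, the fraction scatter separates interphase from mitotic-like
cells, and the pseudo-bulk compartment PC1 recovers the A/B checkerboard
from a distance-normalized correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import ContactTable, contact_fractions
from .transforms import extract_strata, zscore_strata

__all__ = [
    "StrataSimilarityMap",
    "per_strata_heatmap",
    "fraction_scatter",
    "compartment_pc1",
    "idf_stratum_profile",
]


@dataclass
class StrataSimilarityMap:
    """Cells x strata medians of pairwise similarity, column-normalized to [0, 1]."""

    values: np.ndarray
    cell_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids,
                            columns=[f"stratum_{s}" for s in
                                     range(self.values.shape[1])])


def per_strata_heatmap(cells: Sequence[ContactTable],
                       n_strata: int) -> StrataSimilarityMap:
    """Median per-cell similarity at each stratum, column-normalized.

    For every stratum the z-scored inner products between all cell pairs are
    computed per chromosome and the median taken across chromosomes; each
    cell's value is its median similarity to all *other* cells.  Columns are
    min-max normalized (constant columns map to zero).
    """
    cells = list(cells)
    if len(cells) < 3:
        raise ValueError("need at least 3 cells")
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    n = len(cells)
    chroms = cells[0].chroms
    per_chrom_sims = np.full((len(chroms), n_strata, n, n), np.nan)
    for ci, chrom in enumerate(chroms):
        m = cells[0].n_bins(chrom)
        k = min(n_strata, m)
        z_strata = [zscore_strata(extract_strata(c, k, [chrom]))[chrom]
                    for c in cells]
        for s in range(k):
            length = m - s
            if length < 2:
                continue
            z = np.stack([z_strata[i][s] for i in range(n)])
            per_chrom_sims[ci, s] = (z @ z.T) / length
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sims = np.nanmedian(per_chrom_sims, axis=0)  # strata x n x n
    out = np.zeros((n, n_strata))
    mask = ~np.eye(n, dtype=bool)
    for s in range(n_strata):
        mat = sims[s]
        if np.isnan(mat).all():
            continue
        for i in range(n):
            out[i, s] = np.median(mat[i][mask[i]])
    # column min-max normalization; constant columns -> 0
    lo = out.min(axis=0)
    span = out.max(axis=0) - lo
    norm = np.where(span > 0, (out - lo) / np.where(span > 0, span, 1.0), 0.0)
    return StrataSimilarityMap(norm, [c.cell_id for c in cells])


def fraction_scatter(cells: Sequence[ContactTable]) -> pd.DataFrame:
    """Per-cell local (25 kb–2 Mb) and mitotic (2–12 Mb) contact fractions."""
    rows = [(c.cell_id, *contact_fractions(c)) for c in cells]
    return pd.DataFrame(rows, columns=["cell_id", "f_local", "f_mitotic"])


def idf_stratum_profile(cells: Sequence[ContactTable],
                        n_strata: int = 40) -> np.ndarray:
    """Mean inverse-document-frequency weight per stratum.

    Averages the IDF weight over the *complete* locus-pair universe of each
    stratum (pairs unobserved in every cell carry the maximal, df = 0,
    weight).  Because distal contacts are sparser and hence rarer per cell,
    this profile rises with genomic distance — the distance bias of the IDF
    transformation.  The profile is reported for the first ``n_strata``
    strata; at larger distances per-cell occupancy is so low that the
    expected increment falls below document-frequency sampling noise.
    """
    from .transforms import build_feature_matrix, idf_weights

    cells = list(cells)
    res = cells[0].resolution
    fm = build_feature_matrix(cells, 0, n_strata * res)
    w = idf_weights(fm.n_cells, fm.document_frequency())
    s = (fm.keys["bin2"] - fm.keys["bin1"]).to_numpy()
    w_unseen = idf_weights(fm.n_cells, np.zeros(1))[0]
    profile = np.empty(n_strata)
    for stratum in range(n_strata):
        n_pairs = sum(max(cells[0].n_bins(c) - stratum, 0)
                      for c in cells[0].chroms)
        sel = s == stratum
        profile[stratum] = ((w[sel].sum() + (n_pairs - sel.sum()) * w_unseen)
                            / n_pairs)
    return profile


def compartment_pc1(bulk: ContactTable, chrom: str,
                    reference: np.ndarray | None = None) -> np.ndarray:
    """A/B compartment signal from a pseudo-bulk contact map.

    The chromosome matrix is normalized to observed/expected by distance
    (expected = per-stratum mean), converted to a bin-bin Pearson correlation
    matrix, and reduced to its first principal component.  With a
    ``reference`` compartment track the sign is oriented to correlate
    positively with it.
    """
    mat = bulk.to_dense(chrom)
    if mat.sum() == 0:
        raise ValueError(f"chromosome {chrom} is empty in the pseudo-bulk")
    m = mat.shape[0]
    if mat.sum() < 10 * m:
        warnings.warn(f"pseudo-bulk depth is low on {chrom} "
                      f"(< 10 counts per bin on average)")
    d = np.abs(np.arange(m)[:, None] - np.arange(m)[None, :])
    expected = np.array([np.diagonal(mat, s).mean() for s in range(m)])
    exp_mat = expected[d]
    oe = np.divide(mat, exp_mat, out=np.ones_like(mat), where=exp_mat > 0)
    keep = mat.sum(axis=1) > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(oe[np.ix_(keep, keep)])
    corr = np.nan_to_num(corr)
    evals, evecs = np.linalg.eigh(corr)
    pc1_sub = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
    pc1 = np.zeros(m)
    pc1[keep] = pc1_sub
    total_var = np.trace(corr)
    if total_var <= 0 or evals[-1] / total_var < 0.05:
        warnings.warn(f"{chrom}: PC1 explains <5% variance; compartment "
                      f"signal degenerate")
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if np.corrcoef(pc1, ref)[0, 1] < 0:
            pc1 = -pc1
    return pc1
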