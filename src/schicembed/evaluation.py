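"""Clustering and the metric stack: K-means, ARI, NMI, ASW, AvgBIO.

Embeddings are scored against ground-truth labels by clustering with
K-means (k fixed to the true class count, for comparable partitions across
backends) and computing the adjusted Rand index, normalized mutual
information (arithmetic-mean normalization), and the average silhouette
width under cosine distance.  AvgBIO is the mean of the three with ASW
rescaled to [0, 1].  ``repeat_eval`` repeats the whole pipeline with derived
seeds and reports mean +/- SEM; ``median_rank_summary`` turns a
method x dataset score table into the percentile-rank leaderboard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (adjusted_rand_score,
                             normalized_mutual_info_score, silhouette_score)

__all__ = [
    "LabelSet",
    "EvalReport",
    "kmeans_cluster",
    "ari",
    "nmi",
    "asw",
    "avgbio",
    "evaluate_embedding",
    "repeat_eval",
    "median_rank_summary",
]


@dataclass
class LabelSet:
    """Dense integer labels for a list of cells."""

    cell_ids: list[str]
    labels: np.ndarray

    @classmethod
    def from_names(cls, cell_ids: Sequence[str], names: Sequence) -> "LabelSet":
        codes, _ = pd.factorize(np.asarray(names))
        return cls(list(cell_ids), codes)

    @property
    def n_classes(self) -> int:
        return int(len(np.unique(self.labels)))


def kmeans_cluster(coords: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """K-means with 10 restarts; deterministic under a fixed seed."""
    coords = np.asarray(coords)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > coords.shape[0]:
        raise ValueError(f"k={k} exceeds the number of cells {coords.shape[0]}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(coords)


def _check_pair(u, v):
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError("label vectors must have equal length")
    return u, v


def ari(u, v) -> float:
    """Adjusted Rand index: chance-corrected pair-counting agreement."""
    u, v = _check_pair(u, v)
    return float(adjusted_rand_score(u, v))


def nmi(u, v) -> float:
    """Mutual information normalized by the arithmetic mean of entropies."""
    u, v = _check_pair(u, v)
    val = normalized_mutual_info_score(u, v, average_method="arithmetic")
    return float(np.clip(val, 0.0, 1.0))


def asw(coords: np.ndarray, labels) -> float:
    """Average silhouette width with cosine distance and true labels."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 classes")
    return float(silhouette_score(np.asarray(coords), labels, metric="cosine"))


def avgbio(ari_val: float, nmi_val: float, asw_val: float) -> float:
    """Mean of ARI, NMI, and ASW rescaled from [-1, 1] to [0, 1]."""
    return float(np.mean([ari_val, nmi_val, (asw_val + 1.0) / 2.0]))


def evaluate_embedding(coords: np.ndarray, truth: np.ndarray,
                       seed: int = 0) -> dict[str, float]:
    """Cluster an embedding with K-means (k = true class count) and score it."""
    truth = np.asarray(truth)
    k = len(np.unique(truth))
    pred = kmeans_cluster(coords, k, seed)
    a = ari(truth, pred)
    n = nmi(truth, pred)
    s = asw(coords, truth)
    return {"ari": a, "nmi": n, "asw": s, "avgbio": avgbio(a, n, s),
            "avgbio_raw_asw": float(np.mean([a, n, s]))}


@dataclass
class EvalReport:
    """Per-repeat metrics plus mean +/- SEM summaries."""

    repeats: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        mean = self.repeats.mean()
        n = len(self.repeats)
        sem = (self.repeats.std(ddof=1) / np.sqrt(n)) if n > 1 \
            else pd.Series(np.nan, index=self.repeats.columns)
        return pd.DataFrame({"mean": mean, "sem": sem})

    def to_tsv(self, path: str | Path) -> None:
        self.repeats.assign(**{f"meta_{k}": str(v) for k, v in self.meta.items()}
                            ).to_csv(path, sep="\t", index=False)


def repeat_eval(embed_fn: Callable[[int], np.ndarray], truth,
                n_repeats: int = 5, base_seed: int = 0,
                meta: dict | None = None) -> EvalReport:
    """Rerun embedding + clustering with derived seeds ``base_seed + i``.

    ``embed_fn(seed)`` must return the N x d coordinates; deterministic
    backends may ignore the seed (only the clustering then varies).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    truth = np.asarray(truth)
    rows = []
    for i in range(n_repeats):
        seed = base_seed + i
        coords = embed_fn(seed)
        rows.append(evaluate_embedding(coords, truth, seed=seed))
    return EvalReport(pd.DataFrame(rows), meta or {})


def median_rank_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Percentile ranks per dataset (1 = best), median across datasets.

    ``scores`` is methods x datasets; missing entries are excluded from that
    dataset's ranking.  Ties share the mean of their percentile positions.
    """
    pct = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for col in scores.columns:
        s = scores[col].dropna()
        pct.loc[s.index, col] = s.rank(method="average") / len(s)
    out = pd.DataFrame({"median_rank": pct.median(axis=1, skipna=True)})
    out = out.join(pct.add_prefix("rank_"))
    return out.sort_values("median_rank", ascending=False)
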