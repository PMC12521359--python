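"""Benchmark orchestration: datasets x backends -> metric tables + ranking.

``run_benchmark`` evaluates every backend on every dataset with the repeat
harness, selects the best variant per dataset group (e.g. the best of
several resolutions by mean ARI), and summarizes backends by their median
percentile rank of mean AvgBIO across datasets.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone

from .contacts import ContactTable
from .evaluation import median_rank_summary, repeat_eval

__all__ = ["run_benchmark", "make_embed_fn"]


def make_embed_fn(estimator, cells: Sequence[ContactTable]) -> Callable[[int], np.ndarray]:
    """Wrap an embedder estimator into a seeded embedding function.

    Stochastic backends (those exposing ``random_state``) are re-fit per
    seed; deterministic ones are fit once and cached.
    """
    stochastic = getattr(estimator, "_stochastic",
                         "random_state" in estimator.get_params())
    cache: dict = {}

    def embed(seed: int) -> np.ndarray:
        if stochastic:
            est = clone(estimator).set_params(random_state=seed)
            return est.fit_transform(cells)
        if "coords" not in cache:
            cache["coords"] = clone(estimator).fit_transform(cells)
        return cache["coords"]

    return embed


def run_benchmark(datasets: Mapping[str, dict],
                  backends: Mapping[str, object],
                  n_repeats: int = 5,
                  base_seed: int = 0) -> dict[str, pd.DataFrame]:
    """Run every backend on every dataset.

    Parameters
    ----------
    datasets
        name -> ``{"cells": [...], "labels": array-like, "group": str}``;
        entries sharing a ``group`` (e.g. one dataset binned at several
        resolutions) compete and only the best (max mean ARI) represents
        the group in the ranking.
    backends
        name -> unfitted embedder estimator.

    Returns a dict with ``metrics`` (long form, one row per repeat),
    ``summary`` (mean/SEM), ``best`` (per group), and ``ranking`` tables.
    Failing runs are recorded with their reason; partial results are kept.
    """
    rows = []
    failures = []
    for ds_name, ds in datasets.items():
        truth = pd.factorize(np.asarray(ds["labels"]))[0]
        group = ds.get("group", ds_name)
        for be_name, est in backends.items():
            try:
                report = repeat_eval(make_embed_fn(est, ds["cells"]), truth,
                                     n_repeats=n_repeats, base_seed=base_seed)
            except Exception as exc:  # noqa: BLE001 - record and continue
                warnings.warn(f"{be_name} failed on {ds_name}: {exc}")
                failures.append({"dataset": ds_name, "backend": be_name,
                                 "error": str(exc)})
                continue
            for i, rep in report.repeats.iterrows():
                rows.append({"dataset": ds_name, "group": group,
                             "backend": be_name, "repeat": i, **rep.to_dict()})
    metrics = pd.DataFrame(rows)
    if metrics.empty:
        return {"metrics": metrics, "summary": metrics, "best": metrics,
                "ranking": metrics, "failures": pd.DataFrame(failures)}
    summary = (metrics.groupby(["group", "dataset", "backend"])
               [["ari", "nmi", "asw", "avgbio"]]
               .agg(["mean", "sem"]).reset_index())
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    best = (summary.sort_values("ari_mean", ascending=False)
            .groupby(["group", "backend"], as_index=False).first())
    score_table = best.pivot(index="backend", columns="group",
                             values="avgbio_mean")
    ranking = median_rank_summary(score_table)
    return {"metrics": metrics, "summary": summary, "best": best,
            "ranking": ranking, "failures": pd.DataFrame(failures)}
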