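"""Synthetic single-cell Hi-C generator with controllable multiscale structure.

Each population is a probability model over cis contacts of a small genome:

* a power-law distance decay ``(1 + d)^-alpha`` shared by all contacts;
* an A/B compartment checkerboard that multiplies long-range
  (> 2 Mb) same-compartment contacts by ``1 + kappa`` and cross-compartment
  contacts by ``1 - kappa``;
* a set of short-range (< 2 Mb) loop anchors boosted by ``lambda``;
* an optional mitotic shift ``m`` that reallocates probability mass into the
  2–12 Mb band, emulating condensed M-phase chromosomes.

Cells are multinomial draws of a per-cell sequencing depth (lognormal with
median 20k cis contacts, floored above the 5k QC threshold) from the
population's expected map.  Ground-truth labels, compartment tracks, and loop
sets are returned alongside the cells so that embedding and diagnostics
results can be checked against the generating model.

The default geometry is 2 chromosomes x 400 bins at 100 kb resolution, so
"2 Mb" is 20 bins and the 2–12 Mb mitotic band exists inside each chromosome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import ChromSizes, ContactTable, make_table

__all__ = [
    "PopulationSpec",
    "DatasetSpec",
    "checkerboard",
    "random_compartments",
    "expected_matrix",
    "sample_cell",
    "generate_dataset",
    "preset",
    "PRESETS",
    "write_dataset",
]

COMPARTMENT_MIN_BP = 2_000_000   # compartments act on contacts above this distance
MITOTIC_BAND_BP = (2_000_000, 12_000_000)
DEFAULT_RESOLUTION = 100_000
DEFAULT_N_BINS = 400
DEFAULT_BLOCK_BINS = 10          # 1 Mb compartment blocks at 100 kb


@dataclass
class PopulationSpec:
    """Generative model of one cell population."""

    name: str
    compartments: dict[str, np.ndarray]          # per chrom, +1/-1 per bin
    kappa: float = 0.0                           # compartment strength, in [0, 1)
    loops: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    loop_boost: float = 1.0                      # lambda >= 1
    alpha: float = 1.0                           # decay exponent
    mitotic_shift: float = 0.0                   # m in [0, 1)

    def __post_init__(self) -> None:
        if not (0 <= self.kappa < 1):
            raise ValueError("kappa must be in [0, 1) (kappa >= 1 gives negative probabilities)")
        if self.loop_boost < 1:
            raise ValueError("loop_boost must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 <= self.mitotic_shift < 1):
            raise ValueError("mitotic_shift must be in [0, 1)")


@dataclass
class DatasetSpec:
    """A full synthetic dataset: geometry, populations, depths, seed."""

    populations: list[PopulationSpec]
    cells_per_population: list[int]
    n_chroms: int = 2
    n_bins: int = DEFAULT_N_BINS
    resolution: int = DEFAULT_RESOLUTION
    depth_log_median: float = float(np.log(20_000))
    depth_log_sigma: float = 0.35
    depth_floor: int = 5_001
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.populations) != len(self.cells_per_population):
            raise ValueError("one cell count per population required")
        if not self.populations:
            raise ValueError("need at least one population")

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes({c: self.n_bins * self.resolution for c in self.chroms})


def checkerboard(n_bins: int, block: int = DEFAULT_BLOCK_BINS, phase: int = 0) -> np.ndarray:
    """Alternating +1/-1 compartment assignment in blocks of ``block`` bins."""
    blocks = (np.arange(n_bins) // block + phase) % 2
    return np.where(blocks == 0, 1, -1)


def random_compartments(n_bins: int, rng: np.random.Generator,
                        block: int = DEFAULT_BLOCK_BINS) -> np.ndarray:
    """Random +1/-1 A/B assignment in blocks of ``block`` bins.

    Two independent draws give populations whose same/different-compartment
    pair relations differ on about half of all bin pairs — a strictly
    sign-flipped checkerboard would leave the pair relation (and hence the
    expected contact map) unchanged.
    """
    n_blocks = int(np.ceil(n_bins / block))
    signs = rng.choice([1, -1], size=n_blocks)
    return np.repeat(signs, block)[:n_bins]


def expected_matrix(pop: PopulationSpec, chrom: str, n_bins: int,
                    resolution: int) -> np.ndarray:
    """Expected (unnormalized) contact intensity for one chromosome.

    ``E_ij = (1 + d_ij)^-alpha * c_ij * l_ij`` where c applies the
    compartment contrast beyond 2 Mb and l the loop boosts.
    """
    d = np.abs(np.arange(n_bins)[:, None] - np.arange(n_bins)[None, :])
    e = (1.0 + d) ** (-pop.alpha)
    comp = pop.compartments.get(chrom)
    if comp is not None and pop.kappa > 0:
        comp = np.asarray(comp)
        if comp.size < n_bins:
            raise ValueError(f"compartment track for {chrom} covers "
                             f"{comp.size} bins < {n_bins}")
        comp = comp[:n_bins]
        d_comp = int(np.ceil(COMPARTMENT_MIN_BP / resolution))
        same = comp[:, None] == comp[None, :]
        c = np.where(same, 1.0 + pop.kappa, 1.0 - pop.kappa)
        c[d < d_comp] = 1.0
        e = e * c
    for (i, j) in pop.loops.get(chrom, []):
        e[i, j] *= pop.loop_boost
        if i != j:
            e[j, i] *= pop.loop_boost
    return e


def _upper_probs(pop: PopulationSpec, spec: DatasetSpec):
    """Concatenated upper-triangle probabilities over all chromosomes."""
    rows, cols, chrom_ids, vals = [], [], [], []
    iu = np.triu_indices(spec.n_bins)
    for ci, chrom in enumerate(spec.chroms):
        e = expected_matrix(pop, chrom, spec.n_bins, spec.resolution)
        rows.append(iu[0])
        cols.append(iu[1])
        chrom_ids.append(np.full(iu[0].size, ci))
        vals.append(e[iu])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    chrom_ids = np.concatenate(chrom_ids)
    p = np.concatenate(vals)
    p = p / p.sum()
    if pop.mitotic_shift > 0:
        lo = MITOTIC_BAND_BP[0] / spec.resolution
        hi = MITOTIC_BAND_BP[1] / spec.resolution
        d = cols - rows
        band = (d > lo) & (d < hi)
        if not band.any():
            raise ValueError("mitotic band empty: chromosomes too short for a "
                             "2-12 Mb shift at this resolution")
        band_p = np.where(band, p, 0.0)
        p = (1 - pop.mitotic_shift) * p + pop.mitotic_shift * band_p / band_p.sum()
    return chrom_ids, rows, cols, p


def sample_cell(pop: PopulationSpec, spec: DatasetSpec, depth: int,
                seed: int | np.random.Generator,
                cell_id: str = "cell", _cache=None) -> ContactTable:
    """Multinomial draw of ``depth`` contacts from the population model."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    chrom_ids, rows, cols, p = _cache if _cache is not None else _upper_probs(pop, spec)
    counts = rng.multinomial(depth, p)
    nz = counts > 0
    chroms = np.asarray(spec.chroms)[chrom_ids[nz]]
    return make_table(cell_id, spec.resolution, spec.chrom_sizes(),
                      chroms, rows[nz], cols[nz], counts[nz])


def generate_dataset(spec: DatasetSpec
                     ) -> tuple[list[ContactTable], pd.Series, dict]:
    """Sample all cells of a dataset.

    Returns ``(cells, labels, truth)`` where ``labels`` maps cell_id to
    population name and ``truth`` records the generating compartments and
    loop sets for diagnostics oracles.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cells: list[ContactTable] = []
    label_rows = []
    for pop, n_cells in zip(spec.populations, spec.cells_per_population):
        cache = _upper_probs(pop, spec)
        depths = np.exp(rng.normal(spec.depth_log_median, spec.depth_log_sigma,
                                   size=n_cells))
        depths = np.maximum(depths.astype(int), spec.depth_floor)
        for i in range(n_cells):
            cid = f"{pop.name}_{i:04d}"
            cells.append(sample_cell(pop, spec, int(depths[i]), rng, cid,
                                     _cache=cache))
            label_rows.append((cid, pop.name))
    labels = pd.Series({cid: name for cid, name in label_rows}, name="population")
    truth = {
        "resolution": spec.resolution,
        "n_bins": spec.n_bins,
        "chroms": spec.chroms,
        "populations": {
            pop.name: {
                "kappa": pop.kappa,
                "alpha": pop.alpha,
                "loop_boost": pop.loop_boost,
                "mitotic_shift": pop.mitotic_shift,
                "compartments": {c: v.tolist() for c, v in pop.compartments.items()},
                "loops": {c: [list(map(int, ab)) for ab in v]
                          for c, v in pop.loops.items()},
            }
            for pop in spec.populations
        },
    }
    return cells, labels, truth


def _random_loops(rng: np.random.Generator, n_bins: int, n_loops: int,
                  min_d: int = 3, max_d: int = 20) -> list[tuple[int, int]]:
    """Distinct short-range anchor pairs with distance in [min_d, max_d] bins."""
    loops = set()
    while len(loops) < n_loops:
        i = int(rng.integers(0, n_bins - min_d))
        d = int(rng.integers(min_d, min(max_d, n_bins - 1 - i) + 1))
        loops.add((i, i + d))
    return sorted(loops)


def _preset_compartment_contrast(seed: int, cells_per_pop: int = 100) -> DatasetSpec:
    """Two populations differing only in their A/B compartment tracks (kappa=0.4)."""
    n = DEFAULT_N_BINS
    comp_rng = np.random.default_rng(42)  # compartment geometry is part of the preset
    pops = [
        PopulationSpec("popA",
                       {f"chr{i+1}": random_compartments(n, comp_rng) for i in range(2)},
                       kappa=0.4),
        PopulationSpec("popB",
                       {f"chr{i+1}": random_compartments(n, comp_rng) for i in range(2)},
                       kappa=0.4),
    ]
    return DatasetSpec(pops, [cells_per_pop] * 2, seed=seed)


def _preset_loop_contrast(seed: int, cells_per_pop: int = 100) -> DatasetSpec:
    """Two populations sharing compartments but with disjoint loop sets."""
    n = DEFAULT_N_BINS
    comp = {f"chr{i+1}": checkerboard(n, phase=0) for i in range(2)}
    loop_rng = np.random.default_rng(12345)  # loop geometry is part of the preset
    loops_a = {c: _random_loops(loop_rng, n, 30) for c in comp}
    loops_b = {c: _random_loops(loop_rng, n, 30) for c in comp}
    # moderate focal enrichment (~3.5x) typical of chromatin loops; strong
    # enough to separate populations from short-range contacts but fine
    # enough that smoothing transforms can erase the contrast
    pops = [
        PopulationSpec("popA", comp, kappa=0.3, loops=loops_a, loop_boost=3.5),
        PopulationSpec("popB", comp, kappa=0.3, loops=loops_b, loop_boost=3.5),
    ]
    return DatasetSpec(pops, [cells_per_pop] * 2, seed=seed)


def _preset_cell_cycle_like(seed: int, cells_per_pop: int = 100) -> DatasetSpec:
    """A G-S-like and a mitotic-like population (excess 2-12 Mb contacts)."""
    n = DEFAULT_N_BINS
    comp = {f"chr{i+1}": checkerboard(n, phase=0) for i in range(2)}
    loop_rng = np.random.default_rng(777)
    loops = {c: _random_loops(loop_rng, n, 20) for c in comp}
    pops = [
        PopulationSpec("gs", comp, kappa=0.2, loops=loops, loop_boost=3.0,
                       mitotic_shift=0.0),
        PopulationSpec("mitotic", comp, kappa=0.2, loops=loops, loop_boost=3.0,
                       mitotic_shift=0.5),
    ]
    return DatasetSpec(pops, [cells_per_pop] * 2, seed=seed)


def _preset_mixed_tissue(seed: int, cells_per_pop: int = 50) -> DatasetSpec:
    """Three populations with independent compartments and loop sets.

    A multi-signal "tissue": every population differs from every other in
    both its A/B track and its loop anchors, so all backends — including the
    1D coverage baseline, which only sees the loop-anchor coverage bumps —
    can resolve it at full depth.
    """
    n = DEFAULT_N_BINS
    loop_rng = np.random.default_rng(2024)
    comp_rng = np.random.default_rng(2025)
    chroms = [f"chr{i+1}" for i in range(2)]
    pops = [
        PopulationSpec(name,
                       {c: random_compartments(n, comp_rng) for c in chroms},
                       kappa=0.4,
                       loops={c: _random_loops(loop_rng, n, 30) for c in chroms},
                       loop_boost=5.0)
        for name in ("typeA", "typeB", "typeC")
    ]
    return DatasetSpec(pops, [cells_per_pop] * 3, seed=seed)


def _preset_three_population_small(seed: int, cells_per_pop: int = 100) -> DatasetSpec:
    """Three well-separated populations on a small genome (2 x 64 bins).

    Strong compartment (kappa=0.5, independent tracks) and loop (6x, disjoint
    anchor sets) differences on deliberately small chromosomes, sized for
    training image-based models on a single CPU.
    """
    n = 64
    comp_rng = np.random.default_rng(31)
    loop_rng = np.random.default_rng(32)
    chroms = ["chr1", "chr2"]
    pops = []
    for name in ("popA", "popB", "popC"):
        pops.append(PopulationSpec(
            name,
            {c: random_compartments(n, comp_rng, block=8) for c in chroms},
            kappa=0.5,
            loops={c: _random_loops(loop_rng, n, 15) for c in chroms},
            loop_boost=6.0))
    return DatasetSpec(pops, [cells_per_pop] * 3, n_bins=n, seed=seed)


def _preset_power_law(seed: int, cells_per_pop: int = 100) -> DatasetSpec:
    """A single featureless power-law population (decay-only null model)."""
    pops = [PopulationSpec("null", {}, kappa=0.0)]
    return DatasetSpec(pops, [cells_per_pop], seed=seed)


PRESETS = {
    "compartment-contrast": _preset_compartment_contrast,
    "loop-contrast": _preset_loop_contrast,
    "cell-cycle-like": _preset_cell_cycle_like,
    "mixed-tissue": _preset_mixed_tissue,
    "three-population-small": _preset_three_population_small,
    "power-law": _preset_power_law,
}


def preset(name: str, seed: int = 0, **kwargs) -> DatasetSpec:
    """Named dataset preset (see :data:`PRESETS` for the catalogue)."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return factory(seed=seed, **kwargs)


def write_dataset(cells: Sequence[ContactTable], labels: pd.Series, truth: dict,
                  outdir: str | Path) -> None:
    """Emit per-cell pairs text, a chrom-sizes table, labels, and the truth sidecar."""
    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    sizes = cells[0].chrom_sizes
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    res = cells[0].resolution
    for cell in cells:
        with open(outdir / "cells" / f"{cell.cell_id}.pairs", "w") as fh:
            for row in cell.data.itertuples(index=False):
                pos1 = row.bin1 * res + 1
                pos2 = row.bin2 * res + 1
                fh.write(f"{row.chrom}\t{pos1}\t{pos2}\t{row.count}\n")
    labels.rename_axis("cell_id").to_frame().to_csv(outdir / "labels.tsv", sep="\t")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
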