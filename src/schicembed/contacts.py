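"""Per-cell cis contact tables: reading, binning, QC, downsampling, merging.

The universal input of every embedding backend in this package is the
:class:`ContactTable` — one cell's cis contacts binned at a fixed resolution
with canonical ``bin1 <= bin2`` keys.  Positions on disk are treated as
1-based (pairs-file convention); bins are 0-based half-open
``[bin*res, (bin+1)*res)``.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChromSizes",
    "ContactTable",
    "QCReport",
    "read_contacts",
    "qc_filter",
    "contact_fractions",
    "mitotic_filter",
    "downsample",
    "pseudobulk",
]

ENTRY_COLUMNS = ["chrom", "bin1", "bin2", "count"]


class ChromSizes(dict):
    """Mapping chromosome name -> length in base pairs."""

    def __init__(self, sizes: Mapping[str, int]):
        super().__init__()
        for chrom, length in sizes.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
            self[str(chrom)] = length

    def n_bins(self, chrom: str, resolution: int) -> int:
        return math.ceil(self[chrom] / resolution)

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromSizes":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "length"], dtype={"chrom": str})
        return cls(dict(zip(df["chrom"], df["length"])))


@dataclass
class ContactTable:
    """Binned cis contacts of one cell.

    ``data`` holds one row per unique (chrom, bin1, bin2) with bin1 <= bin2
    and a positive integer count.
    """

    cell_id: str
    resolution: int
    chrom_sizes: ChromSizes
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    @property
    def total_cis(self) -> int:
        return int(self.data["count"].sum())

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return self.chrom_sizes.n_bins(chrom, self.resolution)

    def distances_bp(self) -> np.ndarray:
        """Genomic distance of every entry, ``(bin2 - bin1) * resolution``."""
        d = (self.data["bin2"].to_numpy() - self.data["bin1"].to_numpy())
        return d * self.resolution

    def to_dense(self, chrom: str, dtype=np.float64) -> np.ndarray:
        """Symmetric dense contact matrix for one chromosome.

        Off-diagonal counts are mirrored; diagonal counts appear once.
        """
        m = self.n_bins(chrom)
        out = np.zeros((m, m), dtype=dtype)
        sub = self.data[self.data["chrom"] == chrom]
        b1 = sub["bin1"].to_numpy()
        b2 = sub["bin2"].to_numpy()
        c = sub["count"].to_numpy().astype(dtype)
        np.add.at(out, (b1, b2), c)
        off = b1 != b2
        np.add.at(out, (b2[off], b1[off]), c[off])
        return out

    def replace(self, data: pd.DataFrame, cell_id: str | None = None) -> "ContactTable":
        return ContactTable(cell_id=cell_id or self.cell_id,
                            resolution=self.resolution,
                            chrom_sizes=self.chrom_sizes,
                            data=data)


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce bin1 <= bin2 and sum duplicate keys."""
    b1 = np.minimum(df["bin1"], df["bin2"])
    b2 = np.maximum(df["bin1"], df["bin2"])
    out = pd.DataFrame({"chrom": df["chrom"].astype(str), "bin1": b1, "bin2": b2,
                        "count": df["count"].astype(np.int64)})
    out = (out.groupby(["chrom", "bin1", "bin2"], sort=True, observed=True)["count"]
              .sum().reset_index())
    return out[out["count"] > 0].reset_index(drop=True)


def make_table(cell_id: str, resolution: int, chrom_sizes: ChromSizes,
               chrom, bin1, bin2, count) -> ContactTable:
    """Build a ContactTable from parallel arrays, canonicalizing keys."""
    df = pd.DataFrame({"chrom": chrom, "bin1": np.asarray(bin1, dtype=np.int64),
                       "bin2": np.asarray(bin2, dtype=np.int64),
                       "count": np.asarray(count, dtype=np.int64)})
    return ContactTable(cell_id, resolution, chrom_sizes, _canonicalize(df))


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_pairs_file(path: Path, chrom_sizes: ChromSizes, resolution: int,
                      columns: Mapping[str, int] | None,
                      barcode_column: int | None):
    """Yield (cell_id, chrom, bin1, bin2, count) from one pairs-style file.

    Without an explicit ``columns`` mapping the layout is sniffed per line:
    ``chrom pos1 pos2 [count]`` (cis-only shorthand) or the pairs convention
    ``chrom1 pos1 chrom2 pos2 [count]``; trans records are dropped.
    """
    default_cell = path.name
    for suffix in (".gz", ".txt", ".tsv", ".pairs"):
        if default_cell.endswith(suffix):
            default_cell = default_cell[: -len(suffix)]
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if columns is not None:
                    chrom1 = fields[columns["chrom1"]]
                    pos1 = int(fields[columns["pos1"]])
                    chrom2 = fields[columns.get("chrom2", columns["chrom1"])]
                    pos2 = int(fields[columns["pos2"]])
                    count = int(fields[columns["count"]]) if "count" in columns else 1
                    cell = (fields[barcode_column]
                            if barcode_column is not None else default_cell)
                elif len(fields) >= 4 and not fields[2].lstrip("-").isdigit():
                    # chrom1 pos1 chrom2 pos2 [count]
                    chrom1, pos1 = fields[0], int(fields[1])
                    chrom2, pos2 = fields[2], int(fields[3])
                    count = int(fields[4]) if len(fields) > 4 else 1
                    cell = default_cell
                else:
                    chrom1 = chrom2 = fields[0]
                    pos1, pos2 = int(fields[1]), int(fields[2])
                    count = int(fields[3]) if len(fields) > 3 else 1
                    cell = default_cell
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record {line!r}") from exc
            if chrom1 != chrom2:
                continue  # trans contact
            if chrom1 not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom1!r}")
            size = chrom_sizes[chrom1]
            if pos1 < 1 or pos2 < 1 or pos1 > size or pos2 > size:
                raise ValueError(
                    f"{path}:{lineno}: position outside chromosome {chrom1} "
                    f"(length {size}): {pos1}, {pos2}")
            yield cell, chrom1, (pos1 - 1) // resolution, (pos2 - 1) // resolution, count


def read_contacts(paths: Sequence[str | Path] | str | Path,
                  chrom_sizes: ChromSizes,
                  resolution: int,
                  columns: Mapping[str, int] | None = None,
                  barcode_column: int | None = None) -> list[ContactTable]:
    """Read pairs-style text into per-cell contact tables.

    Parameters
    ----------
    paths
        One file per cell, or a single file with a cell barcode column
        (set ``barcode_column``).
    columns
        Optional explicit column indices with keys ``chrom1``, ``pos1``,
        ``pos2`` and optionally ``chrom2``, ``count``.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    records: dict[str, list] = {}
    for path in paths:
        for cell, chrom, b1, b2, count in _parse_pairs_file(
                Path(path), chrom_sizes, resolution, columns, barcode_column):
            records.setdefault(cell, []).append((chrom, b1, b2, count))
    tables = []
    for cell, rows in records.items():
        df = pd.DataFrame(rows, columns=ENTRY_COLUMNS)
        tables.append(ContactTable(cell, resolution, chrom_sizes, _canonicalize(df)))
    return tables


@dataclass
class QCReport:
    """Per-cell QC outcome; one row per input cell."""

    table: pd.DataFrame  # cell_id, total_cis, pass, fail_reason

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def qc_filter(cells: Sequence[ContactTable], min_cis: int = 5000,
              per_chrom_rule: bool = True) -> tuple[list[ContactTable], QCReport]:
    """Drop low-coverage cells.

    A cell is dropped iff it has *fewer than* ``min_cis`` cis contacts, or —
    with ``per_chrom_rule`` — any chromosome of length x Mb (x rounded up)
    carries fewer than x contacts.  The report records the first failing rule.
    """
    if min_cis < 0:
        raise ValueError("min_cis must be >= 0")
    kept: list[ContactTable] = []
    rows = []
    for cell in cells:
        total = cell.total_cis
        reason = ""
        if total < min_cis:
            reason = f"total_cis<{min_cis}"
        elif per_chrom_rule:
            per_chrom = cell.data.groupby("chrom", observed=True)["count"].sum()
            for chrom, length in cell.chrom_sizes.items():
                x = math.ceil(length / 1e6)
                if int(per_chrom.get(chrom, 0)) < x:
                    reason = f"chrom_rule:{chrom}<{x}"
                    break
        if reason:
            rows.append((cell.cell_id, total, False, reason))
        else:
            rows.append((cell.cell_id, total, True, ""))
            kept.append(cell)
    report = QCReport(pd.DataFrame(rows, columns=["cell_id", "total_cis",
                                                  "pass", "fail_reason"]))
    return kept, report


LOCAL_MIN_BP = 25_000
LOCAL_MAX_BP = 2_000_000
MITOTIC_MAX_BP = 12_000_000


def contact_fractions(cell: ContactTable) -> tuple[float, float]:
    """Fractions of local (25 kb–2 Mb) and mitotic (2–12 Mb) contacts.

    Both are relative to all contacts at distance > 25 kb.  Returns
    ``(nan, nan)`` when the denominator is zero.
    """
    d = cell.distances_bp()
    counts = cell.data["count"].to_numpy()
    denom = counts[d > LOCAL_MIN_BP].sum()
    if denom == 0:
        return (float("nan"), float("nan"))
    local = counts[(d > LOCAL_MIN_BP) & (d < LOCAL_MAX_BP)].sum()
    mitotic = counts[(d > LOCAL_MAX_BP) & (d < MITOTIC_MAX_BP)].sum()
    return (float(local / denom), float(mitotic / denom))


def mitotic_filter(cells: Sequence[ContactTable],
                   cutoff: tuple[float, float] = (0.15, 0.35),
                   ) -> tuple[list[ContactTable], list[ContactTable], dict]:
    """Partition cells into G-S-like and mitotic-like by contact fractions.

    A 2-sigma covariance ellipse is fit to the (f_local, f_mitotic) scatter;
    the line through ``cutoff`` and the ellipse center splits the plane, and
    the "left ascending" side — higher local / lower mitotic fraction — is
    G-S.  Returns ``(gs_cells, mitotic_cells, fit_info)``.
    """
    if len(cells) < 10:
        raise ValueError("mitotic_filter needs at least 10 cells to fit the ellipse")
    pts = np.array([contact_fractions(c) for c in cells], dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("undefined contact fractions (cells without >25 kb contacts)")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[-1], 1e-30) or evals[-1] <= 0:
        raise ValueError("degenerate fraction scatter; set a manual threshold instead")
    direction = center - np.asarray(cutoff)
    if np.linalg.norm(direction) < 1e-9:
        raise ValueError("ellipse center coincides with the cutoff point; "
                         "set a manual threshold instead")
    normal = np.array([-direction[1], direction[0]])
    # orient the normal toward the high-local / low-mitotic corner
    if normal @ np.array([1.0, -1.0]) < 0:
        normal = -normal
    side = (pts - np.asarray(cutoff)) @ normal
    gs = [c for c, s in zip(cells, side) if s > 0]
    mitotic = [c for c, s in zip(cells, side) if s <= 0]
    info = {"center": center.tolist(),
            "major_axis": evecs[:, -1].tolist(),
            "axis_lengths_2sigma": (2 * np.sqrt(np.maximum(evals[::-1], 0))).tolist(),
            "cutoff": list(cutoff),
            "rule": "2-sigma covariance ellipse; split by the line through "
                    "the cutoff point and the ellipse center"}
    return gs, mitotic, info


def downsample(cell: ContactTable, fraction: float, seed: int) -> ContactTable:
    """Retain ``round(fraction * total_cis)`` reads without replacement.

    Multivariate hypergeometric draw over the multiset of contacts, so each
    entry's retained count has expectation ``fraction * count``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return cell.replace(cell.data.copy())
    counts = cell.data["count"].to_numpy()
    n_draw = int(round(fraction * counts.sum()))
    rng = np.random.default_rng(seed)
    new_counts = rng.multivariate_hypergeometric(counts, n_draw)
    df = cell.data.copy()
    df["count"] = new_counts
    df = df[df["count"] > 0].reset_index(drop=True)
    return cell.replace(df)


def pseudobulk(cells: Sequence[ContactTable], cell_id: str = "pseudobulk") -> ContactTable:
    """Entrywise sum of counts across cells (raw read pooling)."""
    cells = list(cells)
    if not cells:
        raise ValueError("pseudobulk of an empty cell set")
    res = cells[0].resolution
    chroms = set(cells[0].chrom_sizes)
    for c in cells[1:]:
        if c.resolution != res or set(c.chrom_sizes) != chroms:
            raise ValueError("pseudobulk requires a shared resolution and chromosome set")
    df = pd.concat([c.data for c in cells], ignore_index=True)
    merged = (df.groupby(["chrom", "bin1", "bin2"], sort=True, observed=True)["count"]
                .sum().reset_index())
    return ContactTable(cell_id, res, cells[0].chrom_sizes, merged)
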