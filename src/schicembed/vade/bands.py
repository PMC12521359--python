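"""Band-matrix images: stacked strata of a cell's contact maps.

Row ``s`` of a cell's image holds the s-th diagonal of every chromosome's
binned contact matrix, with chromosomes laid out left to right along the
column axis and separated by zero-padding columns.  The image sum therefore
equals the cell's total count within the first k strata.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..contacts import ContactTable
from ..transforms import extract_strata

__all__ = ["build_band_images", "band_image_shape"]

CHROM_GAP = 1  # zero columns between chromosomes


def band_image_shape(cell: ContactTable, n_strata: int) -> tuple[int, int]:
    widths = [cell.n_bins(c) for c in cell.chroms]
    return n_strata, sum(widths) + CHROM_GAP * (len(widths) - 1)


def build_band_images(cells: Sequence[ContactTable], n_strata: int) -> np.ndarray:
    """Stack the first ``n_strata`` strata of every cell into 2-D images.

    Returns an (N, k, L) array; identical cells yield identical images.
    """
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    first = cells[0]
    min_bins = min(first.n_bins(c) for c in first.chroms)
    if n_strata > min_bins:
        raise ValueError(
            f"n_strata={n_strata} exceeds the smallest chromosome "
            f"({min_bins} bins); use a smaller k")
    k, width = band_image_shape(first, n_strata)
    images = np.zeros((len(cells), k, width))
    for idx, cell in enumerate(cells):
        strata = extract_strata(cell, n_strata)
        offset = 0
        for chrom in cell.chroms:
            m = cell.n_bins(chrom)
            for s, vec in enumerate(strata[chrom]):
                images[idx, s, offset:offset + m - s] = vec
            offset += m + CHROM_GAP
    return images
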