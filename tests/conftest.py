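import numpy as np
import pandas as pd
import pytest

from schicembed.contacts import ChromSizes, make_table


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 2_000_000, "chr2": 1_500_000})


def table(entries, resolution=100_000, sizes=None, cell_id="cell"):
    """Build a ContactTable from (chrom, bin1, bin2, count) tuples."""
    if sizes is None:
        sizes = ChromSizes({"chr1": 40_000_000, "chr2": 40_000_000})
    chrom, b1, b2, c = zip(*entries)
    return make_table(cell_id, resolution, sizes, list(chrom), b1, b2, c)


@pytest.fixture
def small_dataset():
    """20 cells from two easily separable populations (tiny, fast)."""
    from schicembed.synthetic import preset, generate_dataset
    spec = preset("compartment-contrast", seed=7, cells_per_pop=10)
    cells, labels, truth = generate_dataset(spec)
    return cells, pd.factorize(labels)[0], truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
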