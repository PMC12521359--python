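"""Contact table I/O, QC filtering, fractions, downsampling, pooling."""

import numpy as np
import pytest

from schicembed.contacts import (contact_fractions, downsample,
                                 mitotic_filter, pseudobulk, qc_filter,
                                 read_contacts)
from .conftest import table


class TestReadContacts:
    def test_binning_arithmetic(self, tmp_path, sizes):
        f = tmp_path / "a.pairs"
        f.write_text("chr1 150 950\n")
        (cell,) = read_contacts([f], sizes, resolution=500)
        assert cell.data.to_records(index=False).tolist() == [("chr1", 0, 1, 1)]

    def test_canonicalization_and_dedup(self, tmp_path, sizes):
        f = tmp_path / "a.pairs"
        f.write_text("chr1 10 20\nchr1 20 10\n")
        (cell,) = read_contacts([f], sizes, resolution=100)
        assert cell.data.to_records(index=False).tolist() == [("chr1", 0, 0, 2)]
        assert cell.total_cis == 2

    def test_trans_records_dropped(self, tmp_path, sizes):
        f = tmp_path / "a.pairs"
        f.write_text("chr1 10 chr2 10\nchr1 10 500\n")
        (cell,) = read_contacts([f], sizes, resolution=100)
        assert cell.total_cis == 1
        assert set(cell.data["chrom"]) == {"chr1"}

    def test_malformed_line_names_file_and_line(self, tmp_path, sizes):
        f = tmp_path / "bad.pairs"
        f.write_text("chr1 10 20\nchr1 oops 30\n")
        with pytest.raises(ValueError, match=r"bad\.pairs:2"):
            read_contacts([f], sizes, resolution=100)

    def test_position_beyond_chromosome_errors(self, tmp_path, sizes):
        f = tmp_path / "a.pairs"
        f.write_text("chr1 10 99999999\n")
        with pytest.raises(ValueError, match="outside chromosome"):
            read_contacts([f], sizes, resolution=100)

    def test_barcode_column_splits_cells(self, tmp_path, sizes):
        f = tmp_path / "pooled.pairs"
        f.write_text("chr1 10 500 1 cellA\nchr1 10 500 1 cellB\n")
        cells = read_contacts([f], sizes, resolution=100,
                              columns={"chrom1": 0, "pos1": 1, "pos2": 2,
                                       "count": 3}, barcode_column=4)
        assert sorted(c.cell_id for c in cells) == ["cellA", "cellB"]


class TestQCFilter:
    def _cell(self, n, spread_chroms=True):
        # n contacts on chr1 (+1 on chr2 so the per-chrom rule sees both)
        entries = [("chr1", 0, i % 300, 1) for i in range(n)]
        if spread_chroms:
            entries += [("chr2", 0, i, 1) for i in range(50)]
        return table(entries)

    def test_strictly_fewer_than_threshold(self):
        low = self._cell(4_999 - 50)
        ok = self._cell(5_000 - 50)
        kept, report = qc_filter([low, ok], min_cis=5_000, per_chrom_rule=False)
        assert [c.cell_id for c in kept] == [ok.cell_id] or len(kept) == 1
        assert report.table["pass"].tolist() == [False, True]

    def test_per_chromosome_rule(self):
        # 40 Mb chromosome needs >= 40 contacts; chr2 has only 20
        entries = ([("chr1", 0, i % 300, 20) for i in range(300)]
                   + [("chr2", 0, i, 1) for i in range(20)])
        cell = table(entries)
        assert cell.total_cis > 5_000
        kept, report = qc_filter([cell], min_cis=5_000, per_chrom_rule=True)
        assert kept == []
        assert report.table["fail_reason"].iloc[0].startswith("chrom_rule:chr2")

    def test_empty_input_is_not_an_error(self):
        kept, report = qc_filter([], min_cis=5_000)
        assert kept == [] and len(report.table) == 0

    def test_idempotent_and_order_independent(self):
        cells = [self._cell(6_000), self._cell(100), self._cell(7_000)]
        kept1, _ = qc_filter(cells, 5_000)
        kept2, _ = qc_filter(kept1, 5_000)
        assert [c.cell_id for c in kept1] == [c.cell_id for c in kept2]
        kept_rev, _ = qc_filter(cells[::-1], 5_000)
        assert {id(c) for c in kept_rev} == {id(c) for c in kept1}


class TestContactFractions:
    def test_single_band_local(self):
        cell = table([("chr1", 0, 10, 5)])  # 1 Mb
        assert contact_fractions(cell) == (1.0, 0.0)

    def test_single_band_mitotic(self):
        cell = table([("chr1", 0, 50, 5)])  # 5 Mb
        assert contact_fractions(cell) == (0.0, 1.0)

    def test_equal_counts_split(self):
        cell = table([("chr1", 0, 10, 7), ("chr1", 0, 50, 7)])
        assert contact_fractions(cell) == (0.5, 0.5)

    def test_fractions_sum_with_remainder(self):
        cell = table([("chr1", 0, 10, 3), ("chr1", 0, 50, 3),
                      ("chr1", 0, 150, 4)])  # 15 Mb -> remainder band
        f_l, f_m = contact_fractions(cell)
        remainder = 4 / 10
        assert abs(f_l + f_m + remainder - 1.0) < 1e-12

    def test_undefined_when_no_long_contacts(self):
        cell = table([("chr1", 0, 0, 5)])
        f_l, f_m = contact_fractions(cell)
        assert np.isnan(f_l) and np.isnan(f_m)


class TestMitoticFilter:
    @staticmethod
    def _cell_with_fractions(c_local, c_mitotic, c_far, name):
        return table([("chr1", 0, 10, c_local), ("chr1", 0, 50, c_mitotic),
                      ("chr1", 0, 150, c_far)], cell_id=name)

    def test_extreme_cells_classified(self, rng):
        cells = []
        for i in range(20):  # scatter around (0.5, 0.2)
            cells.append(self._cell_with_fractions(
                50 + int(rng.integers(-5, 5)), 20 + int(rng.integers(-5, 5)),
                30, f"bg{i}"))
        gs_cell = self._cell_with_fractions(90, 2, 8, "local_dominated")
        m_cell = self._cell_with_fractions(5, 90, 5, "mitotic_dominated")
        gs, mitotic, info = mitotic_filter(cells + [gs_cell, m_cell])
        assert any(c.cell_id == "local_dominated" for c in gs)
        assert any(c.cell_id == "mitotic_dominated" for c in mitotic)
        assert len(gs) + len(mitotic) == 22

    def test_label_recovery_on_synthetic_populations(self):
        from schicembed.synthetic import generate_dataset, preset
        cells, labels, _ = generate_dataset(
            preset("cell-cycle-like", seed=3, cells_per_pop=40))
        gs, _, _ = mitotic_filter(cells)
        gs_ids = {c.cell_id for c in gs}
        correct = sum((c.cell_id in gs_ids) == (lab == "gs")
                      for c, lab in zip(cells, labels))
        assert correct / len(cells) >= 0.95

    def test_degenerate_scatter_errors(self):
        cells = [self._cell_with_fractions(50, 20, 30, f"c{i}")
                 for i in range(12)]  # identical fractions -> rank deficient
        with pytest.raises(ValueError, match="degenerate|manual"):
            mitotic_filter(cells)

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError, match="10 cells"):
            mitotic_filter([self._cell_with_fractions(5, 5, 5, "x")])


class TestDownsample:
    def test_identity_at_full_fraction(self):
        cell = table([("chr1", 0, 1, 10), ("chr1", 2, 3, 5)])
        out = downsample(cell, 1.0, seed=0)
        assert out.data.equals(cell.data)

    def test_exact_sample_size(self):
        cell = table([("chr1", 0, i, 100) for i in range(100)])
        assert cell.total_cis == 10_000
        out = downsample(cell, 0.5, seed=1)
        assert out.total_cis == 5_000

    def test_hypergeometric_mean(self):
        cell = table([("chr1", 0, 1, 1_000), ("chr1", 2, 3, 4_000)])
        kept = []
        for seed in range(200):
            out = downsample(cell, 0.2, seed=seed)
            sub = out.data[(out.data.bin1 == 0) & (out.data.bin2 == 1)]
            kept.append(int(sub["count"].sum()))
        # mean of a hypergeometric draw (N=5000, K=1000, n=1000) is 200
        sigma = np.sqrt(1000 * 0.2 * 0.8 * (4000 / 4999))
        assert abs(np.mean(kept) - 200) < 3 * sigma / np.sqrt(200)

    def test_composition_matches_product_in_totals(self):
        cell = table([("chr1", 0, i, 50) for i in range(100)])
        totals_two_step = [downsample(downsample(cell, 0.5, s), 0.4, s + 1).total_cis
                           for s in range(20)]
        totals_direct = [downsample(cell, 0.2, s).total_cis for s in range(20)]
        # both schemes draw round(f*total) reads exactly
        assert set(totals_two_step) == {1_000} and set(totals_direct) == {1_000}

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_fraction(self, bad):
        cell = table([("chr1", 0, 1, 10)])
        with pytest.raises(ValueError):
            downsample(cell, bad, seed=0)


class TestPseudobulk:
    def test_identical_cells_double(self):
        cell = table([("chr1", 0, 1, 3), ("chr1", 1, 2, 4)])
        bulk = pseudobulk([cell, cell])
        assert (bulk.data["count"] == [6, 8]).all()

    def test_disjoint_union_and_conservation(self):
        a = table([("chr1", 0, 1, 3)])
        b = table([("chr2", 5, 6, 4)])
        bulk = pseudobulk([a, b])
        assert len(bulk.data) == 2
        assert bulk.total_cis == a.total_cis + b.total_cis

    def test_mixed_resolution_errors(self):
        a = table([("chr1", 0, 1, 3)], resolution=100_000)
        b = table([("chr1", 0, 1, 3)], resolution=50_000)
        with pytest.raises(ValueError, match="resolution"):
            pseudobulk([a, b])
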