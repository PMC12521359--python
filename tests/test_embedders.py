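"""Embedding backends: coverage PCA, imputation-PCA, strata MDS, spectral,
topic model, insulation."""

import numpy as np
import pytest

from schicembed.contacts import ChromSizes
from schicembed.embedders import (BinCoveragePCA, CisTopicLDA, InnerProductMDS,
                                  InsulationPCA, SCHiCluster, SpectralIDF,
                                  classical_mds, similarity_innerproduct)
from .conftest import table

ONE_CHROM = ChromSizes({"chr1": 40_000_000})
SHORT_CHROM = ChromSizes({"chr1": 3_000_000})


class TestBinCoveragePCA:
    def test_endpoint_increments(self):
        cell = table([("chr1", 0, 1, 1)])
        cov = BinCoveragePCA.coverage_vector(cell)
        assert cov[0] == 1 and cov[1] == 1 and cov[2:].sum() == 0

    def test_intra_bin_contact_counts_twice(self):
        cell = table([("chr1", 3, 3, 2)])
        cov = BinCoveragePCA.coverage_vector(cell)
        assert cov[3] == 4

    def test_total_is_twice_cis(self):
        cell = table([("chr1", 0, 5, 3), ("chr2", 1, 1, 2)])
        assert BinCoveragePCA.coverage_vector(cell).sum() == 2 * cell.total_cis

    def test_identical_cells_identical_rows(self):
        a = table([("chr1", 0, 5, 3), ("chr1", 2, 9, 1)], cell_id="a")
        b = table([("chr1", 0, 5, 3), ("chr1", 2, 9, 1)], cell_id="b")
        c = table([("chr1", 7, 8, 4)], cell_id="c")
        emb = BinCoveragePCA(n_components=2).fit_transform([a, b, c])
        assert np.allclose(emb[0], emb[1])

    def test_d_must_be_less_than_n(self):
        cells = [table([("chr1", 0, i, 1)], cell_id=str(i)) for i in range(3)]
        with pytest.raises(ValueError):
            BinCoveragePCA(n_components=3).fit(cells)


class TestInnerProductSimilarity:
    def test_self_similarity_is_one(self):
        cell = table([("chr1", i, i, i + 1) for i in range(5)],
                     sizes=ONE_CHROM)
        sim = similarity_innerproduct([cell, cell], n_strata=1, max_bp=1e5)
        assert sim.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_reversed_stratum_gives_minus_one(self):
        three_bins = ChromSizes({"chr1": 300_000})
        a = table([("chr1", 0, 0, 1), ("chr1", 1, 1, 2), ("chr1", 2, 2, 3)],
                  cell_id="a", sizes=three_bins)
        b = table([("chr1", 0, 0, 3), ("chr1", 1, 1, 2), ("chr1", 2, 2, 1)],
                  cell_id="b", sizes=three_bins)
        sim = similarity_innerproduct([a, b], n_strata=1, max_bp=1e5)
        assert sim.values[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_single_stratum_equals_pearson_oracle(self, rng):
        cells = []
        for i in range(4):
            counts = rng.integers(1, 20, size=10)
            cells.append(table([("chr1", j, j, int(c))
                                for j, c in enumerate(counts)],
                               cell_id=f"c{i}", sizes=ONE_CHROM))
        sim = similarity_innerproduct(cells, n_strata=1, max_bp=1e5,
                                      chrom_agg="mean")
        vecs = np.stack([[cells[i].to_dense("chr1")[j, j] for j in range(400)]
                         for i in range(4)])
        oracle = np.corrcoef(vecs)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(sim.values[off], oracle[off], atol=1e-9)

    def test_constant_stratum_contributes_zero(self):
        a = table([("chr1", j, j, 5) for j in range(400)], cell_id="a",
                  sizes=ONE_CHROM)
        b = table([("chr1", j, j, j + 1) for j in range(400)], cell_id="b",
                  sizes=ONE_CHROM)
        sim = similarity_innerproduct([a, b], n_strata=1, max_bp=1e5)
        assert sim.values[0, 1] == 0.0

    def test_scc_weights_emphasize_high_variance_strata(self, rng):
        # cells agree on stratum 0 and disagree on stratum 1; the raw-sigma
        # weights must move the combined similarity toward the stratum with
        # larger N_s * sigma_i * sigma_j
        base = rng.integers(1, 30, size=30)
        entries_a = [("chr1", j, j, int(c)) for j, c in enumerate(base)]
        entries_b = list(entries_a)
        entries_a += [("chr1", j, j + 1, int(c)) for j, c in enumerate(base[:-1])]
        entries_b += [("chr1", j, j + 1, int(c))
                      for j, c in enumerate(base[:-1][::-1])]
        a = table(entries_a, cell_id="a", sizes=ONE_CHROM)
        b = table(entries_b, cell_id="b", sizes=ONE_CHROM)
        uni = similarity_innerproduct([a, b], n_strata=2, max_bp=2e5).values[0, 1]
        scc = similarity_innerproduct([a, b], n_strata=2, max_bp=2e5,
                                      weights="scc").values[0, 1]
        assert uni != pytest.approx(scc)


class TestClassicalMDS:
    def test_equilateral_triangle(self):
        rho = 0.5
        s = np.full((3, 3), rho)
        np.fill_diagonal(s, 1.0)
        coords = classical_mds(s, 2)
        side = np.sqrt(2 * (1 - rho))
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(coords), side, atol=1e-8)

    def test_all_ones_collapse_to_origin(self):
        coords = classical_mds(np.ones((4, 4)), 2)
        assert np.abs(coords).max() < 1e-9

    def test_reconstructs_euclidean_distances(self, rng):
        pts = rng.normal(size=(5, 2)) * 0.3  # keep d^2 <= 4, s in [-1, 1]
        from scipy.spatial.distance import squareform, pdist
        d = squareform(pdist(pts))
        s = 1 - d ** 2 / 2
        coords = classical_mds(s, 2)
        assert np.allclose(squareform(pdist(coords)), d, atol=1e-8)

    def test_padding_warns_when_rank_deficient(self):
        with pytest.warns(UserWarning, match="padding"):
            coords = classical_mds(np.ones((3, 3)), 2)
        assert coords.shape == (3, 2)


class TestSpectralIDF:
    def _two_groups(self):
        cells = []
        for i in range(4):  # group 1: features on chr1
            cells.append(table([("chr1", j, j + 1, 2) for j in range(5)],
                               cell_id=f"g1_{i}"))
        for i in range(4):  # group 2: disjoint features on chr2
            cells.append(table([("chr2", j, j + 1, 2) for j in range(5)],
                               cell_id=f"g2_{i}"))
        return cells

    def test_disjoint_groups_separate_by_sign(self):
        emb = SpectralIDF(n_components=2, top_n=100).fit_transform(
            self._two_groups())
        signs = np.sign(emb[:, 0])
        assert len(set(signs[:4])) == 1 and len(set(signs[4:])) == 1
        assert signs[0] != signs[4]

    def test_duplicated_cell_identical_coordinates(self):
        cells = self._two_groups()
        cells.append(table([("chr1", j, j + 1, 2) for j in range(5)],
                           cell_id="dup"))
        emb = SpectralIDF(n_components=2, top_n=100).fit_transform(cells)
        assert np.allclose(emb[0], emb[-1], atol=1e-9)

    def test_cosine_self_similarity_diagonal(self):
        est = SpectralIDF(n_components=2, top_n=100).fit(self._two_groups())
        assert np.allclose(np.diag(est.similarity_.values), 1.0)

    def test_empty_feature_row_names_cell(self):
        cells = self._two_groups()
        cells.append(table([("chr1", 300, 399, 1)], cell_id="lonely"))
        with pytest.raises(ValueError, match="lonely"):
            # quantile filter drops the single-cell outlier feature
            SpectralIDF(n_components=2, q_low=0.2, q_high=0.0,
                        top_n=100).fit(cells)


class TestCisTopicLDA:
    def _corpus(self):
        cells = []
        for i in range(6):
            cells.append(table([("chr1", j, j + 1, 20) for j in range(8)],
                               cell_id=f"g1_{i}"))
        for i in range(6):
            cells.append(table([("chr2", j, j + 1, 20) for j in range(8)],
                               cell_id=f"g2_{i}"))
        return cells

    def test_rows_sum_to_one(self):
        emb = CisTopicLDA(n_topics=3, n_iter=30, random_state=0
                          ).fit_transform(self._corpus())
        assert np.allclose(emb.sum(axis=1), 1.0, atol=1e-9)

    def test_single_topic_degenerates(self):
        emb = CisTopicLDA(n_topics=1, n_iter=10).fit_transform(self._corpus())
        assert np.allclose(emb, 1.0)

    def test_disjoint_vocabularies_get_distinct_topics(self):
        hits = 0
        total = 0
        for seed in range(5):
            emb = CisTopicLDA(n_topics=2, n_iter=100, random_state=seed
                              ).fit_transform(self._corpus())
            dom = emb.argmax(axis=1)
            # within each group the dominant topic should be homogeneous and
            # differ between groups
            for g in (dom[:6], dom[6:]):
                total += len(g)
                hits += max(np.sum(g == 0), np.sum(g == 1))
            if dom[:6].mean() == dom[6:].mean():
                hits -= 6  # same topic for both groups counts as failure
        assert hits / total >= 0.95

    def test_empty_vocabulary_errors(self):
        a = table([("chr1", 0, 300, 1)], cell_id="a")
        b = table([("chr1", 0, 310, 1)], cell_id="b")
        with pytest.raises(ValueError, match="window|vocabulary"):
            CisTopicLDA(n_topics=2, max_bp=1e5).fit([a, b])


class TestInsulationPCA:
    def test_uniform_matrix_zero_delta(self):
        entries = [("chr1", i, j, 1) for i in range(30) for j in range(i, 30)]
        cell = table(entries, sizes=SHORT_CHROM)
        est = InsulationPCA(window=5, delta_w=2)
        dv = est._delta_vector(cell, "chr1")
        assert np.abs(dv[:30]).max() == pytest.approx(0.0, abs=1e-9)

    def test_two_block_toy_changes_sign_at_boundary(self):
        entries = ([("chr1", i, j, 10) for i in range(8) for j in range(i, 8)]
                   + [("chr1", i, j, 10) for i in range(8, 16)
                      for j in range(i, 16)]
                   + [("chr1", i, j, 1) for i in range(30)
                      for j in range(i, 30)])
        cell = table(entries, sizes=SHORT_CHROM)
        est = InsulationPCA(window=4, delta_w=2)
        dv = est._delta_vector(cell, "chr1")
        # insulation dips at the block boundary (bin 8): the downstream-minus-
        # upstream delta is negative approaching the dip and positive past it
        assert dv[6] < 0 < dv[10]

    def test_identical_cells_identical_vectors(self):
        entries = [("chr1", i, i + 2, i % 5 + 1) for i in range(28)]
        a = table(entries, cell_id="a", sizes=SHORT_CHROM)
        b = table(entries, cell_id="b", sizes=SHORT_CHROM)
        est = InsulationPCA(window=3, delta_w=2)
        assert np.allclose(est._delta_vector(a, "chr1"),
                           est._delta_vector(b, "chr1"))

    def test_short_chromosome_skipped_with_warning(self):
        from schicembed.contacts import ChromSizes
        sizes = ChromSizes({"chr1": 500_000})  # 5 bins at 100 kb
        cells = [table([("chr1", 0, i, 2) for i in range(5)], sizes=sizes,
                       cell_id=f"c{i}") for i in range(3)]
        with pytest.raises(ValueError, match="insulation window"):
            with pytest.warns(UserWarning):
                InsulationPCA(window=10).fit(cells)


class TestPermutationEquivariance:
    @pytest.mark.parametrize("factory", [
        lambda: BinCoveragePCA(n_components=2),
        lambda: InnerProductMDS(n_components=2),
        lambda: SpectralIDF(n_components=2, top_n=10**6),
        lambda: CisTopicLDA(n_topics=3, n_iter=30, random_state=0),
        lambda: InsulationPCA(n_components=2, window=5),
    ])
    def test_permuting_cells_permutes_rows(self, factory, small_dataset):
        cells, _, _ = small_dataset
        perm = np.random.default_rng(3).permutation(len(cells))
        emb = factory().fit_transform(cells)
        emb_perm = factory().fit_transform([cells[i] for i in perm])
        if isinstance(factory(), CisTopicLDA):
            # Gibbs token order changes with cell order; check topic
            # composition is permuted only approximately
            assert np.allclose(emb[perm].mean(0), emb_perm.mean(0), atol=0.1)
        else:
            assert np.allclose(np.abs(emb[perm]), np.abs(emb_perm), atol=1e-6)


class TestSCHiCluster:
    def test_degenerates_to_pca_of_vc_matrices(self, small_dataset):
        """With no box filter, no random walk and no binarization the chain
        is a per-chromosome PCA of VC-sqrt-normalized matrices."""
        from sklearn.decomposition import PCA
        from schicembed.transforms import vc_sqrt_norm
        cells, _, _ = small_dataset
        est = SCHiCluster(n_components=2, pcs_per_chrom=5, top_frac=None,
                          box_width=0, use_random_walk=False)
        emb = est.fit_transform(cells)

        blocks = []
        for chrom in cells[0].chroms:
            flat = np.stack([vc_sqrt_norm(c.to_dense(chrom, dtype=np.float32)
                                          ).ravel() for c in cells])
            blocks.append(PCA(5, svd_solver="full",
                              random_state=0).fit_transform(flat))
        oracle = PCA(2, svd_solver="full",
                     random_state=0).fit_transform(np.hstack(blocks))
        # compare up to per-column sign
        for j in range(2):
            assert (np.allclose(emb[:, j], oracle[:, j], atol=1e-4)
                    or np.allclose(emb[:, j], -oracle[:, j], atol=1e-4))

    def test_full_top_frac_keeps_all_nonzero(self):
        cells = [table([("chr1", 0, 1, 3), ("chr1", 4, 5, 1)], cell_id="a"),
                 table([("chr1", 2, 3, 2)], cell_id="b"),
                 table([("chr1", 0, 2, 2)], cell_id="c")]
        est = SCHiCluster(top_frac=1.0, box_width=0, use_random_walk=False)
        processed = est._process(cells[0], "chr1")
        dense = cells[0].to_dense("chr1")
        assert ((processed > 0) == (dense > 0)).all()
        assert set(np.unique(processed)) <= {0.0, 1.0}
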