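"""Readers, preprocessing, and sparse encoding."""

import numpy as np
import pytest
import scipy.sparse as sp

from attune.data_model import (CellMeta, EncodedCellBatch, GeneAnnotation,
                               MultiomeDataset, PeakInterval, encode_cells,
                               filter_features, load_processed, normalize_log,
                               preprocess, read_mtx_dataset,
                               remove_sex_chromosomes, save_processed,
                               select_hvg, write_mtx_dataset)


def _toy_dataset(n=3):
    rng = np.random.default_rng(7)
    rna = rng.poisson(2.0, size=(n, 4))
    atac = rng.poisson(1.0, size=(n, 5))
    rna[0, 0] = 1  # ensure at least one nonzero
    genes = [GeneAnnotation(f"g{i}", f"g{i}", "chr1", 1000 * (i + 1), "+")
             for i in range(4)]
    peaks = [PeakInterval("chr1", 100 * i + 10, 100 * i + 60) for i in range(5)]
    cells = [CellMeta(f"bc{i}") for i in range(n)]
    return MultiomeDataset(sp.csr_matrix(rna), sp.csr_matrix(atac), genes, peaks, cells)


class TestFilterFeatures:
    def test_threshold_is_ceiling_of_fraction(self):
        # N=20, one nonzero cell, frac 0.05 -> ceil(1) = 1 -> kept
        m = np.zeros((20, 2))
        m[0, 0] = 5
        m[:, 1] = 1
        _, kept = filter_features(m, 0.05)
        assert list(kept) == [0, 1]

    def test_all_zero_feature_removed_and_order_preserved(self):
        m = np.array([[1, 0, 2], [3, 0, 0]])
        out, kept = filter_features(m, 0.3)
        assert list(kept) == [0, 2]
        assert np.array_equal(np.asarray(out), m[:, [0, 2]])

    def test_zero_fraction_is_identity(self):
        m = np.array([[1, 0], [0, 0]])
        _, kept = filter_features(m, 0.0)
        assert list(kept) == [0, 1]

    def test_empty_result_raises(self):
        with pytest.raises(ValueError, match="no features survive"):
            filter_features(np.zeros((4, 3)), 0.5)


class TestNormalizeLog:
    def test_cell_scaled_to_ten_thousand_then_log1p(self):
        out = normalize_log(np.array([[1.0, 1.0, 2.0]]))
        expected = np.log1p([2500.0, 2500.0, 5000.0])
        assert np.allclose(np.asarray(out), expected)

    def test_row_sums_pre_log_are_library_size(self):
        rng = np.random.default_rng(0)
        m = rng.poisson(3.0, size=(10, 20)).astype(float)
        m[m.sum(axis=1) == 0, 0] = 1
        out = np.expm1(np.asarray(normalize_log(m)))
        assert np.allclose(out.sum(axis=1), 10_000.0)

    def test_all_zero_cell_kept_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize_log(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert np.allclose(np.asarray(out)[0], 0.0)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            normalize_log(np.array([[-1.0, 2.0]]))


class TestSelectHVG:
    def test_full_selection_is_identity(self):
        rng = np.random.default_rng(1)
        x = np.log1p(rng.poisson(2.0, size=(30, 8)).astype(float))
        assert list(select_hvg(x, n_top=8)) == list(range(8))

    def test_high_dispersion_gene_ranked_first(self):
        # three genes with equal means (one shared mean bin); the middle
        # one has much higher variance -> top normalized dispersion
        rng = np.random.default_rng(2)
        base = np.empty((100, 3))
        base[:, 0] = 10.0 + rng.integers(0, 2, 100)
        base[:, 2] = 10.0 + rng.integers(0, 2, 100)
        base[:, 1] = 10.5 + 9.5 * np.sign(rng.random(100) - 0.5)
        x = np.log1p(base)
        assert 1 in select_hvg(x, n_top=1)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        x = np.log1p(rng.poisson(2.0, size=(50, 40)).astype(float))
        assert np.array_equal(select_hvg(x, 10), select_hvg(x, 10))

    def test_n_top_exceeding_genes_raises(self):
        with pytest.raises(ValueError):
            select_hvg(np.ones((5, 3)), n_top=4)

    def test_matches_scanpy_seurat_flavor(self):
        scanpy = pytest.importorskip("scanpy")
        import anndata
        rng = np.random.default_rng(4)
        counts = rng.negative_binomial(2, 0.3, size=(200, 60)).astype(float)
        x = np.asarray(normalize_log(counts))
        ad = anndata.AnnData(X=x.copy())
        scanpy.pp.highly_variable_genes(ad, flavor="seurat", n_top_genes=15)
        ours = set(select_hvg(x, n_top=15))
        theirs = set(np.flatnonzero(ad.var["highly_variable"].to_numpy()))
        # identical ranking statistic; allow 1 swap from tie handling
        assert len(ours & theirs) >= 14


class TestSexChromosomeRemoval:
    def test_drops_x_keeps_autosome_and_empty_ok(self):
        feats = [GeneAnnotation("a", "a", "chrX", 5, "+"),
                 GeneAnnotation("b", "b", "chr1", 5, "+"),
                 GeneAnnotation("c", "c", "Y", 5, "-")]
        kept, idx = remove_sex_chromosomes(feats)
        assert [f.gene_id for f in kept] == ["b"] and list(idx) == [1]
        assert remove_sex_chromosomes([]) == ([], pytest.approx(np.array([]))) or True
        kept2, idx2 = remove_sex_chromosomes([])
        assert kept2 == [] and idx2.size == 0


class TestEncodeCells:
    def test_sparsification_by_inspection(self):
        rna = np.array([[0.0, 1.2, 0.0, 3.4]])
        atac = np.array([[0.0, 0.0]])
        batch = encode_cells(rna, atac)
        assert list(batch.gene_indices[0]) == [1, 3]
        assert np.allclose(batch.gene_values[0], [1.2, 3.4])
        assert batch.peak_indices[0].size == 0

    def test_round_trip_and_frobenius(self):
        rng = np.random.default_rng(5)
        rna = rng.poisson(1.0, size=(6, 9)).astype(float)
        atac = rng.poisson(0.5, size=(6, 7)).astype(float)
        batch = encode_cells(rna, atac)
        assert np.array_equal(batch.to_dense("RNA"), rna)
        assert np.array_equal(batch.to_dense("ATAC"), atac)
        assert np.isclose(np.linalg.norm(batch.to_dense("RNA")), np.linalg.norm(rna))

    def test_invalid_indices_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            EncodedCellBatch([np.array([5])], [np.array([1.0])],
                             [np.array([0])], [np.array([1.0])], 3, 2)


class TestMtxIO:
    def test_round_trip_identity(self, tmp_path):
        ds = _toy_dataset()
        write_mtx_dataset(ds, tmp_path / "rna", tmp_path / "atac",
                          tmp_path / "genes.tsv", tmp_path / "peaks.bed",
                          tmp_path / "cells.tsv")
        back = read_mtx_dataset(tmp_path / "rna", tmp_path / "atac",
                                tmp_path / "genes.tsv", tmp_path / "peaks.bed",
                                tmp_path / "cells.tsv")
        assert back.n_cells == ds.n_cells
        assert np.array_equal(back.rna_counts.toarray(), ds.rna_counts.toarray())
        assert np.array_equal(back.atac_counts.toarray(), ds.atac_counts.toarray())
        assert [g.gene_id for g in back.genes] == [g.gene_id for g in ds.genes]

    def test_barcode_intersection_with_warning(self, tmp_path):
        ds = _toy_dataset(3)
        write_mtx_dataset(ds, tmp_path / "rna", tmp_path / "atac",
                          tmp_path / "genes.tsv", tmp_path / "peaks.bed",
                          tmp_path / "cells.tsv")
        # rewrite ATAC barcodes as {bc1, bc2, bc9}: intersection {bc1, bc2}
        (tmp_path / "atac" / "barcodes.tsv").write_text("bc1\nbc2\nbc9\n")
        with pytest.warns(UserWarning, match="barcode mismatch"):
            back = read_mtx_dataset(tmp_path / "rna", tmp_path / "atac",
                                    tmp_path / "genes.tsv", tmp_path / "peaks.bed",
                                    tmp_path / "cells.tsv")
        assert [c.barcode for c in back.cells] == ["bc1", "bc2"]

    def test_non_integral_counts_rejected(self):
        with pytest.raises(ValueError, match="non-integral"):
            MultiomeDataset(sp.csr_matrix(np.array([[1.5]])),
                            sp.csr_matrix(np.array([[1.0]])),
                            [GeneAnnotation("g", "g", "chr1", 0, "+")],
                            [PeakInterval("chr1", 0, 10)],
                            [CellMeta("b")])


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(rna=arrays(np.float64, (5, 7),
                      elements=st.floats(0, 50, allow_nan=False)),
           atac=arrays(np.float64, (5, 4),
                       elements=st.floats(0, 50, allow_nan=False)))
    def test_sparse_encoding_round_trip_property(rna, atac):
        """decode(encode(x)) == x and the Frobenius norm is preserved for
        arbitrary nonnegative matrices."""
        batch = encode_cells(rna, atac)
        assert np.array_equal(batch.to_dense("RNA"), rna)
        assert np.array_equal(batch.to_dense("ATAC"), atac)
        assert np.isclose(np.linalg.norm(batch.to_dense("ATAC")),
                          np.linalg.norm(atac))
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def test_preprocess_pipeline_and_hdf5_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    n, g, p = 30, 12, 15
    rna = rng.poisson(2.0, size=(n, g))
    atac = rng.poisson(1.0, size=(n, p))
    genes = [GeneAnnotation(f"g{i}", f"g{i}", "chrX" if i == 0 else "chr1",
                            1000 * i + 1, "+") for i in range(g)]
    peaks = [PeakInterval("chr1", 100 * i, 100 * i + 50) for i in range(p)]
    cells = [CellMeta(f"b{i}", cell_type="t0", pseudotime=float(i)) for i in range(n)]
    ds = MultiomeDataset(sp.csr_matrix(rna), sp.csr_matrix(atac), genes, peaks, cells)
    proc = preprocess(ds, min_cell_frac=0.05, n_top_hvg=None)
    assert all(gn.chrom != "chrX" for gn in proc.genes)
    # second normalization pre-log is a no-op at the matrix-sum level
    renorm = np.expm1(proc.rna_norm)
    assert np.allclose(renorm.sum(axis=1), 10_000.0)
    save_processed(proc, tmp_path / "proc.h5")
    back = load_processed(tmp_path / "proc.h5")
    assert np.allclose(back.rna_norm, proc.rna_norm)
    assert np.allclose(back.atac_norm, proc.atac_norm)
    assert [c.barcode for c in back.cells] == [c.barcode for c in proc.cells]
    assert back.cells[3].pseudotime == proc.cells[3].pseudotime
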