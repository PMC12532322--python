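"""Integration and prediction metric correctness."""

import numpy as np
import pytest

from attune.metrics import (composite_scores, foscttm, graph_connectivity,
                            mean_average_precision, neighbor_consistency,
                            prediction_metrics, seurat_alignment_score,
                            silhouette_scores)


def _two_clusters(rng, n_per=40, sep=50.0, d=4):
    a = rng.normal(size=(n_per, d))
    b = rng.normal(size=(n_per, d)) + sep
    z = np.vstack([a, b])
    types = np.array(["A"] * n_per + ["B"] * n_per)
    return z, types


class TestFoscttm:
    def test_identical_embeddings_zero(self):
        z = np.random.default_rng(0).normal(size=(10, 3))
        assert foscttm(z, z) == 0.0

    def test_adversarial_swap_is_one(self):
        z_a = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert foscttm(z_a, z_a[::-1]) == 1.0

    def test_random_embeddings_near_half(self):
        rng = np.random.default_rng(1)
        n = 200
        val = foscttm(rng.normal(size=(n, 8)), rng.normal(size=(n, 8)))
        se = 0.5 / np.sqrt(n)
        assert abs(val - 0.5) < 3 * se

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(20, 4)), rng.normal(size=(20, 4))
        assert foscttm(a, b) == pytest.approx(foscttm(b, a))


class TestMAP:
    def test_separated_clusters_perfect(self):
        z, types = _two_clusters(np.random.default_rng(3))
        assert mean_average_precision(z, types, k=10) == 1.0

    def test_permuted_labels_near_type_frequency(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(300, 5))
        types = np.array(["A"] * 150 + ["B"] * 150)
        val = mean_average_precision(z, rng.permutation(types), k=30)
        assert abs(val - 0.5) < 0.1

    def test_k_one_is_nearest_neighbor_accuracy(self):
        z = np.array([[0.0], [0.1], [10.0], [10.1]])
        types = np.array(["A", "A", "B", "B"])
        assert mean_average_precision(z, types, k=1) == 1.0
        types_bad = np.array(["A", "B", "A", "B"])
        assert mean_average_precision(z, types_bad, k=1) == 0.0


class TestSilhouettes:
    def test_tight_types_mixed_modalities(self):
        rng = np.random.default_rng(5)
        z, types = _two_clusters(rng, sep=100.0)
        mods = np.tile(["RNA", "ATAC"], 40)
        ct, batch = silhouette_scores(z, types, mods)
        assert ct > 0.9 and batch > 0.9

    def test_separated_modalities_low_batch_score(self):
        rng = np.random.default_rng(6)
        n = 40
        z = np.vstack([rng.normal(size=(n, 3)), rng.normal(size=(n, 3)) + 100.0])
        types = np.array(["A"] * (2 * n))
        types[::2] = "B"                      # both types in both blobs
        mods = np.array(["RNA"] * n + ["ATAC"] * n)
        _, batch = silhouette_scores(z, types, mods)
        assert batch < 0.1

    def test_outputs_in_unit_interval(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(60, 4))
        types = np.array(["A", "B", "C"] * 20)
        mods = np.array(["RNA", "ATAC"] * 30)
        ct, batch = silhouette_scores(z, types, mods)
        assert 0.0 <= ct <= 1.0 and 0.0 <= batch <= 1.0


class TestNeighborConsistency:
    def test_identical_embeddings_one(self):
        z = np.random.default_rng(8).normal(size=(50, 4))
        assert neighbor_consistency(z, z, k=10) == 1.0

    def test_independent_randoms_near_chance(self):
        rng = np.random.default_rng(9)
        n, k = 400, 30
        val = neighbor_consistency(rng.normal(size=(n, 6)),
                                   rng.normal(size=(n, 6)), k=k)
        # expected overlap ~ k/(n-1); Jaccard of two k-sets with that overlap
        exp_inter = k * k / (n - 1)
        expected = exp_inter / (2 * k - exp_inter)
        assert abs(val - expected) < 0.05

    def test_k_too_large_rejected(self):
        z = np.zeros((5, 2))
        with pytest.raises(ValueError):
            neighbor_consistency(z, z, k=5)


class TestSAS:
    def test_interleaved_modalities_near_one(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=(200, 4))
        mods = np.tile(["RNA", "ATAC"], 100)
        assert seurat_alignment_score(z, mods, k=15) > 0.85

    def test_separated_modalities_near_zero(self):
        rng = np.random.default_rng(11)
        z = np.vstack([rng.normal(size=(100, 4)), rng.normal(size=(100, 4)) + 100.0])
        mods = np.array(["RNA"] * 100 + ["ATAC"] * 100)
        assert seurat_alignment_score(z, mods, k=15) < 0.05

    def test_clipped_to_unit_interval(self):
        rng = np.random.default_rng(12)
        for trial in range(5):
            z = rng.normal(size=(40, 3))
            mods = rng.choice(["RNA", "ATAC"], size=40)
            if len(np.unique(mods)) < 2:
                continue
            assert 0.0 <= seurat_alignment_score(z, mods, k=5, seed=trial) <= 1.0


class TestGraphConnectivity:
    def test_tight_clusters_fully_connected(self):
        z, types = _two_clusters(np.random.default_rng(13))
        assert graph_connectivity(z, types, k=10) == 1.0

    def test_split_type_gives_half(self):
        rng = np.random.default_rng(14)
        islands = np.vstack([rng.normal(size=(20, 3)),
                             rng.normal(size=(20, 3)) + 1000.0])
        types = np.array(["A"] * 40)
        assert graph_connectivity(islands, types, k=3) == pytest.approx(0.5)

    def test_bounded(self):
        rng = np.random.default_rng(15)
        z = rng.normal(size=(50, 4))
        types = rng.choice(["A", "B"], size=50)
        assert 0.0 <= graph_connectivity(z, types, k=5) <= 1.0


class TestComposites:
    COMPONENTS = dict(map=0.5, cell_type_asw=0.5, nc=0.5,
                      sas=1.0, batch_asw=1.0, gc=1.0)

    def test_weighted_average(self):
        bio, omics, overall = composite_scores(self.COMPONENTS)
        assert bio == 0.5 and omics == 1.0
        assert overall == pytest.approx(0.7)

    def test_all_ones_give_one(self):
        comp = {k: 1.0 for k in self.COMPONENTS}
        assert composite_scores(comp)[2] == pytest.approx(1.0)

    def test_peer_min_max_scaling(self):
        peers = {k: [0.2, 0.5, 0.8] for k in self.COMPONENTS}
        comp = {k: 0.8 for k in self.COMPONENTS}
        bio, omics, overall = composite_scores(comp, peer_values=peers)
        assert bio == omics == overall == pytest.approx(1.0)

    def test_overall_responds_linearly_to_bio(self):
        c1 = dict(self.COMPONENTS)
        c2 = dict(self.COMPONENTS, map=self.COMPONENTS["map"] + 0.3,
                  cell_type_asw=self.COMPONENTS["cell_type_asw"] + 0.3,
                  nc=self.COMPONENTS["nc"] + 0.3)
        d_overall = composite_scores(c2)[2] - composite_scores(c1)[2]
        assert d_overall / 0.3 == pytest.approx(0.6)

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            composite_scores({"map": 1.0})


class TestPredictionMetrics:
    def test_perfect_prediction(self):
        x = np.random.default_rng(16).normal(size=(20, 5))
        rmse, pear, spear = prediction_metrics(x, x)
        assert rmse == 0.0 and pear == pytest.approx(1.0) and spear == pytest.approx(1.0)

    def test_negated_prediction(self):
        x = np.random.default_rng(17).normal(size=(20, 5))
        _, pear, _ = prediction_metrics(-x, x)
        assert pear == pytest.approx(-1.0)

    def test_constant_shift_rmse(self):
        x = np.random.default_rng(18).normal(size=(10, 4))
        rmse, _, _ = prediction_metrics(x + 2.5, x)
        assert rmse == pytest.approx(2.5)

    def test_constant_genes_excluded_with_warning(self):
        x = np.random.default_rng(19).normal(size=(10, 3))
        x_const = x.copy()
        x_const[:, 0] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            _, pear, _ = prediction_metrics(x_const, x_const)
        assert pear == pytest.approx(1.0)


def test_bounded_metrics_on_random_draws():
    rng = np.random.default_rng(20)
    for _ in range(50):
        n = rng.integers(20, 60)
        z_a = rng.normal(size=(n, 4))
        z_b = rng.normal(size=(n, 4))
        types = rng.choice(["A", "B"], size=2 * n)
        if len(np.unique(types)) < 2:
            continue
        z = np.vstack([z_a, z_b])
        mods = np.array(["RNA"] * n + ["ATAC"] * n)
        k = int(min(10, n - 1))
        vals = [foscttm(z_a, z_b),
                mean_average_precision(z, types, k=k),
                *silhouette_scores(z, types, mods),
                neighbor_consistency(z_a, z_b, k=k),
                seurat_alignment_score(z, mods, k=k),
                graph_connectivity(z, types, k=k)]
        assert all(0.0 <= v <= 1.0 for v in vals)
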