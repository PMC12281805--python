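"""QSAR landscape roughness and modelability indices."""

import math

import numpy as np
import pytest
from scipy import stats

from topolearn import (
    FeatureMatrix,
    LabeledDataset,
    SyntheticSpec,
    make_landscape,
    make_point_cloud,
    pairwise_distances,
    rmodi,
    rogi,
    sali,
    sari,
    sari_batch,
)
from topolearn.modelability import _sari_raw


def toy_dataset(labels, coords=None):
    n = len(labels)
    coords = np.arange(n, dtype=float)[:, None] if coords is None else coords
    return LabeledDataset(FeatureMatrix(coords), np.asarray(labels, float))


class TestSali:
    def test_formula_arithmetic(self):
        data = toy_dataset([5.0, 3.0])
        sim = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = sali(data, sim)
        assert out.sali_max == pytest.approx(4.0)

    def test_identical_activities_zero(self):
        data = toy_dataset([2.0, 2.0, 2.0])
        sim = np.full((3, 3), 0.4)
        np.fill_diagonal(sim, 1.0)
        out = sali(data, sim)
        assert out.sali_max == pytest.approx(0.0)

    def test_duplicate_pair_masked_and_counted(self, caplog):
        data = toy_dataset([1.0, 2.0, 3.0])
        sim = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.3], [0.2, 0.3, 1.0]])
        with caplog.at_level("WARNING"):
            out = sali(data, sim)
        assert out.masked_pairs == 1
        assert math.isnan(out.sali_matrix[0, 1])
        assert not math.isnan(out.sali_matrix[0, 2])

    def test_all_masked_gives_missing_summary(self):
        data = toy_dataset([1.0, 2.0])
        out = sali(data, np.ones((2, 2)))
        assert math.isnan(out.sali_mean)
        assert out.masked_pairs == 1


class TestSari:
    def test_three_molecule_toy_matches_bruteforce(self):
        labels = np.array([1.0, 2.0, 5.0])
        sim = np.array([[1.0, 0.8, 0.3], [0.8, 1.0, 0.5], [0.3, 0.5, 1.0]])
        data = toy_dataset(labels)
        # independent recomputation of the documented formulas
        pairs = [(0, 1), (0, 2), (1, 2)]
        lo = [(i, j) for i, j in pairs if sim[i, j] < 0.65]
        hi = [(i, j) for i, j in pairs if sim[i, j] >= 0.65]
        w = {p: abs(labels[p[0]] - labels[p[1]]) for p in pairs}
        cont = sum(w[p] * sim[p] for p in lo) / sum(w[p] for p in lo)
        disc = np.mean([w[p] for p in hi])
        raw = _sari_raw(data, sim, 0.65)
        assert raw[0] == pytest.approx(cont, abs=1e-12)
        assert raw[1] == pytest.approx(disc, abs=1e-12)
        # single-dataset fallback normalization: disc / label range
        expected = 0.5 * (cont + (1.0 - disc / np.ptp(labels)))
        assert sari(data, sim) == pytest.approx(expected, abs=1e-12)

    def test_output_in_unit_interval(self, rng):
        for _ in range(5):
            n = 12
            coords = rng.random((n, 2))
            data = LabeledDataset(FeatureMatrix(coords), rng.normal(size=n))
            assert 0.0 <= sari(data) <= 1.0

    def test_smooth_scores_above_cliff_landscape(self):
        for seed in range(5):
            cloud = make_point_cloud(
                SyntheticSpec(shape="hypercube", n=120, dim=2, seed=seed)
            )
            smooth = make_landscape(cloud, 0.0, seed=seed)
            cliffy = make_landscape(cloud, 0.5, seed=seed)
            s = sari_batch([smooth, cliffy])
            assert s[0] > s[1]


class TestRmodi:
    def test_all_neighbors_similar_gives_one(self):
        data = toy_dataset([0.0, 0.01, 0.02, 0.03, 1.0])
        # only the far point (distance 1 in coords, label jump 0.97) is a cliff
        coords = np.array([[0.0], [0.1], [0.2], [0.3], [10.0]])
        data = toy_dataset([0.0, 0.01, 0.02, 0.03, 1.0], coords)
        assert rmodi(data) == pytest.approx(0.8)

    def test_smooth_chain_is_one(self):
        # 20 evenly spaced labels: every NN gap is range/19 < 0.1 * range
        data = toy_dataset(np.linspace(0, 0.5, 20))
        assert rmodi(data) == 1.0

    def test_alternating_cliffs_zero(self):
        data = toy_dataset([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        assert rmodi(data) == 0.0

    def test_constant_labels_defined_as_one(self, caplog):
        data = toy_dataset([2.0] * 5)
        with caplog.at_level("WARNING"):
            assert rmodi(data) == 1.0

    def test_half_planted_cliffs_near_half(self):
        for seed in range(3):
            cloud = make_point_cloud(
                SyntheticSpec(shape="hypercube", n=400, dim=2, seed=seed)
            )
            data = make_landscape(cloud, 0.5, seed=seed)
            # brute-force expectation: NN pairs in the same cliff class are smooth
            assert rmodi(data) == pytest.approx(0.5, abs=0.05)


class TestRogi:
    def test_constant_labels_zero(self):
        data = toy_dataset([3.0] * 8)
        assert rogi(data) == 0.0
        assert rogi(data, variant="xd") == 0.0

    def test_two_tight_clusters_hand_computed(self):
        # two clusters of 3, within-distance ~0, between-distance 1:
        # sigma(t) stays 0.5 until the final merge at t = 1, so only the
        # last trapezoid (width 0.02, height 2 * 0.5 at t = 1) contributes.
        coords = np.array([[0.0], [1e-4], [2e-4], [1.0], [1.0 + 1e-4], [1.0 + 2e-4]])
        data = toy_dataset([0.0, 0.0, 0.0, 1.0, 1.0, 1.0], coords)
        expected = 0.02 * (0.0 + 2 * 0.5) / 2.0
        assert rogi(data, n_thresholds=51) == pytest.approx(expected, rel=1e-6)

    def test_label_noise_increases_rogi(self):
        for seed in range(5):
            cloud = make_point_cloud(
                SyntheticSpec(shape="hypercube", n=150, dim=2, seed=seed)
            )
            rng = np.random.default_rng(seed)
            base = make_landscape(cloud, 0.0, seed=seed)
            vals = []
            for noise in (0.0, 0.3, 0.8):
                noisy = LabeledDataset(
                    cloud, base.labels + rng.normal(0, noise, cloud.n)
                )
                vals.append(rogi(noisy))
            assert vals[0] < vals[1] < vals[2]


class TestOrderingAcrossRoughness:
    def test_indices_track_planted_cliff_fraction(self):
        fractions = np.linspace(0.0, 0.95, 20)
        cloud = make_point_cloud(SyntheticSpec(shape="hypercube", n=150, dim=2, seed=9))
        rogis, rmodis = [], []
        for k, f in enumerate(fractions):
            data = make_landscape(cloud, float(f), seed=9)
            rogis.append(rogi(data))
            rmodis.append(rmodi(data))
        # planted-cliff fraction beyond 0.5 makes the cliff layer the
        # majority; roughness as seen by NN indices peaks near 0.5
        half = fractions <= 0.5
        assert stats.spearmanr(fractions[half], np.array(rogis)[half]).statistic > 0.8
        assert stats.spearmanr(fractions[half], np.array(rmodis)[half]).statistic < -0.8

    def test_reordering_invariance(self, rng, smooth_landscape):
        perm = rng.permutation(smooth_landscape.n)
        permuted = smooth_landscape.subset(perm)
        assert rogi(permuted) == pytest.approx(rogi(smooth_landscape), rel=1e-9)
        assert rmodi(permuted) == pytest.approx(rmodi(smooth_landscape), rel=1e-9)
        assert sari(permuted) == pytest.approx(sari(smooth_landscape), rel=1e-9)
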