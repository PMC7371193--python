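"""GEO features, composite descriptors, weighted distance, weight fitting
and retrieval metrics."""

import numpy as np
import pytest

from zershape.canterakis import random_rotation, rotation_matrix
from zershape.descriptors import (
    BioZernikeDescriptor,
    DescriptorConfig,
    DistanceWeights,
    GeoDescriptor,
    biozernike_descriptor,
    descriptor_distance,
    fit_weights,
    geo_descriptor,
    make_pairs,
    pair_features,
    retrieval_metrics,
)
from zershape.structure import RepresentativeAtomSet


class TestGeoDescriptor:
    def test_points_on_sphere_have_degenerate_distance_distribution(self):
        # antipodal pairs: centroid exactly 0, every point at radius r
        rng = np.random.default_rng(0)
        v = rng.normal(size=(100, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = 9.0
        pts = np.concatenate([v, -v]) * r
        atoms = RepresentativeAtomSet(pts, np.ones(200))
        g = geo_descriptor(atoms)
        d = g.as_dict()
        for p in range(10, 100, 10):
            assert d[f"dist_p{p}"] == pytest.approx(r, rel=1e-6)
        assert d["dist_std"] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance_machine_precision(self, blob_atoms):
        rng = np.random.default_rng(1)
        R = rotation_matrix(random_rotation(rng))
        moved = blob_atoms.transformed(rotation=R, translation=[13.0, -4.0, 99.0])
        g0 = geo_descriptor(blob_atoms).values
        g1 = geo_descriptor(moved).values
        np.testing.assert_allclose(g1, g0, rtol=1e-9, atol=1e-9)

    def test_percentiles_match_sort_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(200, 3)) * 5
        atoms = RepresentativeAtomSet(pts, np.ones(200))
        g = geo_descriptor(atoms)
        com = pts.mean(axis=0)
        dists = np.sort(np.linalg.norm(pts - com, axis=1))
        # linear-interpolation percentile on sorted order statistics
        for k, p in enumerate(range(10, 100, 10)):
            pos = (len(dists) - 1) * p / 100
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expected = dists[lo] + (pos - lo) * (dists[hi] - dists[lo])
            assert g.values[3 + k] == pytest.approx(expected)

    def test_percentiles_non_decreasing(self, blob_atoms):
        g = geo_descriptor(blob_atoms).values
        assert np.all(np.diff(g[3:12]) >= 0)

    def test_length_and_validation(self):
        with pytest.raises(ValueError):
            GeoDescriptor(np.zeros(16))
        with pytest.raises(ValueError):
            geo_descriptor(RepresentativeAtomSet([[0, 0, 0]], [1.0]))


class TestBioZernikeDescriptor:
    def test_component_lengths(self, helix_atoms):
        desc = biozernike_descriptor(helix_atoms, DescriptorConfig(grid_width=0.5))
        assert len(desc.cn) == 3784
        assert desc.geo.values.shape == (17,)
        assert desc.dzd.shape == (121,)

    def test_bitwise_determinism(self, helix_atoms):
        cfg = DescriptorConfig(grid_width=0.5)
        d1 = biozernike_descriptor(helix_atoms, cfg)
        d2 = biozernike_descriptor(helix_atoms, cfg)
        np.testing.assert_array_equal(d1.cn, d2.cn)
        np.testing.assert_array_equal(d1.geo.values, d2.geo.values)


class TestDescriptorDistance:
    @staticmethod
    def _toy(geo, cn):
        return BioZernikeDescriptor(GeoDescriptor(np.array(geo)), np.array(cn))

    def test_zero_on_identical(self):
        g = np.arange(17.0)
        d = self._toy(g, [1.0, 2.0])
        w = DistanceWeights(np.ones(17), np.ones(2))
        assert descriptor_distance(d, d, w) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        d1 = self._toy(rng.normal(size=17), rng.normal(size=5))
        d2 = self._toy(rng.normal(size=17), rng.normal(size=5))
        w = DistanceWeights(rng.uniform(0, 2, 17), rng.uniform(0, 2, 5))
        assert descriptor_distance(d1, d2, w) == pytest.approx(
            descriptor_distance(d2, d1, w))

    def test_two_component_hand_computation(self):
        geo1 = np.zeros(17); geo1[0] = 1.0
        geo2 = np.zeros(17); geo2[0] = -2.0
        d1 = self._toy(geo1, [3.0])
        d2 = self._toy(geo2, [5.0])
        w = DistanceWeights(np.full(17, 2.0), np.array([0.5]))
        # geo term: 2^2 * |1 - (-2)| / (1 + 1 + 2) = 3; other 16 features: 0
        # cn term: 0.5 * |3 - 5| = 1
        assert descriptor_distance(d1, d2, w) == pytest.approx(4.0)

    def test_weights_enter_squared_vs_linear(self):
        geo1 = np.zeros(17); geo2 = np.zeros(17); geo2[0] = 1.0
        d1 = self._toy(geo1, [0.0]); d2 = self._toy(geo2, [1.0])
        w3 = DistanceWeights(np.full(17, 3.0), np.array([3.0]))
        w1 = DistanceWeights(np.ones(17), np.ones(1))
        base_geo = descriptor_distance(d1, d2, DistanceWeights(np.ones(17), np.zeros(1)))
        base_cn = descriptor_distance(d1, d2, DistanceWeights(np.zeros(17), np.ones(1)))
        assert descriptor_distance(d1, d2, w3) == pytest.approx(
            9 * base_geo + 3 * base_cn)
        assert descriptor_distance(d1, d2, w1) == pytest.approx(base_geo + base_cn)

    def test_length_mismatch_rejected(self):
        d1 = self._toy(np.zeros(17), [1.0, 2.0])
        d2 = self._toy(np.zeros(17), [1.0])
        with pytest.raises(ValueError):
            descriptor_distance(d1, d2, DistanceWeights(np.ones(17), np.ones(2)))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            DistanceWeights(-np.ones(17), np.ones(3))


class TestFitWeights:
    @staticmethod
    def _planted(n_classes=8, n_members=6, n_noise=30, seed=0):
        """Pairs where exactly one moment component separates classes."""
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-50, 50, n_classes)
        feats, labels = [], []
        for c in range(n_classes):
            for _ in range(n_members):
                cn = np.concatenate([
                    [centers[c] + rng.normal(scale=0.2)],
                    rng.normal(size=n_noise),  # pure noise components
                ])
                feats.append(cn)
                labels.append(c)
        feats = np.array(feats); labels = np.array(labels)
        i, j, same = make_pairs(labels)
        X = np.abs(feats[i] - feats[j])
        return X, same, labels[i]

    def test_planted_component_recovered_sparse(self):
        X, same, groups = self._planted()
        w = fit_weights(X, same, groups, n_geo=0, seed=0)
        assert w.wm[0] > 0
        others = w.wm[1:]
        # non-negativity constraint yields a sparse solution: the planted
        # component dominates and most noise weights vanish
        assert w.wm[0] > 10 * np.median(others + 1e-12)
        assert np.mean(others < 1e-3 * w.wm[0]) > 0.5

    def test_single_class_rejected(self):
        X = np.abs(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            fit_weights(X, np.ones(10, dtype=bool), np.zeros(10), n_geo=0)

    def test_deterministic_under_pair_permutation(self):
        X, same, groups = self._planted(seed=5)
        w1 = fit_weights(X, same, groups, n_geo=0, seed=1)
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(same))
        w2 = fit_weights(X[perm], same[perm], groups[perm], n_geo=0, seed=1)
        np.testing.assert_allclose(w1.wm, w2.wm, atol=1e-5 * (1 + w1.wm.max()))


class TestRetrievalMetrics:
    def test_perfect_separation(self):
        d = np.array([0.1, 0.2, 0.3, 5.0, 6.0, 7.0])
        y = np.array([True, True, True, False, False, False])
        m = retrieval_metrics(d, y)
        assert m["roc_auc"] == 1.0
        assert m["max_mcc"] == pytest.approx(1.0)
        assert m["pr_auc"] == pytest.approx(1.0)

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(size=4000)
        y = rng.uniform(size=4000) < 0.5
        assert retrieval_metrics(d, y)["roc_auc"] == pytest.approx(0.5, abs=0.05)

    def test_six_point_example_matches_threshold_enumeration(self):
        d = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        y = np.array([True, False, True, False, False, True])
        m = retrieval_metrics(d, y)
        # brute-force ROC AUC over all positive/negative pairs
        pos, neg = d[y], d[~y]
        wins = sum((p < n) + 0.5 * (p == n) for p in pos for n in neg)
        assert m["roc_auc"] == pytest.approx(wins / (len(pos) * len(neg)))
        # brute-force max MCC over thresholds
        best = -1.0
        for t in np.unique(d):
            pred = d <= t
            tp = np.sum(pred & y); fp = np.sum(pred & ~y)
            fn = np.sum(~pred & y); tn = np.sum(~pred & ~y)
            den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
            if den > 0:
                best = max(best, (tp * tn - fp * fn) / den)
        assert m["max_mcc"] == pytest.approx(best)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            retrieval_metrics(np.array([1.0, 2.0]), np.array([True, True]))


class TestMakePairs:
    def test_500_classes_of_5_match_bookkeeping(self):
        labels = np.repeat(np.arange(500), 5)
        i, j, same = make_pairs(labels)
        assert int(same.sum()) == 5000
        assert int((~same).sum()) == 3118750

    def test_single_class_of_three(self):
        i, j, same = make_pairs(np.zeros(3))
        assert int(same.sum()) == 3
        assert int((~same).sum()) == 0

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            make_pairs(np.array([1]))
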