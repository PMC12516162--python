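"""Voxel features, logistic proposal classifier, and liberal thresholding."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import rimvein as rv
from rimvein.proposal import threshold_candidates

from conftest import ellipsoid_volume


class TestFeatures:
    def test_zero_volume_gives_zero_features(self):
        volume = ellipsoid_volume(fill=0.0)
        feats = rv.extract_voxel_features(volume)
        assert np.all(feats.features == 0)

    def test_zero_sigma_reproduces_raw(self):
        volume = ellipsoid_volume(seed=3)
        feats = rv.extract_voxel_features(volume, scales=(0.0,))
        names = list(feats.feature_names)
        for contrast in ("t1w", "flair", "epim", "epip"):
            raw = feats.features[:, names.index(f"{contrast}_raw")]
            smooth = feats.features[:, names.index(f"{contrast}_smooth0")]
            np.testing.assert_array_equal(raw, smooth)

    def test_product_feature(self):
        volume = ellipsoid_volume(fill=0.0)
        volume.t1w[:] = -1.0
        volume.flair[:] = 2.0
        feats = rv.extract_voxel_features(volume)
        col = list(feats.feature_names).index("t1w_x_flair")
        assert np.all(feats.features[:, col] == -2.0)


class TestClassifier:
    def test_separable_features_reach_perfect_accuracy(self, phantom_pair):
        volume, truth = phantom_pair
        feats = rv.extract_voxel_features(rv.z_normalize(volume))
        clf = rv.fit_voxel_classifier(feats, truth.lesion_label_grid, seed=0)
        pmap = rv.predict_probability_map(clf, feats)
        y = (truth.lesion_label_grid > 0)[volume.brain_mask]
        pred = pmap.values[volume.brain_mask] >= 0.5
        assert (pred == y).mean() > 0.98

    def test_refit_is_deterministic(self, phantom_pair):
        volume, truth = phantom_pair
        feats = rv.extract_voxel_features(rv.z_normalize(volume))
        c1 = rv.fit_voxel_classifier(feats, truth.lesion_label_grid, seed=0)
        c2 = rv.fit_voxel_classifier(feats, truth.lesion_label_grid, seed=0)
        np.testing.assert_array_equal(c1.coefficients, c2.coefficients)

    def test_uninformative_labels_give_chance_auroc(self):
        """Labels independent of the intensities: held-out AUROC ~ 0.5."""
        train = ellipsoid_volume(shape=(32, 32, 32), seed=10)
        test = ellipsoid_volume(shape=(32, 32, 32), seed=11)
        rng = np.random.default_rng(0)
        random_truth = (rng.random(train.brain_mask.shape) < 0.3) & train.brain_mask
        clf = rv.fit_voxel_classifier(rv.extract_voxel_features(train),
                                      random_truth.astype(int), seed=0)
        pmap = rv.predict_probability_map(clf, rv.extract_voxel_features(test))
        y = ((rng.random(test.brain_mask.shape) < 0.3) & test.brain_mask)[test.brain_mask]
        roc = rv.roc_and_youden(pmap.values[test.brain_mask], y.astype(int))
        assert roc.auroc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        volume = ellipsoid_volume(seed=3)
        feats = rv.extract_voxel_features(volume)
        with pytest.raises(ValueError):
            rv.fit_voxel_classifier(feats, np.zeros(volume.shape, int))

    def test_feature_name_mismatch_rejected(self, phantom_pair):
        volume, truth = phantom_pair
        feats = rv.extract_voxel_features(rv.z_normalize(volume))
        clf = rv.fit_voxel_classifier(feats, truth.lesion_label_grid, seed=0)
        other = rv.extract_voxel_features(rv.z_normalize(volume), scales=(1.5,))
        with pytest.raises(ValueError):
            rv.predict_probability_map(clf, other)

    def test_zero_coefficients_give_half(self, phantom_pair):
        volume, truth = phantom_pair
        feats = rv.extract_voxel_features(rv.z_normalize(volume))
        clf = rv.fit_voxel_classifier(feats, truth.lesion_label_grid, seed=0)
        clf.model.coef_[:] = 0.0
        clf.model.intercept_[:] = 0.0
        pmap = rv.predict_probability_map(clf, feats)
        assert np.all(pmap.values[volume.brain_mask] == 0.5)


class TestThreshold:
    def _pmap(self, values, mask=None):
        mask = np.ones(values.shape, bool) if mask is None else mask
        return rv.ProbabilityMap(values=values.astype(np.float32), brain_mask=mask)

    def test_all_below_threshold_empty(self):
        pmap = self._pmap(np.full((8, 8, 8), 0.04))
        mask, labels, n = threshold_candidates(pmap, 0.05, min_size=1)
        assert n == 0 and not mask.any()

    def test_two_blobs_two_components(self):
        values = np.zeros((16, 16, 16))
        values[2:5, 2:5, 2:5] = 0.9
        values[10:13, 10:13, 10:13] = 0.9
        _, labels, n = threshold_candidates(self._pmap(values), 0.05)
        assert n == 2

    def test_component_count_matches_flood_fill_oracle(self, rng):
        values = (rng.random((16, 16, 16)) > 0.7).astype(float) * 0.5
        _, labels, n = threshold_candidates(self._pmap(values), 0.05, min_size=1)
        struct = ndimage.generate_binary_structure(3, 3)
        _, n_oracle = ndimage.label(values >= 0.05, structure=struct)
        # oracle: independent flood fill over the same 26-neighbourhood
        assert n == _flood_fill_count(values >= 0.05)
        assert n == n_oracle

    def test_mask_monotone_in_threshold(self, rng):
        values = rng.random((12, 12, 12))
        pmap = self._pmap(values)
        lo, _, _ = threshold_candidates(pmap, 0.2, min_size=1)
        hi, _, _ = threshold_candidates(pmap, 0.6, min_size=1)
        assert np.all(lo[hi])  # hi-threshold mask is a subset

    def test_min_size_drops_small_components(self):
        values = np.zeros((10, 10, 10))
        values[1, 1, 1] = 0.9            # single voxel
        values[5:8, 5:8, 5:8] = 0.9      # 27 voxels
        _, _, n = threshold_candidates(self._pmap(values), 0.05, min_size=3)
        assert n == 1

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            threshold_candidates(self._pmap(np.zeros((4, 4, 4))), 0.0)


def _flood_fill_count(mask: np.ndarray) -> int:
    """Brute-force 26-connectivity flood fill."""
    seen = np.zeros_like(mask, bool)
    count = 0
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(p, mask.shape)) \
                        and mask[p] and not seen[p]:
                    seen[p] = True
                    stack.append(p)
    return count


def test_candidate_coverage_on_phantom(phantom_pair):
    """Nearly all true lesion centers fall inside the liberal 0.05 mask."""
    volume, truth = phantom_pair
    norm = rv.z_normalize(volume)
    feats = rv.extract_voxel_features(norm)
    clf = rv.fit_voxel_classifier(feats, truth.lesion_label_grid, seed=0)
    pmap = rv.predict_probability_map(clf, feats)
    mask, _, _ = threshold_candidates(pmap, 0.05)
    centers = np.array([r.center for r in truth.records])
    hit = mask[centers[:, 0], centers[:, 1], centers[:, 2]]
    assert hit.mean() >= 0.9
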