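"""Patch extraction, the three attention-masking rules (against a per-voxel
brute-force oracle), and the two patch-sampling distributions."""

import numpy as np
import pytest

import rimvein as rv
from rimvein.labels import LabelRecord
from rimvein.patches import (EPIM_CHANNEL, apply_attention_mask, extract_patch,
                             candidate_sampling_weight, sample_joint_candidate,
                             sample_pretrain_center)

from conftest import ellipsoid_volume


def mask_oracle(patch, crop, target):
    """Independent per-voxel implementation of the three masking rules."""
    out = patch.astype(np.float32).copy()
    s = crop.shape[0]

    def is_target(x, y, z):
        return 0 <= x < s and 0 <= y < s and 0 <= z < s and crop[x, y, z] == target

    for x in range(s):
        for y in range(s):
            for z in range(s):
                inside = crop[x, y, z] == target
                other = crop[x, y, z] > 0 and not inside
                if inside:
                    surface = not all(is_target(x + dx, y + dy, z + dz)
                                      for dx, dy, dz in
                                      [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)])
                    if not surface:
                        out[EPIM_CHANNEL, x, y, z] *= 2.0
                else:
                    out[EPIM_CHANNEL, x, y, z] = 0.0
                if other:
                    for ch in range(4):
                        if ch != EPIM_CHANNEL:
                            out[ch, x, y, z] *= 0.1
    return out


class TestExtract:
    def test_interior_crop_equals_direct_indexing(self, norm_volume):
        patch, _ = extract_patch(norm_volume, (20, 20, 20), size=16)
        direct = norm_volume.stacked()[:, 12:28, 12:28, 12:28]
        np.testing.assert_array_equal(patch, direct)

    def test_corner_crop_zero_padded(self, norm_volume):
        """At the volume corner, exactly the out-of-bounds voxels are zero."""
        patch, _ = extract_patch(norm_volume, (0, 0, 0), size=16)
        expected = np.zeros_like(patch)
        expected[:, 8:, 8:, 8:] = norm_volume.stacked()[:, :8, :8, :8]
        np.testing.assert_array_equal(patch, expected)

    def test_round_trip(self, norm_volume):
        center = (10, 25, 14)
        patch, _ = extract_patch(norm_volume, center, size=12)
        stacked = norm_volume.stacked()
        sl = tuple(slice(c - 6, c + 6) for c in center)
        np.testing.assert_array_equal(patch, stacked[(slice(None), *sl)])

    def test_center_outside_rejected(self, norm_volume):
        with pytest.raises(ValueError):
            extract_patch(norm_volume, (99, 0, 0))


class TestMaskRules:
    def _toy(self):
        patch = np.zeros((4, 8, 8, 8), np.float32)
        crop = np.zeros((8, 8, 8), np.int32)
        crop[2:5, 2:5, 2:5] = 1          # target: 3x3x3 block, one interior voxel
        crop[6:8, 6:8, 6:8] = 2          # competing candidate
        return patch, crop

    def test_epim_outside_target_zeroed(self):
        patch, crop = self._toy()
        patch[EPIM_CHANNEL, 0, 0, 0] = 1.7
        out = apply_attention_mask(patch, crop, 1).data
        assert out[EPIM_CHANNEL, 0, 0, 0] == 0.0

    def test_epim_interior_doubled(self):
        patch, crop = self._toy()
        patch[EPIM_CHANNEL, 3, 3, 3] = -0.5     # the unique interior voxel
        out = apply_attention_mask(patch, crop, 1).data
        assert out[EPIM_CHANNEL, 3, 3, 3] == -1.0

    def test_epim_surface_unchanged(self):
        patch, crop = self._toy()
        patch[EPIM_CHANNEL, 2, 2, 2] = 0.8
        out = apply_attention_mask(patch, crop, 1).data
        assert out[EPIM_CHANNEL, 2, 2, 2] == np.float32(0.8)

    def test_other_candidate_dimmed_on_flair(self):
        patch, crop = self._toy()
        flair = 1  # channel order t1w, flair, epim, epip
        patch[flair, 6, 6, 6] = 2.0
        out = apply_attention_mask(patch, crop, 1).data
        assert out[flair, 6, 6, 6] == np.float32(2.0 * 0.1)

    def test_background_context_preserved(self):
        patch, crop = self._toy()
        patch[1, 0, 0, 0] = 1.3
        out = apply_attention_mask(patch, crop, 1).data
        assert out[1, 0, 0, 0] == np.float32(1.3)

    def test_absent_target_rejected(self):
        patch, crop = self._toy()
        with pytest.raises(ValueError):
            apply_attention_mask(patch, crop, 7)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            size = 8
            patch = rng.standard_normal((4, size, size, size)).astype(np.float32)
            crop = np.zeros((size, size, size), np.int32)
            n_cand = rng.integers(1, 4)
            for cid in range(1, n_cand + 1):
                c = rng.integers(1, size - 1, 3)
                r = rng.integers(1, 3)
                sl = tuple(slice(max(0, x - r), min(size, x + r + 1)) for x in c)
                crop[sl] = cid
            present = np.unique(crop)
            present = present[present > 0]
            if len(present) == 0:
                continue
            target = int(rng.choice(present))
            out = apply_attention_mask(patch, crop, target).data
            np.testing.assert_array_equal(out, mask_oracle(patch, crop, target))

    def test_single_candidate_never_dims(self, rng):
        patch = rng.standard_normal((4, 8, 8, 8)).astype(np.float32)
        crop = np.zeros((8, 8, 8), np.int32)
        crop[2:6, 2:6, 2:6] = 1
        out = apply_attention_mask(patch, crop, 1).data
        for ch in (0, 1, 3):
            np.testing.assert_array_equal(out[ch], patch[ch])


class TestSampling:
    def test_peaked_map_dominates_draws(self):
        volume = ellipsoid_volume(shape=(16, 16, 16))
        values = np.zeros(volume.shape, np.float32)
        values[8, 8, 8] = 1.0
        pmap = rv.ProbabilityMap(values=values, brain_mask=volume.brain_mask)
        rng = np.random.default_rng(0)
        draws = sample_pretrain_center(pmap, rng, epsilon=0.01, n=5000)
        hit = (draws == [8, 8, 8]).all(axis=1).mean()
        n_mask = volume.brain_mask.sum()
        expected = (1.0 + 0.01) / (0.01 * n_mask + 1.0)
        assert hit == pytest.approx(expected, rel=0.15)
        assert hit > 20 / n_mask  # far above the uniform rate

    def test_fixed_seed_reproducible(self, norm_volume):
        values = np.full(norm_volume.shape, 0.2, np.float32)
        pmap = rv.ProbabilityMap(values=values * norm_volume.brain_mask,
                                 brain_mask=norm_volume.brain_mask)
        a = sample_pretrain_center(pmap, np.random.default_rng(7), n=50)
        b = sample_pretrain_center(pmap, np.random.default_rng(7), n=50)
        np.testing.assert_array_equal(a, b)

    def test_oversampling_ratios(self):
        fp = LabelRecord(candidate_id=1, lesion=0, prl=0, cvs=0)
        lesion = LabelRecord(candidate_id=2, lesion=1, prl=0, cvs=0)
        triple = LabelRecord(candidate_id=3, lesion=1, prl=1, cvs=1)
        assert candidate_sampling_weight(fp) == 1.0
        assert candidate_sampling_weight(lesion) == 3.0
        assert candidate_sampling_weight(triple) == 9.0
        rng = np.random.default_rng(0)
        draws = [sample_joint_candidate([fp, lesion], rng) for _ in range(8000)]
        ratio = draws.count(2) / draws.count(1)
        assert ratio == pytest.approx(3.0, rel=0.15)
        rng = np.random.default_rng(0)
        draws = [sample_joint_candidate([fp, triple], rng) for _ in range(8000)]
        ratio = draws.count(3) / draws.count(1)
        assert ratio == pytest.approx(9.0, rel=0.25)

    def test_single_candidate_always_drawn(self):
        only = LabelRecord(candidate_id=5, lesion=1, prl=0, cvs=0)
        rng = np.random.default_rng(0)
        assert all(sample_joint_candidate([only], rng) == 5 for _ in range(10))
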