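"""Augmentation, the two loss functions (closed forms + oracles), fold
splitting, and short seeded training runs."""

import dataclasses

import numpy as np
import pytest

import rimvein as rv
from rimvein.autodiff import Tensor
from rimvein.labels import MISSING, UNSURE, LabelRecord
from rimvein.network import JointModel
from rimvein.training import (AugmentParams, TrainConfig, augment_subject,
                              build_recon_weight_map, crossval_split,
                              draw_augment_params, masked_bce, pretrain,
                              train_joint, weighted_mse)


@pytest.fixture(scope="module")
def subjects():
    """Two small prepared subjects for training-loop tests."""
    spec = rv.PhantomSpec(volume_shape=(40, 40, 40), n_lesions=4, n_prl=1,
                          n_cvs=1, n_confluent_pairs=0, seed=21)
    cohort = rv.phantom_cohort(2, spec, seed=3)
    clf = rv.fit_voxel_classifier(
        [rv.extract_voxel_features(s.volume) for s in cohort],
        [s.truth.lesion_label_grid for s in cohort], seed=0)
    return [rv.prepare_subject(s, clf) for s in cohort]


TINY_TRAIN = TrainConfig(pretrain_epochs=1, joint_epochs=1, patches_per_subject=6,
                         minibatch=4, seed=0)


class TestAugment:
    def test_identity_params_return_input(self, subjects):
        aug, _ = augment_subject(subjects[0], np.random.default_rng(0),
                                 TINY_TRAIN, params=AugmentParams.identity())
        np.testing.assert_allclose(aug.volume.flair, subjects[0].volume.flair,
                                   atol=1e-4)
        np.testing.assert_array_equal(aug.candidate_map.labels,
                                      subjects[0].candidate_map.labels)

    def test_drawn_rescales_within_range(self):
        rng = np.random.default_rng(0)
        cfg = TrainConfig()
        scales = [draw_augment_params(rng, cfg).scale for _ in range(10000)]
        assert min(scales) >= 0.66 and max(scales) <= 1.5
        gammas = [draw_augment_params(rng, cfg).log_gamma for _ in range(1000)]
        assert min(gammas) >= -0.5 and max(gammas) <= 0.5

    def test_double_flip_is_identity(self, subjects):
        params = AugmentParams(flips=(True, False, True),
                               angles_deg=(0, 0, 0), scale=1.0, log_gamma=0.0)
        once, _ = augment_subject(subjects[0], np.random.default_rng(0),
                                  TINY_TRAIN, params=params)
        twice, _ = augment_subject(once, np.random.default_rng(0),
                                   TINY_TRAIN, params=params)
        np.testing.assert_allclose(twice.volume.flair, subjects[0].volume.flair,
                                   atol=1e-4)

    def test_labels_move_with_intensities(self, subjects):
        params = AugmentParams(flips=(True, False, False),
                               angles_deg=(0, 0, 0), scale=1.0, log_gamma=0.0)
        aug, _ = augment_subject(subjects[0], np.random.default_rng(0),
                                 TINY_TRAIN, params=params)
        np.testing.assert_array_equal(aug.candidate_map.labels,
                                      subjects[0].candidate_map.labels[::-1])


class TestWeightedMse:
    def test_perfect_reconstruction_zero(self, rng):
        x = rng.standard_normal((2, 4, 6, 6, 6)).astype(np.float32)
        assert weighted_mse(x.copy(), x, np.ones_like(x)).item() == 0.0

    def test_epim_upweight_ratio_exactly_four(self):
        crop = np.zeros((6, 6, 6), np.int32)
        w = build_recon_weight_map(crop)
        recon = np.zeros((4, 6, 6, 6), np.float32)
        target = np.zeros_like(recon)
        target[2, 1, 1, 1] = 0.7      # EPIm voxel error
        loss_epim = weighted_mse(recon, target, w).item()
        target2 = np.zeros_like(recon)
        target2[0, 1, 1, 1] = 0.7     # plain T1 voxel, weight 1
        loss_t1 = weighted_mse(recon, target2, w).item()
        assert loss_epim / loss_t1 == 4.0

    def test_candidate_voxels_upweighted_on_all_channels(self):
        crop = np.zeros((6, 6, 6), np.int32)
        crop[2, 2, 2] = 3
        w = build_recon_weight_map(crop)
        assert w[0, 2, 2, 2] == 4.0 and w[3, 2, 2, 2] == 4.0
        assert w[0, 0, 0, 0] == 1.0 and w[2, 0, 0, 0] == 4.0

    def test_matches_naive_loop_oracle(self, rng):
        r = rng.standard_normal((2, 3, 3, 3)).astype(np.float32)
        t = rng.standard_normal((2, 3, 3, 3)).astype(np.float32)
        w = rng.uniform(0.5, 4.0, (2, 3, 3, 3))
        num = den = 0.0
        for idx in np.ndindex(r.shape):
            num += w[idx] * (float(r[idx]) - float(t[idx])) ** 2
            den += w[idx]
        assert weighted_mse(r, t, w).item() == pytest.approx(num / den, rel=1e-12)


class TestMaskedBce:
    def test_observed_lesion_only_closed_form(self):
        label = LabelRecord(candidate_id=1, lesion=1, prl=MISSING, cvs=MISSING)
        pred = rv.CandidatePrediction(0.5, 0.9, 0.9)
        assert masked_bce(pred, label).item() == pytest.approx(np.log(2), abs=1e-12)

    def test_exact_prediction_zero_loss(self):
        label = LabelRecord(candidate_id=1, lesion=1, prl=0, cvs=1)
        pred = np.array([1.0 - 1e-13, 1e-13, 1.0 - 1e-13])
        assert masked_bce(pred, label).item() == pytest.approx(0.0, abs=1e-9)

    def test_all_missing_zero_loss_and_zero_gradients(self, tiny_net, rng):
        model = JointModel(tiny_net)
        x = Tensor(rng.standard_normal((2, 4, 24, 24, 24)).astype(np.float32))
        pred = model(x)
        labels = [LabelRecord(candidate_id=i, lesion=MISSING, prl=MISSING,
                              cvs=UNSURE) for i in range(2)]
        loss = masked_bce(pred, labels)
        assert loss.item() == 0.0
        loss.backward()
        for _, p in model.named_parameters():
            assert p.grad is None or np.abs(p.grad).max() < 1e-9

    def test_unsure_weights_zero(self):
        label = LabelRecord(candidate_id=1, lesion=1, prl=0, cvs=UNSURE)
        np.testing.assert_array_equal(label.loss_weights, [1, 1, 0])

    def test_dependency_violation_rejected(self):
        with pytest.raises(ValueError):
            LabelRecord(candidate_id=1, lesion=0, prl=1, cvs=0)


class TestCrossval:
    def test_even_folds(self):
        folds = crossval_split(list(range(20)), k=10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 2 for f in folds)

    def test_disjoint_cover(self):
        ids = [f"s{i}" for i in range(23)]
        folds = crossval_split(ids, k=10, seed=1)
        flat = [s for f in folds for s in f]
        assert sorted(flat) == sorted(ids)
        assert max(len(f) for f in folds) - min(len(f) for f in folds) <= 1

    def test_seeded_reproducibility(self):
        a = crossval_split(list(range(15)), k=5, seed=9)
        b = crossval_split(list(range(15)), k=5, seed=9)
        assert a == b

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            crossval_split([1, 2, 3], k=10)


class TestLoops:
    def test_pretrain_zero_epochs_returns_initialization(self, subjects, tiny_net):
        cfg = dataclasses.replace(TINY_TRAIN, pretrain_epochs=0)
        ae, history = pretrain(subjects, tiny_net, cfg)
        fresh = rv.Autoencoder(tiny_net, rng=np.random.default_rng([cfg.seed, 10]))
        for (_, a), (_, b) in zip(ae.named_parameters(), fresh.named_parameters()):
            np.testing.assert_array_equal(a.data, b.data)
        assert history == []

    def test_pretrain_reduces_reconstruction_loss(self, subjects, tiny_net):
        cfg = dataclasses.replace(TINY_TRAIN, pretrain_epochs=3,
                                  patches_per_subject=8)
        _, history = pretrain(subjects, tiny_net, cfg)
        assert history[-1] < history[0]

    def test_joint_training_is_seed_deterministic(self, subjects, tiny_net):
        m1, h1 = train_joint(subjects, tiny_net, TINY_TRAIN)
        m2, h2 = train_joint(subjects, tiny_net, TINY_TRAIN)
        assert h1 == h2
        for (_, a), (_, b) in zip(m1.named_parameters(), m2.named_parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_joint_training_requires_observed_labels(self, subjects, tiny_net):
        blank = []
        for s in subjects:
            labels = [LabelRecord(candidate_id=l.candidate_id, lesion=MISSING,
                                  prl=MISSING, cvs=MISSING) for l in s.labels]
            blank.append(rv.SubjectData(volume=s.volume, prob_map=s.prob_map,
                                        candidate_map=s.candidate_map,
                                        labels=labels))
        with pytest.raises(ValueError):
            train_joint(blank, tiny_net, TINY_TRAIN)
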