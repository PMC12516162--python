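"""End-to-end orchestration: phantom cohorts, candidate preparation, training
and candidate-level evaluation.

This is the programmatic counterpart of the shell pipeline (phantom ->
propose -> split -> train -> classify -> score): it builds a training and a
held-out phantom cohort, fits the voxel-wise proposal classifier on the
training subjects, prepares per-subject candidates and labels, trains the
patch network, and evaluates candidate-level AUROCs against the phantom
ground truth on the held-out subjects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import classify_all_candidates
from .labels import MISSING
from .network import JointModel, NetworkConfig
from .phantom import PhantomSpec, PhantomTruth, export_truth_table, generate_phantom
from .preprocess import MultiContrastVolume, z_normalize
from .proposal import (VoxelClassifier, extract_voxel_features,
                       fit_voxel_classifier, predict_probability_map,
                       threshold_candidates)
from .scores import assemble_candidate_labels, match_coordinates, roc_and_youden
from .split import split_all
from .training import SubjectData, TrainConfig, pretrain, train_joint

__all__ = [
    "CohortSubject",
    "Experiment",
    "phantom_cohort",
    "prepare_subject",
    "build_experiment",
    "censor_cvs_labels",
    "evaluate_model",
    "run_recovery_experiment",
]


@dataclass
class CohortSubject:
    volume: MultiContrastVolume          # z-normalized
    truth: PhantomTruth
    gold: pd.DataFrame                   # observed gold-standard table


def phantom_cohort(n_subjects: int, base_spec: PhantomSpec, seed: int,
                   id_prefix: str = "sub",
                   lesion_count_range: tuple[int, int] | None = None
                   ) -> list[CohortSubject]:
    """Generate and z-normalize ``n_subjects`` phantoms with independent
    per-subject seeds derived from ``seed``.

    With ``lesion_count_range=(lo, hi)``, each subject's lesion count is drawn
    uniformly in [lo, hi] (as lesion burden varies across people), keeping the
    base spec's PRL/CVS counts.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    out = []
    for i, s in enumerate(seeds):
        sid = f"{id_prefix}{i:03d}"
        spec = dataclasses.replace(base_spec, seed=int(s))
        if lesion_count_range is not None:
            n = int(rng.integers(lesion_count_range[0], lesion_count_range[1] + 1))
            spec = dataclasses.replace(spec, n_lesions=n)
        volume, truth = generate_phantom(spec, subject_id=sid)
        out.append(CohortSubject(volume=z_normalize(volume), truth=truth,
                                 gold=export_truth_table(truth)))
    return out


def prepare_subject(subject: CohortSubject, classifier: VoxelClassifier,
                    proposal_threshold: float = 0.05,
                    min_size: int = 3) -> SubjectData:
    """Probability map, split candidates, and candidate labels for one subject."""
    feats = extract_voxel_features(subject.volume, classifier.scales)
    pmap = predict_probability_map(classifier, feats)
    _, comps, _ = threshold_candidates(pmap, proposal_threshold, min_size)
    cmap = split_all(pmap, comps, subject.volume.voxel_size_mm)
    labels = assemble_candidate_labels(cmap, subject.gold)
    return SubjectData(volume=subject.volume, prob_map=pmap,
                       candidate_map=cmap, labels=labels)


@dataclass
class Experiment:
    train: list[SubjectData]
    test: list[SubjectData]
    test_subjects: list[CohortSubject] = field(default_factory=list)
    voxel_classifier: VoxelClassifier | None = None


def build_experiment(n_train: int, n_test: int, base_spec: PhantomSpec,
                     seed: int, proposal_threshold: float = 0.05,
                     min_size: int = 3,
                     lesion_count_range: tuple[int, int] | None = None
                     ) -> Experiment:
    """Training + held-out phantom cohorts with a voxel classifier fitted on
    the training subjects only (no leakage into the held-out set).  Held-out
    labels always come from the complete (uncensored) truth."""
    train_cohort = phantom_cohort(n_train, base_spec, seed, id_prefix="train",
                                  lesion_count_range=lesion_count_range)
    test_spec = dataclasses.replace(base_spec, missing_lesion_labels=False,
                                    missing_cvs_labels=False,
                                    unsure_cvs_fraction=0.0)
    test_cohort = phantom_cohort(n_test, test_spec, seed + 1, id_prefix="test",
                                 lesion_count_range=lesion_count_range)
    classifier = fit_voxel_classifier(
        [extract_voxel_features(s.volume) for s in train_cohort],
        [s.truth.lesion_label_grid for s in train_cohort], seed=seed)
    train = [prepare_subject(s, classifier, proposal_threshold, min_size)
             for s in train_cohort]
    test = [prepare_subject(s, classifier, proposal_threshold, min_size)
            for s in test_cohort]
    return Experiment(train=train, test=test, test_subjects=test_cohort,
                      voxel_classifier=classifier)


def censor_cvs_labels(experiment: Experiment, fraction: float,
                      seed: int = 0) -> Experiment:
    """Copy of the experiment in which a seeded ``fraction`` of training
    subjects have every CVS label marked missing (subject-level missingness,
    as when CVS ratings were never collected for a subject)."""
    rng = np.random.default_rng(seed)
    n = len(experiment.train)
    k = int(round(fraction * n))
    censored_idx = set(rng.choice(n, size=k, replace=False).tolist())
    train = []
    for i, s in enumerate(experiment.train):
        if i in censored_idx:
            labels = [dataclasses.replace(l, cvs=MISSING) for l in s.labels]
            s = SubjectData(volume=s.volume, prob_map=s.prob_map,
                            candidate_map=s.candidate_map, labels=labels)
        train.append(s)
    return Experiment(train=train, test=experiment.test,
                      test_subjects=experiment.test_subjects,
                      voxel_classifier=experiment.voxel_classifier)


def evaluate_model(model: JointModel, experiment: Experiment,
                   n_patches: int = 25, seed: int = 0) -> dict:
    """Candidate-level evaluation on the held-out subjects.

    Returns AUROCs for the three outputs, the pooled candidate prediction
    table with its ground-truth labels, and the fraction of true lesion
    centers captured by the candidate partition.
    """
    rng = np.random.default_rng(seed)
    frames = []
    n_captured = 0
    n_centers = 0
    for subject, cohort in zip(experiment.test, experiment.test_subjects):
        table = classify_all_candidates(subject.volume, subject.candidate_map,
                                        model, n_patches=n_patches, rng=rng)
        truth_labels = {l.candidate_id: l for l in subject.labels}
        table["y_lesion"] = [truth_labels[c].lesion for c in table.candidate_id]
        table["y_prl"] = [truth_labels[c].prl for c in table.candidate_id]
        table["y_cvs"] = [truth_labels[c].cvs for c in table.candidate_id]
        table.insert(0, "subject", subject.volume.subject_id)
        frames.append(table)
        matched, _ = match_coordinates(subject.candidate_map, cohort.gold)
        n_captured += int((matched["candidate_id"] > 0).sum())
        n_centers += len(matched)
    pooled = pd.concat(frames, ignore_index=True)
    result = {
        "candidates": pooled,
        "coverage_pct": 100.0 * n_captured / max(1, n_centers),
    }
    for name, score_col, y_col in (("lesion", "p_lesion", "y_lesion"),
                                   ("prl", "p_prl", "y_prl"),
                                   ("cvs", "p_cvs", "y_cvs")):
        roc = roc_and_youden(pooled[score_col], pooled[y_col])
        result[f"{name}_auroc"] = roc.auroc
    return result


def run_recovery_experiment(n_train: int, n_test: int, base_spec: PhantomSpec,
                            net_config: NetworkConfig, train_config: TrainConfig,
                            seed: int, missing_cvs_fraction: float = 0.0,
                            n_eval_patches: int = 25,
                            lesion_count_range: tuple[int, int] | None = None
                            ) -> dict:
    """The full end-to-end recovery experiment; returns the evaluation dict
    plus the trained model and loss histories."""
    experiment = build_experiment(n_train, n_test, base_spec, seed,
                                  lesion_count_range=lesion_count_range)
    if missing_cvs_fraction > 0:
        experiment = censor_cvs_labels(experiment, missing_cvs_fraction, seed)
    autoenc, pre_history = pretrain(experiment.train, net_config, train_config)
    model, joint_history = train_joint(experiment.train, net_config, train_config,
                                       pretrained_encoder=autoenc.encoder)
    result = evaluate_model(model, experiment, n_patches=n_eval_patches, seed=seed)
    result.update(model=model, pretrain_history=pre_history,
                  joint_history=joint_history, experiment=experiment)
    return result
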