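"""Candidate classification by patch ensembling and subject segmentation.

Each candidate is classified by averaging the network's predictions over 25
patches whose centers are drawn uniformly from the candidate's voxels, each
attention-masked for that candidate (the same masking used in training).
Voxel-wise output grids apply the default operating thresholds (chosen at
Youden's J on the development data of the underlying method): a candidate
enters the lesion grid when p_lesion >= 0.789, and — nested inside the
lesion-retained set, since a PRL or CVS lesion is necessarily a lesion — the
PRL grid when p_prl >= 0.106 and the CVS grid when p_cvs >= 0.212.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import CandidatePrediction, JointModel
from .patches import apply_attention_mask, extract_patch
from .preprocess import MultiContrastVolume
from .proposal import (ProbabilityMap, VoxelClassifier, extract_voxel_features,
                       predict_probability_map, threshold_candidates)
from .split import CandidateMap, split_all

__all__ = [
    "ThresholdSet",
    "SegmentationResult",
    "classify_candidate",
    "classify_all_candidates",
    "segment_subject",
]


@dataclass(frozen=True)
class ThresholdSet:
    lesion: float = 0.789
    prl: float = 0.106
    cvs: float = 0.212

    def __post_init__(self):
        for name, value in (("lesion", self.lesion), ("prl", self.prl),
                            ("cvs", self.cvs)):
            if not (0.0 < value < 1.0):
                raise ValueError(f"threshold {name!r} must lie in (0, 1); got {value}")


def classify_candidate(volume: MultiContrastVolume, candidate_map: CandidateMap,
                       candidate_id: int, model: JointModel,
                       n_patches: int = 25,
                       rng: np.random.Generator | None = None,
                       patch_size: int = 24,
                       ) -> tuple[CandidatePrediction, np.ndarray]:
    """Ensemble prediction for one candidate.

    Returns the averaged :class:`CandidatePrediction` and the (n_patches, 3)
    array of per-patch predictions it is the arithmetic mean of.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    vox = candidate_map.voxels_of(candidate_id)
    if len(vox) == 0:
        raise ValueError(f"candidate {candidate_id} is empty")
    stacked = volume.stacked()
    centers = vox[rng.integers(len(vox), size=n_patches)]
    batch = np.empty((n_patches, stacked.shape[0], patch_size, patch_size, patch_size),
                     np.float32)
    for i, center in enumerate(centers):
        patch, crop = extract_patch(stacked, center, patch_size, candidate_map.labels)
        batch[i] = apply_attention_mask(patch, crop, candidate_id, center).data
    per_patch = model.predict(batch)
    mean = per_patch.mean(axis=0)
    return CandidatePrediction(float(mean[0]), float(mean[1]), float(mean[2])), per_patch


def classify_all_candidates(volume: MultiContrastVolume, candidate_map: CandidateMap,
                            model: JointModel, n_patches: int = 25,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Prediction table: one row per candidate with its three probabilities."""
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for cid in candidate_map.candidate_ids:
        vox = candidate_map.voxels_of(cid)
        pred, _ = classify_candidate(volume, candidate_map, int(cid), model,
                                     n_patches=n_patches, rng=rng)
        rows.append({
            "candidate_id": int(cid), "n_voxels": len(vox),
            "centroid_x": vox[:, 0].mean(), "centroid_y": vox[:, 1].mean(),
            "centroid_z": vox[:, 2].mean(),
            "p_lesion": pred.p_lesion, "p_prl": pred.p_prl, "p_cvs": pred.p_cvs,
        })
    return pd.DataFrame(rows, columns=[
        "candidate_id", "n_voxels", "centroid_x", "centroid_y", "centroid_z",
        "p_lesion", "p_prl", "p_cvs"])


@dataclass
class SegmentationResult:
    lesion_grid: np.ndarray
    prl_grid: np.ndarray
    cvs_grid: np.ndarray
    candidates: pd.DataFrame
    candidate_map: CandidateMap
    prob_map: ProbabilityMap
    thresholds: ThresholdSet


def segment_subject(volume: MultiContrastVolume,
                    model: JointModel,
                    voxel_classifier: VoxelClassifier | None = None,
                    prob_map: ProbabilityMap | None = None,
                    thresholds: ThresholdSet = ThresholdSet(),
                    proposal_threshold: float = 0.05,
                    min_size: int = 3,
                    n_patches: int = 25,
                    rng: np.random.Generator | None = None) -> SegmentationResult:
    """Full pipeline on one normalized subject: propose -> split -> classify
    -> thresholded voxel-wise grids.

    PRL and CVS grids are nested inside the lesion-thresholded candidate set.
    An empty segmentation is a valid result.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if prob_map is None:
        if voxel_classifier is None:
            raise ValueError("provide either a voxel classifier or a probability map")
        feats = extract_voxel_features(volume, voxel_classifier.scales)
        prob_map = predict_probability_map(voxel_classifier, feats)
    _, comps, _ = threshold_candidates(prob_map, proposal_threshold, min_size)
    cmap = split_all(prob_map, comps, volume.voxel_size_mm)
    table = classify_all_candidates(volume, cmap, model, n_patches=n_patches, rng=rng)
    lesion_grid = np.zeros(volume.shape, bool)
    prl_grid = np.zeros(volume.shape, bool)
    cvs_grid = np.zeros(volume.shape, bool)
    for _, row in table.iterrows():
        if row.p_lesion < thresholds.lesion:
            continue
        cand = cmap.labels == int(row.candidate_id)
        lesion_grid |= cand
        if row.p_prl >= thresholds.prl:
            prl_grid |= cand
        if row.p_cvs >= thresholds.cvs:
            cvs_grid |= cand
    return SegmentationResult(lesion_grid=lesion_grid, prl_grid=prl_grid,
                              cvs_grid=cvs_grid, candidates=table,
                              candidate_map=cmap, prob_map=prob_map,
                              thresholds=thresholds)
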