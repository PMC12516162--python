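"""Voxel-wise lesion probability map and liberal candidate proposal.

A logistic-regression voxel classifier plays the role of the external
voxel-wise lesion segmenter that proposes candidates: it is trained on simple
multi-contrast local features (raw intensities, Gaussian-smoothed intensities
at two scales, a T1xFLAIR coupling term, and per-contrast gradient
magnitudes) and its probability map is thresholded liberally (default 0.05)
so the proposal stage is sensitive but not specific.  The pipeline also
accepts an externally supplied probability map, so the output of any other
voxel-wise segmenter can be dropped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

from .preprocess import CONTRAST_NAMES, MultiContrastVolume

__all__ = [
    "ProbabilityMap",
    "VoxelFeatureSet",
    "VoxelClassifier",
    "extract_voxel_features",
    "fit_voxel_classifier",
    "predict_probability_map",
    "threshold_candidates",
]

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class ProbabilityMap:
    """Voxel-wise lesion probabilities in [0, 1]; zero outside the brain mask."""

    values: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        v = self.values
        if (v < 0).any() or (v > 1).any():
            raise ValueError("probability values must lie in [0, 1]")
        self.values = np.where(self.brain_mask, v, 0.0).astype(np.float32)


@dataclass
class VoxelFeatureSet:
    """One fixed-order feature row per in-mask voxel."""

    features: np.ndarray                 # (n_voxels, n_features)
    feature_names: tuple[str, ...]
    brain_mask: np.ndarray
    scales: tuple[float, ...]

    def __post_init__(self):
        if not np.isfinite(self.features).all():
            raise ValueError("voxel features contain non-finite values")


def extract_voxel_features(volume: MultiContrastVolume,
                           scales: Sequence[float] = (1.0, 2.0)) -> VoxelFeatureSet:
    """Per-voxel features: raw + smoothed (one per scale) intensities per
    contrast, T1w*FLAIR product, gradient magnitude per contrast."""
    mask = volume.brain_mask
    if not mask.any():
        raise ValueError("brain mask is empty")
    columns, names = [], []
    grids = volume.contrasts()
    for name, grid in grids.items():
        columns.append(grid[mask])
        names.append(f"{name}_raw")
    for sigma in scales:
        for name, grid in grids.items():
            sm = grid if sigma <= 0 else ndimage.gaussian_filter(grid, sigma)
            columns.append(sm[mask])
            names.append(f"{name}_smooth{sigma:g}")
    columns.append(grids["t1w"][mask] * grids["flair"][mask])
    names.append("t1w_x_flair")
    for name, grid in grids.items():
        gm = np.sqrt(sum(g ** 2 for g in np.gradient(grid.astype(np.float32))))
        columns.append(gm[mask])
        names.append(f"{name}_gradmag")
    feats = np.column_stack(columns).astype(np.float32)
    return VoxelFeatureSet(features=feats, feature_names=tuple(names),
                           brain_mask=mask, scales=tuple(scales))


@dataclass
class VoxelClassifier:
    """Serializable logistic voxel classifier with its feature contract."""

    model: LogisticRegression
    feature_names: tuple[str, ...]
    scales: tuple[float, ...]
    background_ratio: float = 10.0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> np.ndarray:
        return self.model.coef_.ravel()


def fit_voxel_classifier(features: VoxelFeatureSet | Sequence[VoxelFeatureSet],
                         truth_grid: np.ndarray | Sequence[np.ndarray],
                         background_ratio: float = 10.0,
                         seed: int = 0) -> VoxelClassifier:
    """Fit the logistic voxel model on lesion-vs-background voxels.

    Background voxels are downsampled to ``background_ratio`` negatives per
    positive (seeded), which both speeds fitting and lifts background
    probabilities so the liberal threshold stays sensitive.
    """
    feature_sets = [features] if isinstance(features, VoxelFeatureSet) else list(features)
    grids = [truth_grid] if isinstance(truth_grid, np.ndarray) else list(truth_grid)
    X = np.concatenate([f.features for f in feature_sets])
    y = np.concatenate([(g > 0)[f.brain_mask]
                        for f, g in zip(feature_sets, grids)]).astype(np.int8)
    if y.all() or not y.any():
        raise ValueError("training voxels contain a single class")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_neg = min(len(neg), int(background_ratio * len(pos)))
    keep = np.concatenate([pos, rng.choice(neg, n_neg, replace=False)])
    keep.sort()
    model = LogisticRegression(max_iter=500)
    model.fit(X[keep], y[keep])
    return VoxelClassifier(model=model,
                           feature_names=feature_sets[0].feature_names,
                           scales=feature_sets[0].scales,
                           background_ratio=background_ratio, seed=seed)


def predict_probability_map(classifier: VoxelClassifier,
                            features: VoxelFeatureSet) -> ProbabilityMap:
    if features.feature_names != classifier.feature_names:
        raise ValueError("feature order does not match the fitted classifier")
    probs = classifier.model.predict_proba(features.features)[:, 1]
    values = np.zeros(features.brain_mask.shape, np.float32)
    values[features.brain_mask] = probs
    return ProbabilityMap(values=values, brain_mask=features.brain_mask)


def threshold_candidates(pmap: ProbabilityMap, threshold: float = 0.05,
                         min_size: int = 3) -> tuple[np.ndarray, np.ndarray, int]:
    """Threshold the map (values >= threshold) and label connected components
    by 26-connectivity, dropping components smaller than ``min_size`` voxels.

    Returns ``(mask, component_labels, n_components)`` with component labels
    renumbered consecutively from 1.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    mask = pmap.values >= threshold
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n and min_size > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_size)
        small = small[small > 0]
        if len(small):
            mask &= ~np.isin(labels, small)
            labels, n = ndimage.label(mask, structure=_STRUCT_26)
    return mask, labels, int(n)
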