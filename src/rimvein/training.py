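"""Augmentation, autoencoder pretraining, and missingness-weighted joint training.

Each epoch re-augments every training subject with one spatial transform
(per-axis flips w.p. 0.5, small rotations, rescaling in [0.66, 1.5]; linear
interpolation for intensities, nearest for label grids) and one intensity
transform (gamma correction with log-gamma ~ U(-0.5, 0.5), applied on a
shifted [0, 1] scale and re-z-scored, since the inputs are z-scored).
Patches are sampled from the augmented brains, attention-masked, shuffled
across subjects, and passed through the network in mini-batches of 64 with
Adam at learning rate 0.001.

Pretraining minimizes a weighted MSE reconstructing the masked patch, with
candidate voxels (all channels) and the whole EPIm/EPIp channels upweighted
4x.  Joint training minimizes a binary cross-entropy over the three outputs
in which missing or "unsure" labels carry weight 0 (zero loss and exactly
zero gradient).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import autodiff
from .autodiff import Adam, Tensor
from .labels import LabelRecord
from .network import Autoencoder, CandidatePrediction, Encoder, JointModel, NetworkConfig
from .patches import (EPIM_CHANNEL, apply_attention_mask, extract_patch,
                      sample_joint_candidate, sample_pretrain_center)
from .preprocess import CONTRAST_NAMES, MultiContrastVolume
from .proposal import ProbabilityMap
from .split import CandidateMap

__all__ = [
    "TrainConfig",
    "save_history_csv",
    "AugmentParams",
    "SubjectData",
    "draw_augment_params",
    "augment_subject",
    "weighted_mse",
    "build_recon_weight_map",
    "masked_bce",
    "pretrain",
    "train_joint",
    "crossval_split",
]


@dataclass(frozen=True)
class TrainConfig:
    pretrain_epochs: int = 50
    joint_epochs: int = 100
    patches_per_subject: int = 50
    minibatch: int = 64
    learning_rate: float = 1e-3
    flip_prob: float = 0.5
    rotation_max_deg: float = 15.0
    rescale_range: tuple[float, float] = (0.66, 1.5)
    log_gamma_range: tuple[float, float] = (-0.5, 0.5)
    recon_upweight: float = 4.0
    oversample_factor: float = 3.0
    pretrain_center_epsilon: float = 0.01
    patch_size: int = 24
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml

        fields = yaml.safe_load(open(path)) or {}
        for key in ("rescale_range", "log_gamma_range"):
            if key in fields:
                fields[key] = tuple(fields[key])
        return cls(**fields)


def save_history_csv(history: Sequence[float], path) -> None:
    """Write a per-epoch loss history as a two-column CSV."""
    import pandas as pd

    pd.DataFrame({"epoch": np.arange(1, len(history) + 1),
                  "loss": list(history)}).to_csv(path, index=False)


@dataclass
class SubjectData:
    """Everything training needs for one subject."""

    volume: MultiContrastVolume          # z-normalized
    prob_map: ProbabilityMap
    candidate_map: CandidateMap
    labels: list[LabelRecord] = field(default_factory=list)

    @property
    def label_by_id(self) -> dict[int, LabelRecord]:
        return {l.candidate_id: l for l in self.labels}


# ---------------------------------------------------------------------------
# augmentation

@dataclass(frozen=True)
class AugmentParams:
    flips: tuple[bool, bool, bool]
    angles_deg: tuple[float, float, float]
    scale: float
    log_gamma: float

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(flips=(False, False, False), angles_deg=(0.0, 0.0, 0.0),
                   scale=1.0, log_gamma=0.0)


def draw_augment_params(rng: np.random.Generator,
                        config: TrainConfig) -> AugmentParams:
    flips = tuple(bool(rng.random() < config.flip_prob) for _ in range(3))
    r = config.rotation_max_deg
    angles = tuple(float(a) for a in rng.uniform(-r, r, 3))
    scale = float(rng.uniform(*config.rescale_range))
    log_gamma = float(rng.uniform(*config.log_gamma_range))
    return AugmentParams(flips=flips, angles_deg=angles, scale=scale,
                         log_gamma=log_gamma)


def _rotation_matrix(angles_deg) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


def _spatial_transform(grid: np.ndarray, params: AugmentParams, order: int) -> np.ndarray:
    out = grid
    for axis, f in enumerate(params.flips):
        if f:
            out = np.flip(out, axis=axis)
    if params.scale == 1.0 and all(a == 0 for a in params.angles_deg):
        return np.ascontiguousarray(out)
    # output->input mapping: rotate by -angles and scale by 1/f about the center
    rot = _rotation_matrix(params.angles_deg)
    mat = rot.T @ np.diag([1.0 / params.scale] * 3)
    center = (np.asarray(grid.shape) - 1) / 2.0
    offset = center - mat @ center
    return ndimage.affine_transform(out, mat, offset=offset, order=order,
                                    mode="constant", cval=0.0,
                                    output=np.float32 if order > 0 else out.dtype)


def _gamma_correct(grid: np.ndarray, mask: np.ndarray, log_gamma: float) -> np.ndarray:
    """Gamma on z-scored data: shift to [0, 1] within the mask, apply gamma,
    invert the shift, then re-z-score within the mask."""
    out = np.zeros_like(grid, np.float32)
    vals = grid[mask].astype(np.float64)
    lo, hi = vals.min(), vals.max()
    if hi - lo < 1e-8:
        return out
    v01 = (vals - lo) / (hi - lo)
    v = np.power(v01, np.exp(log_gamma)) * (hi - lo) + lo
    sd = v.std()
    out[mask] = ((v - v.mean()) / (sd if sd > 1e-12 else 1.0)).astype(np.float32)
    return out


def augment_subject(subject: SubjectData, rng: np.random.Generator,
                    config: TrainConfig,
                    params: AugmentParams | None = None
                    ) -> tuple[SubjectData, AugmentParams]:
    """One consistent spatial + intensity transform across all four contrasts,
    the brain mask, the probability map, and the candidate label grid."""
    if params is None:
        params = draw_augment_params(rng, config)
    mask = _spatial_transform(subject.volume.brain_mask.astype(np.uint8),
                              params, order=0).astype(bool)
    contrasts = {}
    for name in CONTRAST_NAMES:
        g = _spatial_transform(getattr(subject.volume, name), params, order=1)
        g = _gamma_correct(g, mask, params.log_gamma) if mask.any() else g
        contrasts[name] = g
    volume = replace(subject.volume, brain_mask=mask, **contrasts)
    pvals = np.clip(_spatial_transform(subject.prob_map.values, params, order=1), 0, 1)
    pmap = ProbabilityMap(values=pvals, brain_mask=mask)
    clabels = _spatial_transform(subject.candidate_map.labels, params, order=0)
    cmap = CandidateMap(labels=clabels, peaks=subject.candidate_map.peaks,
                        voxel_size_mm=subject.candidate_map.voxel_size_mm)
    return SubjectData(volume=volume, prob_map=pmap, candidate_map=cmap,
                       labels=subject.labels), params


# ---------------------------------------------------------------------------
# losses

def build_recon_weight_map(candidate_crop: np.ndarray, n_channels: int = 4,
                           upweight: float = 4.0) -> np.ndarray:
    """Reconstruction weights: ``upweight`` on candidate voxels (all channels)
    and on the entire EPIm and EPIp channels; 1 elsewhere."""
    s = candidate_crop.shape
    w = np.ones((n_channels,) + s, np.float32)
    w[:, candidate_crop > 0] = upweight
    w[EPIM_CHANNEL] = upweight
    w[EPIM_CHANNEL + 1] = upweight      # EPIp follows EPIm in channel order
    return w


def weighted_mse(reconstruction: Tensor | np.ndarray, target: np.ndarray,
                 weight_map: np.ndarray) -> Tensor:
    """Sum(w (r - t)^2) / Sum(w); differentiable w.r.t. the reconstruction."""
    recon = reconstruction if isinstance(reconstruction, Tensor) else Tensor(reconstruction)
    if recon.shape != np.shape(target) or np.shape(target) != np.shape(weight_map):
        raise ValueError("reconstruction, target, and weight map shapes differ")
    return autodiff.weighted_mse_loss(recon, target, weight_map)


def masked_bce(prediction: Tensor | CandidatePrediction | np.ndarray,
               label: LabelRecord | Sequence[LabelRecord]) -> Tensor:
    """Missingness-weighted BCE; single-record or batch form.

    Components whose label is missing or "unsure" have weight 0: they
    contribute zero loss and exactly zero gradient.
    """
    records = [label] if isinstance(label, LabelRecord) else list(label)
    targets = np.stack([r.targets for r in records])
    weights = np.stack([r.loss_weights for r in records])
    if isinstance(prediction, CandidatePrediction):
        pred = Tensor(prediction.as_array()[None])
    elif isinstance(prediction, Tensor):
        pred = prediction if prediction.data.ndim == 2 else Tensor(prediction.data[None])
    else:
        arr = np.asarray(prediction, np.float64)
        pred = Tensor(arr if arr.ndim == 2 else arr[None])
    if pred.shape[0] != len(records):
        raise ValueError("prediction/label batch size mismatch")
    return autodiff.masked_bce_loss(pred, targets, weights)


# ---------------------------------------------------------------------------
# patch streams

def _present_candidates(cmap: CandidateMap) -> dict[int, np.ndarray]:
    """Candidate id -> voxel coordinates, for candidates that survived
    augmentation (nearest-neighbour rescaling can erase tiny ones)."""
    ids = np.unique(cmap.labels)
    return {int(k): np.argwhere(cmap.labels == k) for k in ids if k > 0}


def _pretrain_patches(subject: SubjectData, rng: np.random.Generator,
                      config: TrainConfig):
    centers = sample_pretrain_center(subject.prob_map, rng,
                                     epsilon=config.pretrain_center_epsilon,
                                     n=config.patches_per_subject)
    stacked = subject.volume.stacked()
    out = []
    for center in centers:
        patch, crop = extract_patch(stacked, center, config.patch_size,
                                    subject.candidate_map.labels)
        present = np.unique(crop)
        present = present[present > 0]
        target = int(rng.choice(present)) if len(present) else 0
        masked = apply_attention_mask(patch, crop, target, center,
                                      require_target=False)
        out.append((masked.data, build_recon_weight_map(
            crop, upweight=config.recon_upweight)))
    return out


def _joint_patches(subject: SubjectData, rng: np.random.Generator,
                   config: TrainConfig):
    voxels = _present_candidates(subject.candidate_map)
    records = [l for l in subject.labels if l.candidate_id in voxels]
    if not records:
        return []
    stacked = subject.volume.stacked()
    by_id = {l.candidate_id: l for l in records}
    out = []
    for _ in range(config.patches_per_subject):
        cid = sample_joint_candidate(records, rng, config.oversample_factor)
        vox = voxels[cid]
        center = vox[rng.integers(len(vox))]
        patch, crop = extract_patch(stacked, center, config.patch_size,
                                    subject.candidate_map.labels)
        masked = apply_attention_mask(patch, crop, cid, center)
        out.append((masked.data, by_id[cid]))
    return out


# ---------------------------------------------------------------------------
# training loops

def pretrain(subjects: Sequence[SubjectData], net_config: NetworkConfig,
             config: TrainConfig) -> tuple[Autoencoder, list[float]]:
    """Seeded autoencoder pretraining with weighted-MSE reconstruction of the
    masked patches; returns the autoencoder (its ``.encoder`` is what joint
    training consumes) and the per-epoch loss history."""
    if not subjects:
        raise ValueError("need at least one subject")
    model = Autoencoder(net_config, rng=np.random.default_rng([config.seed, 10]))
    rng = np.random.default_rng([config.seed, 11])
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.pretrain_epochs):
        batch_items = []
        for subject in subjects:
            aug, _ = augment_subject(subject, rng, config)
            batch_items.extend(_pretrain_patches(aug, rng, config))
        order = rng.permutation(len(batch_items))
        losses = []
        for b0 in range(0, len(order), config.minibatch):
            idx = order[b0:b0 + config.minibatch]
            data = np.stack([batch_items[i][0] for i in idx])
            wmap = np.stack([batch_items[i][1] for i in idx])
            x = Tensor(data)
            recon = model(x)
            loss = autodiff.weighted_mse_loss(recon, data, wmap)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return model, history


def train_joint(subjects: Sequence[SubjectData], net_config: NetworkConfig,
                config: TrainConfig,
                pretrained_encoder: Encoder | None = None
                ) -> tuple[JointModel, list[float]]:
    """Joint multi-label training with candidate oversampling, attention
    masking, and missingness-weighted BCE."""
    if not any(l.any_observed for s in subjects for l in s.labels):
        raise ValueError("no observed labels in the training set")
    model = JointModel(net_config, rng=np.random.default_rng([config.seed, 20]))
    model.dropout_rng = np.random.default_rng([config.seed, 21])
    if pretrained_encoder is not None:
        _copy_module_state(pretrained_encoder, model.encoder)
    rng = np.random.default_rng([config.seed, 22])
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: list[float] = []
    for _ in range(config.joint_epochs):
        items = []
        for subject in subjects:
            aug, _ = augment_subject(subject, rng, config)
            items.extend(_joint_patches(aug, rng, config))
        order = rng.permutation(len(items))
        losses = []
        for b0 in range(0, len(order), config.minibatch):
            idx = order[b0:b0 + config.minibatch]
            data = np.stack([items[i][0] for i in idx])
            records = [items[i][1] for i in idx]
            pred = model(Tensor(data))
            loss = masked_bce(pred, records)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return model, history


def _copy_module_state(src, dst) -> None:
    src_params = dict(src.named_parameters())
    for name, p in dst.named_parameters():
        p.data = src_params[name].data.copy()
    src_buffers = dict(src.named_buffers())
    for name, b in dst.named_buffers():
        b[...] = src_buffers[name]


def crossval_split(subject_ids: Sequence, k: int = 10, seed: int = 0) -> list[list]:
    """Disjoint subject-level folds covering all subjects; sizes differ by <=1."""
    ids = list(subject_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return folds
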