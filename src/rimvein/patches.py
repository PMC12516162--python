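"""Patch extraction, attention masking, and patch/candidate sampling.

Patches are 4-channel ``size``^3 blocks (channel order T1w, FLAIR, EPIm,
EPIp) cropped around a center voxel; patches are not required to be centered
on a candidate, to cover it, or to contain only one candidate.  Out-of-volume
voxels are zero-padded (z-scored background is ~0, so padding is
distributionally neutral).

The attention mask designates the candidate to classify:

* EPIm channel — voxels outside the target candidate are zeroed; non-surface
  (interior) target voxels are emphasized x2; surface voxels are unchanged.
  A surface voxel is a target voxel with a 6-neighbour outside the target
  (computed within the patch crop; beyond-patch voxels count as outside).
* T1w/FLAIR/EPIp channels — voxels inside *other* candidates are dimmed x0.1;
  everything else is untouched, preserving context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .labels import LabelRecord
from .preprocess import MultiContrastVolume
from .proposal import ProbabilityMap

__all__ = [
    "MaskedPatch",
    "EPIM_CHANNEL",
    "extract_patch",
    "apply_attention_mask",
    "sample_pretrain_center",
    "sample_joint_candidate",
    "candidate_sampling_weight",
]

EPIM_CHANNEL = 2        # index of the EPI magnitude channel
_SIX = ndimage.generate_binary_structure(3, 1)


@dataclass
class MaskedPatch:
    data: np.ndarray                 # (4, s, s, s), after masking
    target_candidate_id: int
    center: tuple[int, int, int]
    candidate_crop: np.ndarray       # (s, s, s) integer candidate labels

    def __post_init__(self):
        if not np.isfinite(self.data).all():
            raise ValueError("masked patch contains non-finite values")


def extract_patch(volume: MultiContrastVolume | np.ndarray,
                  center: Sequence[int], size: int = 24,
                  candidate_labels: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray | None]:
    """Crop a ``size``^3 patch per channel around ``center`` (zero-padded at
    volume borders); the candidate label grid is cropped identically."""
    stacked = volume.stacked() if isinstance(volume, MultiContrastVolume) else np.asarray(volume)
    shape = stacked.shape[1:]
    center = tuple(int(c) for c in center)
    if not all(0 <= c < s for c, s in zip(center, shape)):
        raise ValueError(f"center {center} outside volume of shape {shape}")
    half = size // 2
    starts = [c - half for c in center]
    patch = np.zeros((stacked.shape[0], size, size, size), np.float32)
    src, dst = [], []
    for st, s in zip(starts, shape):
        lo, hi = max(st, 0), min(st + size, s)
        src.append(slice(lo, hi))
        dst.append(slice(lo - st, hi - st))
    patch[(slice(None), *dst)] = stacked[(slice(None), *src)]
    crop = None
    if candidate_labels is not None:
        crop = np.zeros((size, size, size), candidate_labels.dtype)
        crop[tuple(dst)] = candidate_labels[tuple(src)]
    return patch, crop


def apply_attention_mask(patch: np.ndarray, candidate_crop: np.ndarray,
                         target_candidate_id: int,
                         center: Sequence[int] = (0, 0, 0),
                         require_target: bool = True) -> MaskedPatch:
    """Apply the three masking rules for the designated candidate.

    With ``require_target=False`` a patch with no target candidate (used in
    autoencoder pretraining when a sampled patch contains no candidate) gets
    the same rules degenerately: the whole EPIm channel is zeroed and every
    candidate present is dimmed as an "other" candidate.
    """
    target = candidate_crop == target_candidate_id if target_candidate_id else \
        np.zeros_like(candidate_crop, bool)
    if require_target and not target.any():
        raise ValueError(f"target candidate {target_candidate_id} absent from patch")
    interior = ndimage.binary_erosion(target, _SIX)  # border voxels are surface
    other = (candidate_crop > 0) & ~target
    out = patch.astype(np.float32).copy()
    epim = out[EPIM_CHANNEL]
    epim[~target] = 0.0
    epim[interior] *= 2.0
    for ch in range(out.shape[0]):
        if ch == EPIM_CHANNEL:
            continue
        out[ch][other] *= 0.1
    return MaskedPatch(data=out, target_candidate_id=int(target_candidate_id),
                       center=tuple(int(c) for c in center),
                       candidate_crop=candidate_crop)


def sample_pretrain_center(pmap: ProbabilityMap, rng: np.random.Generator,
                           epsilon: float = 0.01,
                           n: int | None = None) -> np.ndarray:
    """Draw patch center(s) with probability proportional to (p + epsilon)
    over brain-mask voxels, so low-probability tissue remains reachable."""
    mask = pmap.brain_mask
    if not mask.any():
        raise ValueError("brain mask is empty")
    coords = np.argwhere(mask)
    w = pmap.values[mask].astype(np.float64) + epsilon
    w /= w.sum()
    idx = rng.choice(len(coords), size=n if n is not None else 1, p=w)
    picked = coords[idx]
    return picked if n is not None else picked[0]


def candidate_sampling_weight(label: LabelRecord, oversample: float = 3.0) -> float:
    """Sampling weight max(1, oversample * #positive labels): each positive
    category (lesion, PRL, CVS) multiplies the draw rate relative to a
    false-positive candidate."""
    return max(1.0, oversample * label.n_positive)


def sample_joint_candidate(labels: Sequence[LabelRecord], rng: np.random.Generator,
                           oversample: float = 3.0) -> int:
    """Draw a candidate id with the oversampling weights above."""
    if not labels:
        raise ValueError("no candidates to sample from")
    w = np.array([candidate_sampling_weight(l, oversample) for l in labels])
    idx = rng.choice(len(labels), p=w / w.sum())
    return labels[idx].candidate_id
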