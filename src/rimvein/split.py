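"""Confluent-candidate splitting by probability peaks and nearest centers.

A connected suprathreshold component can contain several confluent lesions.
Each component is partitioned by (1) finding lesion centers as 26-neighbourhood
local maxima of the Gaussian-smoothed probability map whose finite-difference
Hessian is negative semi-definite, merging centers closer than
``min_separation_mm`` into the higher-probability one, then (2) assigning
every component voxel to its Euclidean-nearest center in millimetres.

Determinism conventions: plateau maxima are represented by their
lexicographically smallest coordinate; distance ties go to the lower center
index; global candidate ids follow raster (lexicographic) order of the peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .proposal import ProbabilityMap

__all__ = [
    "CandidateMap",
    "find_lesion_centers",
    "assign_to_centers",
    "split_all",
]

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class CandidateMap:
    """Integer-labelled partition of the proposed mask into candidates."""

    labels: np.ndarray                     # 0 background, 1..K candidates
    peaks: np.ndarray                      # (K, 3) voxel coordinate of each peak
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_candidates(self) -> int:
        return len(self.peaks)

    @property
    def candidate_ids(self) -> np.ndarray:
        return np.arange(1, self.n_candidates + 1)

    def voxels_of(self, candidate_id: int) -> np.ndarray:
        return np.argwhere(self.labels == candidate_id)

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in self.candidate_ids:
            vox = self.voxels_of(k)
            rows.append({
                "candidate_id": int(k),
                "n_voxels": len(vox),
                "centroid_x": vox[:, 0].mean(), "centroid_y": vox[:, 1].mean(),
                "centroid_z": vox[:, 2].mean(),
                "peak_x": int(self.peaks[k - 1][0]),
                "peak_y": int(self.peaks[k - 1][1]),
                "peak_z": int(self.peaks[k - 1][2]),
            })
        return pd.DataFrame(rows, columns=[
            "candidate_id", "n_voxels", "centroid_x", "centroid_y", "centroid_z",
            "peak_x", "peak_y", "peak_z"])


def _hessian_nsd(smoothed: np.ndarray, coord: tuple[int, int, int],
                 tol: float = 1e-6) -> bool:
    """Negative semi-definiteness of the central-difference Hessian, with
    edge-replicated values at the volume border."""
    p = np.pad(smoothed, 1, mode="edge")
    i, j, k = (c + 1 for c in coord)
    H = np.empty((3, 3))
    f0 = p[i, j, k]
    H[0, 0] = p[i + 1, j, k] - 2 * f0 + p[i - 1, j, k]
    H[1, 1] = p[i, j + 1, k] - 2 * f0 + p[i, j - 1, k]
    H[2, 2] = p[i, j, k + 1] - 2 * f0 + p[i, j, k - 1]
    H[0, 1] = H[1, 0] = (p[i + 1, j + 1, k] - p[i + 1, j - 1, k]
                         - p[i - 1, j + 1, k] + p[i - 1, j - 1, k]) / 4
    H[0, 2] = H[2, 0] = (p[i + 1, j, k + 1] - p[i + 1, j, k - 1]
                         - p[i - 1, j, k + 1] + p[i - 1, j, k - 1]) / 4
    H[1, 2] = H[2, 1] = (p[i, j + 1, k + 1] - p[i, j + 1, k - 1]
                         - p[i, j - 1, k + 1] + p[i, j - 1, k - 1]) / 4
    return bool(np.linalg.eigvalsh(H).max() <= tol)


def find_lesion_centers(smoothed: np.ndarray, component_mask: np.ndarray,
                        voxel_size_mm=(1.0, 1.0, 1.0),
                        min_separation_mm: float = 3.0) -> np.ndarray:
    """Lesion centers within one component of the smoothed probability map.

    Returns an (n, 3) array of voxel coordinates in raster (lexicographic)
    order; always at least one center.
    """
    if not component_mask.any():
        raise ValueError("component is empty")
    masked = np.where(component_mask, smoothed, -np.inf)
    local_max = (masked == ndimage.maximum_filter(
        masked, footprint=_STRUCT_26, mode="constant", cval=-np.inf)) & component_mask
    # Collapse plateaus (26-connected clusters of equal-valued maxima) to
    # their lexicographically smallest coordinate.
    plat_labels, n_plat = ndimage.label(local_max, structure=_STRUCT_26)
    reps = []
    for lab in range(1, n_plat + 1):
        coords = np.argwhere(plat_labels == lab)
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
        reps.append(tuple(coords[order[0]]))
    centers = [c for c in reps if _hessian_nsd(smoothed, c)]
    if not centers:
        # degenerate component (e.g. pure noise ridge): fall back to the
        # lexicographically smallest global maximum of the component
        vmax = masked.max()
        coords = np.argwhere(masked == vmax)
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
        centers = [tuple(coords[order[0]])]
    # merge centers closer than min_separation into the higher-probability one
    vox = np.asarray(voxel_size_mm)
    vals = np.array([smoothed[c] for c in centers])
    carr = np.asarray(centers, float)
    # visit by descending value; lexicographic order breaks value ties
    order = np.lexsort((carr[:, 2], carr[:, 1], carr[:, 0], -vals))
    kept: list[int] = []
    for idx in order:
        if all(np.linalg.norm((carr[idx] - carr[j]) * vox) >= min_separation_mm
               for j in kept):
            kept.append(idx)
    final = carr[kept].astype(int)
    final = final[np.lexsort((final[:, 2], final[:, 1], final[:, 0]))]
    return final


def assign_to_centers(component_voxels: np.ndarray,
                      centers: np.ndarray,
                      voxel_size_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Label every component voxel by its Euclidean-nearest center (in mm).

    Returns an index array into ``centers`` (0-based); distance ties go to the
    lower center index (argmin convention).
    """
    if len(centers) == 0:
        raise ValueError("need at least one center")
    vox = np.asarray(voxel_size_mm, float)
    d2 = (((component_voxels[:, None, :] - centers[None, :, :]) * vox) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def split_all(pmap: ProbabilityMap, component_labels: np.ndarray,
              voxel_size_mm=(1.0, 1.0, 1.0), smooth_sigma: float = 1.0,
              min_separation_mm: float = 3.0) -> CandidateMap:
    """Split every connected component into candidates; ids in raster order
    of peaks.  Voxel sets partition the thresholded mask exactly."""
    smoothed = ndimage.gaussian_filter(pmap.values.astype(np.float64), smooth_sigma) \
        if smooth_sigma > 0 else pmap.values.astype(np.float64)
    out = np.zeros_like(component_labels, dtype=np.int32)
    all_peaks: list[tuple] = []
    assignments: list[tuple[np.ndarray, np.ndarray]] = []  # (voxels, center idx)
    n_comp = int(component_labels.max())
    slices = ndimage.find_objects(component_labels)
    for comp in range(1, n_comp + 1):
        box = slices[comp - 1]
        if box is None:
            continue
        local_mask = component_labels[box] == comp
        full_mask = np.zeros_like(component_labels, bool)
        full_mask[box] = local_mask
        centers = find_lesion_centers(smoothed, full_mask, voxel_size_mm,
                                      min_separation_mm)
        vox = np.argwhere(full_mask)
        lab = assign_to_centers(vox, centers, voxel_size_mm)
        base = len(all_peaks)
        all_peaks.extend(tuple(c) for c in centers)
        assignments.append((vox, lab + base))
    if not all_peaks:
        return CandidateMap(labels=out, peaks=np.zeros((0, 3), int),
                            voxel_size_mm=tuple(voxel_size_mm))
    peaks = np.asarray(all_peaks, int)
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0]))
    rank = np.empty(len(order), int)
    rank[order] = np.arange(len(order))          # old index -> new id-1
    for vox, lab in assignments:
        out[vox[:, 0], vox[:, 1], vox[:, 2]] = rank[lab] + 1
    return CandidateMap(labels=out, peaks=peaks[order],
                        voxel_size_mm=tuple(voxel_size_mm))
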