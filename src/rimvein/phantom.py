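"""Synthetic multi-contrast brain phantoms with known lesion/PRL/CVS truth.

The phantom emulates the imaging signatures the classifier must learn:

* ellipsoidal white-matter lesions, hyperintense on FLAIR and hypointense on
  T1w;
* paramagnetic rim lesions (PRLs): a hypointense 1-voxel shell on the EPI
  phase image at the lesion periphery (shell = lesion voxels whose
  6-neighbourhood touches non-lesion tissue, the same surface convention the
  attention mask uses);
* central-vein-sign (CVS) lesions: a thin hypointense line on the EPI
  magnitude image passing through the lesion center; a configurable fraction
  of non-CVS lesions carry an *eccentric* vein line (offset >= 2 voxels from
  the center) so centrality is what distinguishes the classes;
* confluent lesion pairs sharing a 6-connected boundary, so the proposal
  stage sees a single connected component that must be split;
* FLAIR-bright "mimic" foci with only partial T1w hypointensity — non-lesion
  tissue that the liberal proposal threshold picks up (sensitive, not
  specific), providing false-positive candidates for the classifier to
  reject;
* free-floating background vein lines on EPI magnitude;
* additive Gaussian noise inside the brain mask, and subject-level label
  missingness (missing lesion labels, missing CVS labels, "unsure" CVS).

Generation is bit-identical for identical specs: independent RNG streams are
derived from ``spec.seed`` for placement ([seed, 1]), noise ([seed, 2]) and
"unsure" label draws ([seed, 3]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import MultiContrastVolume

__all__ = [
    "MISSING",
    "UNSURE",
    "STATUS_STRINGS",
    "PhantomSpec",
    "LesionRecord",
    "PhantomTruth",
    "PhantomPlacementError",
    "generate_phantom",
    "export_truth_table",
    "save_phantom",
]

# status codes for observed labels; 0/1 mean observed negative/positive
MISSING = -1
UNSURE = -2
STATUS_STRINGS = {0: "0", 1: "1", MISSING: "NA", UNSURE: "unsure"}

# deterministic template constants (intensities on an arbitrary scanner scale)
_BASELINE = {"t1w": 1.0, "flair": 1.0, "epim": 1.0, "epip": 0.0}
_GRADIENT_AMPLITUDE = {"t1w": 0.2, "flair": 0.2, "epim": 0.2, "epip": 0.05}
_GRADIENT_DIRECTION = {
    "t1w": (1.0, 0.0, 0.0),
    "flair": (0.0, 1.0, 0.0),
    "epim": (0.0, 0.0, 1.0),
    "epip": (0.7071, 0.7071, 0.0),
}


class PhantomPlacementError(RuntimeError):
    """Lesions could not be placed within the attempt cap (infeasible spec)."""


@dataclass(frozen=True)
class PhantomSpec:
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int = 8
    n_prl: int = 2
    n_cvs: int = 2
    n_confluent_pairs: int = 1
    lesion_radius_range_mm: tuple[float, float] = (2.0, 4.5)
    rim_contrast: float = -2.0
    vein_contrast: float = -2.0
    noise_sd: float = 0.1
    missing_lesion_labels: bool = False
    missing_cvs_labels: bool = False
    unsure_cvs_fraction: float = 0.0
    seed: int = 0
    # appearance parameters beyond the core contract
    lesion_flair_contrast: float = 1.2
    lesion_t1_contrast: float = -1.0
    eccentric_vein_fraction: float = 0.3
    n_mimics: int = 5
    mimic_contrast: float = 1.2
    mimic_t1_contrast: float = -0.6
    n_background_veins: int = 3

    def validate(self) -> None:
        if self.n_lesions < 0 or self.n_prl < 0 or self.n_cvs < 0:
            raise ValueError("lesion counts must be non-negative")
        if self.n_prl > self.n_lesions or self.n_cvs > self.n_lesions:
            raise ValueError("n_prl and n_cvs must not exceed n_lesions")
        if 2 * self.n_confluent_pairs > self.n_lesions:
            raise ValueError("not enough lesions for the requested confluent pairs")
        lo, hi = self.lesion_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range_mm must be a positive interval")
        if not 0 <= self.unsure_cvs_fraction <= 1:
            raise ValueError("unsure_cvs_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class LesionRecord:
    lesion_id: int                       # grid label (1-based)
    center: tuple[int, int, int]         # 0-based voxel indices
    prl: int                             # ground truth 0/1
    cvs: int                             # ground truth 0/1
    lesion_status: int = 1               # observed codes: 0/1/MISSING/UNSURE
    prl_status: int = 0
    cvs_status: int = 0
    eccentric_vein: bool = False


@dataclass
class PhantomTruth:
    lesion_label_grid: np.ndarray        # 0 background, k = lesion k
    records: list[LesionRecord] = field(default_factory=list)
    subject_id: str = "phantom"


# ---------------------------------------------------------------------------
# placement helpers

_ATTEMPT_CAP = 500


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.44
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return d <= 1.0


def _inside_brain(center: np.ndarray, semi_vox: np.ndarray, shape) -> bool:
    c = (np.asarray(shape) - 1) / 2.0
    brain_semi = np.asarray(shape) * 0.44
    margin = semi_vox.max() + 1.5
    d = (((center - c) / (brain_semi - margin)) ** 2).sum()
    return bool(np.all(brain_semi > margin + 1)) and d <= 1.0


def _separated(center, semi_vox, placed, skip: set[int], pad: float = 3.0) -> bool:
    for j, (c2, s2) in enumerate(placed):
        if j in skip or c2 is None:
            continue
        if np.linalg.norm(center - c2) < semi_vox.max() + s2.max() + pad:
            return False
    return True


def _place_lesions(spec: PhantomSpec, rng: np.random.Generator):
    """Return (centers, semi_axes_vox) for all lesions; confluent pairs are
    lesions (0,1), (2,3), ... with overlapping extents."""
    shape = spec.volume_shape
    voxel = np.asarray(spec.voxel_size_mm)
    lo, hi = spec.lesion_radius_range_mm
    placed: list[tuple[np.ndarray | None, np.ndarray]] = []
    semi_all = [rng.uniform(lo, hi, 3) / voxel for _ in range(spec.n_lesions)]
    for i in range(spec.n_lesions):
        semi = semi_all[i]
        partner = i - 1 if (i % 2 == 1 and i // 2 < spec.n_confluent_pairs) else None
        for _ in range(_ATTEMPT_CAP):
            if partner is None:
                center = np.array([rng.uniform(0, s - 1) for s in shape])
            else:
                pc, ps = placed[partner]
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                gap = rng.uniform(0.7, 0.9) * (semi.max() + ps.max())
                center = pc + gap * u
            center = np.round(center)
            skip = {partner} if partner is not None else set()
            if not _inside_brain(center, semi, shape):
                continue
            if not _separated(center, semi, placed, skip):
                continue
            if partner is not None and not _pair_touches(
                    placed[partner][0], placed[partner][1], center, semi):
                continue
            placed.append((center, semi))
            break
        else:
            raise PhantomPlacementError(
                f"could not place lesion {i} within {_ATTEMPT_CAP} attempts; "
                "the spec is infeasible for this volume")
    return [(c.astype(int), s) for c, s in placed]


def _ellipsoid_mask(center, semi, shape):
    """Boolean mask and normalized squared distance field on a bounding box."""
    lo = np.maximum(0, np.floor(center - semi).astype(int) - 1)
    hi = np.minimum(np.asarray(shape), np.ceil(center + semi).astype(int) + 2)
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    return box, d


_SIX = ndimage.generate_binary_structure(3, 1)


def _pair_touches(c1, s1, c2, s2) -> bool:
    """Do the two rasterized ellipsoids form one 6-connected component?"""
    lo = np.floor(np.minimum(c1 - s1, c2 - s2)).astype(int) - 1
    span = np.ceil(np.maximum(c1 + s1, c2 + s2)).astype(int) + 2 - lo
    grids = np.ogrid[: span[0], : span[1], : span[2]]
    d1 = sum(((g - (c - l)) / s) ** 2 for g, c, l, s in zip(grids, c1, lo, s1))
    d2 = sum(((g - (c - l)) / s) ** 2 for g, c, l, s in zip(grids, c2, lo, s2))
    m1 = (d1 <= 1.0) & (d1 <= d2)
    m2 = (d2 <= 1.0) & (d2 < d1)
    if not (m1.any() and m2.any()):
        return False
    return bool((ndimage.binary_dilation(m1, _SIX) & m2).any())


def _label_grid(spec: PhantomSpec, lesions) -> np.ndarray:
    """Rasterize ellipsoids; overlap goes to the nearest (normalized) center,
    so the labels partition the union and each center keeps its own label."""
    shape = spec.volume_shape
    labels = np.zeros(shape, np.int32)
    best = np.full(shape, np.inf, np.float32)
    for k, (center, semi) in enumerate(lesions, start=1):
        box, d = _ellipsoid_mask(center, semi, shape)
        claim = (d <= 1.0) & (d < best[box])
        best[box] = np.where(claim, d, best[box])
        labels[box][claim] = k
    return labels


def _vein_voxels(center, semi, direction, offset, shape) -> np.ndarray:
    """Voxels of a 1-voxel-thick line through ``center + offset`` along
    ``direction``, clipped to slightly beyond the lesion boundary."""
    length = float(semi.max()) + 2.0
    ts = np.arange(-length, length + 0.125, 0.25)
    pts = np.round(center + offset + ts[:, None] * direction).astype(int)
    pts = pts[(pts >= 0).all(axis=1) & (pts < np.asarray(shape)).all(axis=1)]
    if len(pts) == 0:
        return pts
    d = (((pts - center) / semi) ** 2).sum(axis=1)
    return np.unique(pts[d <= 1.3], axis=0)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# generation

def generate_phantom(spec: PhantomSpec,
                     subject_id: str = "phantom") -> tuple[MultiContrastVolume, PhantomTruth]:
    """Generate one synthetic subject: four contrasts, brain mask, and truth."""
    spec.validate()
    shape = spec.volume_shape
    rng_place = np.random.default_rng([spec.seed, 1])
    rng_noise = np.random.default_rng([spec.seed, 2])
    rng_unsure = np.random.default_rng([spec.seed, 3])

    mask = _brain_mask(shape)
    lesions = _place_lesions(spec, rng_place)
    labels = _label_grid(spec, lesions)

    # biomarker assignment (independent draws; subsets may overlap)
    prl_ids = set(rng_place.choice(spec.n_lesions, spec.n_prl, replace=False).tolist()) \
        if spec.n_prl else set()
    cvs_ids = set(rng_place.choice(spec.n_lesions, spec.n_cvs, replace=False).tolist()) \
        if spec.n_cvs else set()
    eccentric = {i for i in range(spec.n_lesions)
                 if i not in cvs_ids and rng_place.random() < spec.eccentric_vein_fraction}

    # deterministic intensity template
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    norm_grids = np.meshgrid(*coords, indexing="ij", sparse=True)
    contrasts = {}
    for name in ("t1w", "flair", "epim", "epip"):
        g = np.full(shape, _BASELINE[name], np.float32)
        direction = _GRADIENT_DIRECTION[name]
        g += _GRADIENT_AMPLITUDE[name] * sum(
            d * x for d, x in zip(direction, norm_grids)).astype(np.float32)
        contrasts[name] = g

    lesion_mask = labels > 0
    contrasts["flair"][lesion_mask] += spec.lesion_flair_contrast
    contrasts["t1w"][lesion_mask] += spec.lesion_t1_contrast

    # PRL rims: 1-voxel shell on EPI phase
    for i in prl_ids:
        k = i + 1
        this = labels == k
        interior = ndimage.binary_erosion(this, _SIX)
        shell = this & ~interior
        contrasts["epip"][shell] += spec.rim_contrast

    # vein lines on EPI magnitude
    for i in range(spec.n_lesions):
        center, semi = lesions[i]
        if i in cvs_ids:
            offset = np.zeros(3)
        elif i in eccentric:
            offset = None  # computed below, perpendicular to the line
        else:
            continue
        u = rng_place.standard_normal(3)
        u /= np.linalg.norm(u)
        if offset is None:
            offset = _perpendicular(u) * 2.0
        vox = _vein_voxels(center.astype(float), semi, u, offset, shape)
        if len(vox):
            contrasts["epim"][vox[:, 0], vox[:, 1], vox[:, 2]] += spec.vein_contrast

    # free-floating background veins
    in_brain = np.argwhere(mask)
    for _ in range(spec.n_background_veins):
        start = in_brain[rng_place.integers(len(in_brain))]
        u = rng_place.standard_normal(3)
        u /= np.linalg.norm(u)
        ts = np.arange(0, rng_place.uniform(8, 18), 0.25)
        pts = np.round(start + ts[:, None] * u).astype(int)
        pts = pts[(pts >= 0).all(axis=1) & (pts < np.asarray(shape)).all(axis=1)]
        pts = np.unique(pts, axis=0)
        keep = mask[pts[:, 0], pts[:, 1], pts[:, 2]] & ~lesion_mask[pts[:, 0], pts[:, 1], pts[:, 2]]
        pts = pts[keep]
        contrasts["epim"][pts[:, 0], pts[:, 1], pts[:, 2]] += spec.vein_contrast

    # FLAIR-bright mimic foci (non-lesions)
    placed_all = [(c.astype(float), s) for c, s in lesions]
    for _ in range(spec.n_mimics):
        semi = np.full(3, rng_place.uniform(1.5, 2.5)) / np.asarray(spec.voxel_size_mm)
        for _ in range(_ATTEMPT_CAP):
            center = np.round(np.array([rng_place.uniform(0, s - 1) for s in shape]))
            if _inside_brain(center, semi, shape) and _separated(center, semi, placed_all, set()):
                break
        else:
            raise PhantomPlacementError("could not place mimic focus")
        placed_all.append((center, semi))
        box, d = _ellipsoid_mask(center, semi, shape)
        inside = d <= 1.0
        contrasts["flair"][box][inside] += spec.mimic_contrast
        contrasts["t1w"][box][inside] += spec.mimic_t1_contrast

    # noise inside the brain only (outside stays exactly zero, as after
    # skull stripping)
    if spec.noise_sd > 0:
        for name in ("t1w", "flair", "epim", "epip"):
            noise = rng_noise.normal(0.0, spec.noise_sd, shape).astype(np.float32)
            contrasts[name] += noise
    for name in ("t1w", "flair", "epim", "epip"):
        contrasts[name][~mask] = 0.0

    # truth records with observed-label codes
    records = []
    for i, (center, _) in enumerate(lesions):
        prl = int(i in prl_ids)
        cvs = int(i in cvs_ids)
        lesion_status = 1
        if spec.missing_lesion_labels and not (prl or cvs):
            lesion_status = MISSING
        cvs_status = MISSING if spec.missing_cvs_labels else cvs
        records.append(LesionRecord(
            lesion_id=i + 1, center=tuple(int(c) for c in center),
            prl=prl, cvs=cvs, lesion_status=lesion_status,
            prl_status=prl, cvs_status=cvs_status,
            eccentric_vein=i in eccentric))
    # "unsure" CVS: one seeded Bernoulli draw per CVS-eligible lesion
    # (observed CVS status), in lesion-id order
    eligible = [r for r in records if r.cvs_status != MISSING]
    if eligible:
        draws = rng_unsure.random(len(eligible))
        for r, d in zip(eligible, draws):
            if d < spec.unsure_cvs_fraction:
                r.cvs_status = UNSURE

    volume = MultiContrastVolume(
        t1w=contrasts["t1w"], flair=contrasts["flair"],
        epim=contrasts["epim"], epip=contrasts["epip"],
        brain_mask=mask, voxel_size_mm=spec.voxel_size_mm, subject_id=subject_id)
    truth = PhantomTruth(lesion_label_grid=labels, records=records, subject_id=subject_id)
    return volume, truth


def export_truth_table(truth: PhantomTruth, observed: bool = True) -> pd.DataFrame:
    """One row per lesion: subject, lesion_id, x, y, z, lesion, prl, cvs.

    With ``observed=True`` (the default) statuses carry the missing/unsure
    codes as they would in a gold-standard table ("0"/"1"/"NA"/"unsure");
    ``observed=False`` exports the uncensored ground truth for evaluation.
    """
    rows = []
    for r in truth.records:
        if observed:
            lesion, prl, cvs = r.lesion_status, r.prl_status, r.cvs_status
        else:
            lesion, prl, cvs = 1, r.prl, r.cvs
        rows.append({
            "subject": truth.subject_id, "lesion_id": r.lesion_id,
            "x": r.center[0], "y": r.center[1], "z": r.center[2],
            "lesion": STATUS_STRINGS[lesion],
            "prl": STATUS_STRINGS[prl],
            "cvs": STATUS_STRINGS[cvs],
        })
    return pd.DataFrame(rows, columns=["subject", "lesion_id", "x", "y", "z",
                                       "lesion", "prl", "cvs"])


def save_phantom(volume: MultiContrastVolume, truth: PhantomTruth,
                 out_dir: str | Path) -> Path:
    """Write contrasts + brain mask + truth label grid as NIfTI, truth as CSV."""
    from .preprocess import save_volume

    out_dir = Path(out_dir)
    save_volume(volume, out_dir)
    nib.save(nib.Nifti1Image(truth.lesion_label_grid.astype(np.int16), volume.affine),
             out_dir / "truth_labels.nii")
    export_truth_table(truth).to_csv(out_dir / "truth.csv", index=False)
    return out_dir
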