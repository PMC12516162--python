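"""Multi-contrast volume container, intensity normalization, and NIfTI I/O.

The pipeline consumes volumes that have already been bias-corrected,
co-registered to the EPI magnitude space, and skull-stripped; the only
intensity step performed here is z-normalization to a standard normal
distribution per contrast.  Normalization statistics are computed over the
brain mask only, and voxels outside the mask are zeroed, so patches near the
brain edge carry zeros — a consistent padding convention shared with patch
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "MultiContrastVolume",
    "DegenerateContrastError",
    "CONTRAST_NAMES",
    "z_normalize",
    "validate_geometry",
    "save_volume",
    "load_volume",
]

CONTRAST_NAMES = ("t1w", "flair", "epim", "epip")


class DegenerateContrastError(ValueError):
    """A contrast has (near-)zero variance within the brain mask."""


@dataclass
class MultiContrastVolume:
    """Four co-registered 3-D contrasts plus a brain mask for one subject."""

    t1w: np.ndarray
    flair: np.ndarray
    epim: np.ndarray
    epip: np.ndarray
    brain_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = "subject"
    affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])
        self.brain_mask = np.asarray(self.brain_mask, bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.brain_mask.shape

    def contrasts(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CONTRAST_NAMES}

    def stacked(self) -> np.ndarray:
        """Channel-first stack (4, D, H, W) in the fixed contrast order."""
        return np.stack([getattr(self, name) for name in CONTRAST_NAMES])


def z_normalize(volume: MultiContrastVolume, tol: float = 1e-8) -> MultiContrastVolume:
    """Normalize each contrast to mean 0 / sd 1 within the brain mask.

    Voxels outside the mask are set to 0.  Raises
    :class:`DegenerateContrastError` if a contrast is constant within the mask.
    Idempotent: re-applying to an already-normalized volume is a no-op (within
    floating-point tolerance).
    """
    mask = volume.brain_mask
    if not mask.any():
        raise ValueError("brain mask is empty")
    out = {}
    for name, grid in volume.contrasts().items():
        vals = grid[mask].astype(np.float64)
        sd = vals.std()
        if sd < tol:
            raise DegenerateContrastError(
                f"contrast {name!r} has zero variance within the brain mask")
        norm = np.zeros_like(grid, dtype=np.float32)
        norm[mask] = ((vals - vals.mean()) / sd).astype(np.float32)
        out[name] = norm
    return replace(volume, **out)


def validate_geometry(volume: MultiContrastVolume) -> list[dict]:
    """Report-only geometry checks: shape mismatches, empty mask, non-finite
    voxels (with an example coordinate).  Returns an empty list if clean."""
    report: list[dict] = []
    ref = volume.brain_mask.shape
    for name, grid in volume.contrasts().items():
        if grid.shape != ref:
            report.append({"check": "shape", "contrast": name,
                           "expected": ref, "found": grid.shape})
            continue
        bad = ~np.isfinite(grid)
        if bad.any():
            coord = tuple(int(c) for c in np.argwhere(bad)[0])
            report.append({"check": "finite", "contrast": name,
                           "n_bad": int(bad.sum()), "first_coordinate": coord})
    if not volume.brain_mask.any():
        report.append({"check": "mask", "detail": "brain mask is empty"})
    return report


# ---------------------------------------------------------------------------
# NIfTI I/O (affines preserved verbatim)

def save_volume(volume: MultiContrastVolume, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, grid in volume.contrasts().items():
        nib.save(nib.Nifti1Image(np.asarray(grid, np.float32), volume.affine),
                 out_dir / f"{name}.nii")
    nib.save(nib.Nifti1Image(volume.brain_mask.astype(np.uint8), volume.affine),
             out_dir / "brain_mask.nii")
    return out_dir


def load_volume(in_dir: str | Path, subject_id: str | None = None) -> MultiContrastVolume:
    in_dir = Path(in_dir)

    def _read(stem):
        for suffix in (".nii", ".nii.gz"):
            p = in_dir / (stem + suffix)
            if p.exists():
                return nib.load(p)
        raise FileNotFoundError(f"no {stem}.nii[.gz] in {in_dir}")

    imgs = {name: _read(name) for name in CONTRAST_NAMES}
    mask_img = _read("brain_mask")
    affine = mask_img.affine
    zooms = tuple(float(z) for z in mask_img.header.get_zooms()[:3])
    return MultiContrastVolume(
        **{name: np.asarray(img.dataobj, np.float32) for name, img in imgs.items()},
        brain_mask=np.asarray(mask_img.dataobj) > 0,
        voxel_size_mm=zooms,
        subject_id=subject_id or in_dir.name,
        affine=affine,
    )
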