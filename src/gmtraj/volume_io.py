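"""NIfTI I/O, the analysis mask, and the voxel-to-mm geometry contract.

Every map in one analysis shares a grid shape and affine; mm coordinates only
ever come from the affine (0-based voxel indices, RAS+ by default).  Reported
coordinates can be sign-flipped to an LPI-style convention for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GMMap",
    "AnalysisMask",
    "read_gm_map",
    "write_stat_map",
    "make_analysis_mask",
    "voxel_to_mm",
    "voxel_volume_ul",
]


def voxel_volume_ul(affine: np.ndarray) -> float:
    """Voxel volume in microliters (= mm^3) from the affine."""
    return float(abs(np.linalg.det(affine[:3, :3])))


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the affine)."""
    return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))


def voxel_to_mm(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map (possibly fractional) 0-based voxel indices to mm coordinates."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    out = ijk @ affine[:3, :3].T + affine[:3, 3]
    return out[0] if out.shape[0] == 1 else out


@dataclass
class GMMap:
    """One subject's modulated grey-matter volume map on the common grid."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return voxel_sizes_mm(self.affine)

    @property
    def voxel_volume_ul(self) -> float:
        return voxel_volume_ul(self.affine)


@dataclass
class AnalysisMask:
    """Binary analysis domain shared by all voxelwise statistics."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_ul(self) -> float:
        return voxel_volume_ul(self.affine)

    @property
    def volume_ul(self) -> float:
        return self.n_voxels * self.voxel_volume_ul

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return voxel_sizes_mm(self.affine)


def read_gm_map(path, subject_id: str | None = None, negatives: str = "error") -> GMMap:
    """Load a 3D GM map from NIfTI.

    Parameters
    ----------
    path
        NIfTI-1 file (.nii or .nii.gz).
    subject_id
        Defaults to the file stem.
    negatives
        "error" rejects maps with negative voxels, "clip" zeroes them.
    """
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {img.shape} in {path}")
    data = np.asarray(img.get_fdata(), dtype=float)
    if np.any(data < 0):
        if negatives == "clip":
            data = np.clip(data, 0, None)
        else:
            raise ValueError(f"negative GM values in {path}; pass negatives='clip' to zero them")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite GM values in {path}")
    if subject_id is None:
        subject_id = Path(str(path)).name.split(".")[0]
    return GMMap(data=data, affine=np.asarray(img.affine, dtype=float), subject_id=subject_id)


def write_stat_map(grid: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a 3D statistical (or GM) map as NIfTI-1; NaN is allowed.

    Data are stored in float64 so round-trips are bit exact.
    """
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError(f"expected a 3D grid, got shape {grid.shape}")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    img = nib.Nifti1Image(grid.astype(np.float64), affine)
    img.header.set_data_dtype(np.float64)
    path = Path(str(path))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_mask(mask: AnalysisMask | np.ndarray, affine_or_path, path=None) -> Path:
    """Write a binary mask as 8-bit NIfTI."""
    if isinstance(mask, AnalysisMask):
        data, affine = mask.data, mask.affine
        path = affine_or_path
    else:
        data, affine, path = mask, affine_or_path, path
    img = nib.Nifti1Image(np.asarray(data, dtype=np.uint8), np.asarray(affine, float))
    img.header.set_data_dtype(np.uint8)
    path = Path(str(path))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def check_same_grid(maps) -> None:
    """Ensure all maps share shape and affine (to 1e-6)."""
    first = maps[0]
    for m in maps[1:]:
        if m.data.shape != first.data.shape:
            raise ValueError(f"grid mismatch: {m.data.shape} vs {first.data.shape}")
        if not np.allclose(m.affine, first.affine, atol=1e-6):
            raise ValueError("affine mismatch across maps")


def make_analysis_mask(maps, mean_threshold: float = 0.05) -> AnalysisMask:
    """Mask = voxels whose mean GM across subjects exceeds ``mean_threshold``."""
    if len(maps) == 0:
        raise ValueError("need at least one map")
    check_same_grid(maps)
    mean = np.mean([m.data for m in maps], axis=0)
    mask = mean > mean_threshold
    if not mask.any():
        raise ValueError(f"empty mask: no voxel has mean GM > {mean_threshold}")
    return AnalysisMask(data=mask, affine=maps[0].affine.copy())
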