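"""Cluster-extent inference: labeling, the Monte-Carlo null, and cluster tables.

Family-wise error over the analysis mask is controlled the classic Monte-Carlo
way: simulate smooth Gaussian null fields on the same grid, apply the same
two-sided voxel threshold, and record the largest suprathreshold cluster per
iteration.  The extent threshold is the smallest cluster size whose null
exceedance probability falls below the family-wise alpha; real clusters must
meet both the voxel threshold and this size to survive.

Null fields are thresholded at Gaussian quantiles (the simulated fields are
Gaussian by construction); observed t maps use the Student-t critical value
from :mod:`gmtraj.robust_glm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume_io import AnalysisMask, voxel_to_mm, voxel_volume_ul

__all__ = [
    "ClusterParams",
    "NullClusterDistribution",
    "ClusterTable",
    "ExtentThreshold",
    "label_clusters",
    "simulate_null_max_clusters",
    "extent_threshold",
    "extract_cluster_table",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}

CLUSTER_COLUMNS = [
    "term",
    "polarity",
    "cluster_id",
    "size_voxels",
    "volume_ul",
    "com_x_mm",
    "com_y_mm",
    "com_z_mm",
    "peak_t",
    "peak_x_mm",
    "peak_y_mm",
    "peak_z_mm",
]


@dataclass
class ClusterParams:
    """Settings for voxel thresholding and the Monte-Carlo cluster null."""

    voxel_p_two_tailed: float = 0.005
    df: int = 39
    connectivity: int = 6
    alpha_fwe: float = 0.05
    n_iterations: int = 10_000
    smoothness_fwhm_mm: float = 4.7
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.voxel_p_two_tailed < 1:
            raise ValueError("voxel_p_two_tailed must be in (0,1)")
        if not 0 < self.alpha_fwe < 1:
            raise ValueError("alpha_fwe must be in (0,1)")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(f"connectivity must be one of {tuple(_CONNECTIVITY_RANK)}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.smoothness_fwhm_mm < 0:
            raise ValueError("smoothness must be >= 0")


@dataclass
class NullClusterDistribution:
    """Max suprathreshold cluster size per null iteration."""

    max_cluster_size: np.ndarray
    params: ClusterParams

    @property
    def n_iterations(self) -> int:
        return len(self.max_cluster_size)


@dataclass
class ExtentThreshold:
    size_voxels: int
    volume_ul: float


@dataclass
class ClusterTable:
    """Surviving clusters plus the labeled grid they came from."""

    table: pd.DataFrame
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.table)


def label_clusters(binary: np.ndarray, connectivity: int = 6):
    """Label 3D connected components; returns (labels, sizes).

    ``sizes[k]`` is the voxel count of label k+1; connectivity is 6 (faces),
    18 (+edges) or 26 (+corners).
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {tuple(_CONNECTIVITY_RANK)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(np.asarray(binary, dtype=bool), structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def simulate_null_max_clusters(mask: AnalysisMask, params: ClusterParams) -> NullClusterDistribution:
    """Monte-Carlo null distribution of the max cluster size under smoothness.

    Each iteration: white Gaussian field on the grid, smoothed to the requested
    FWHM, standardized to zero mean / unit variance within the mask, two-sided
    thresholded at the Gaussian quantile for ``voxel_p_two_tailed``, labeled
    per sign, and the largest cluster over both signs recorded.
    """
    from scipy.ndimage import gaussian_filter

    mask_arr = np.asarray(mask.data, dtype=bool)
    if not mask_arr.any():
        raise ValueError("empty mask")
    vs = float(np.mean(mask.voxel_size_mm))
    sigma_vox = _fwhm_to_sigma(params.smoothness_fwhm_mm) / vs
    z_crit = float(stats.norm.ppf(1.0 - params.voxel_p_two_tailed / 2.0))
    rng = np.random.default_rng([int(params.seed), 2])

    maxima = np.zeros(params.n_iterations, dtype=int)
    for i in range(params.n_iterations):
        f = rng.standard_normal(mask_arr.shape)
        if sigma_vox > 0:
            f = gaussian_filter(f, sigma=sigma_vox)
        vals = f[mask_arr]
        f_std = np.zeros_like(f)
        f_std[mask_arr] = (vals - vals.mean()) / vals.std()
        best = 0
        for supra in (f_std > z_crit, f_std < -z_crit):
            supra &= mask_arr
            if supra.any():
                _, sizes = label_clusters(supra, params.connectivity)
                if sizes.size:
                    best = max(best, int(sizes.max()))
        maxima[i] = best
    return NullClusterDistribution(max_cluster_size=maxima, params=params)


def extent_threshold(
    dist: NullClusterDistribution | np.ndarray,
    alpha_fwe: float = 0.05,
    voxel_volume: float | None = None,
) -> ExtentThreshold:
    """Smallest cluster size whose null exceedance probability is below alpha.

    A real cluster survives when its size is >= the returned threshold; ties
    (exceedance exactly alpha) resolve to the larger, conservative size.
    """
    if not 0 < alpha_fwe < 1:
        raise ValueError("alpha_fwe must be in (0,1)")
    if isinstance(dist, NullClusterDistribution):
        sizes = dist.max_cluster_size
        if voxel_volume is None:
            voxel_volume = float("nan")
    else:
        sizes = np.asarray(dist)
        if voxel_volume is None:
            voxel_volume = float("nan")
    n = len(sizes)
    if n == 0:
        raise ValueError("empty null distribution")
    sorted_sizes = np.sort(sizes)
    for s in range(1, int(sorted_sizes[-1]) + 2):
        exceed = (n - np.searchsorted(sorted_sizes, s, side="left")) / n
        if exceed < alpha_fwe:
            return ExtentThreshold(size_voxels=s, volume_ul=s * voxel_volume)
    raise RuntimeError("unreachable")


def extract_cluster_table(
    t_map: np.ndarray,
    t_threshold: float,
    extent_voxels: int,
    affine: np.ndarray,
    connectivity: int = 6,
    term: str = "",
    polarity: str = "",
) -> ClusterTable:
    """Threshold a sign-split t map, label, and keep clusters >= extent.

    ``t_map`` is NaN outside the mask / off-sign voxels; thresholding is on
    |t|.  Center of mass is the unweighted mean of member voxel centers,
    affine-mapped to mm; the peak is the voxel with largest |t|.
    """
    t_map = np.asarray(t_map, dtype=float)
    with np.errstate(invalid="ignore"):
        supra = np.abs(t_map) >= t_threshold
    supra &= np.isfinite(t_map)
    labels, sizes = label_clusters(supra, connectivity)
    vox_ul = voxel_volume_ul(affine)

    rows = []
    out_labels = np.zeros_like(labels)
    new_id = 0
    order = np.argsort(sizes)[::-1]  # biggest first
    for idx in order:
        size = int(sizes[idx])
        if size < extent_voxels:
            continue
        lab = idx + 1
        member = labels == lab
        new_id += 1
        out_labels[member] = new_id
        coords = np.argwhere(member)
        com = voxel_to_mm(affine, coords.mean(axis=0))
        tvals = t_map[member]
        peak_i = int(np.argmax(np.abs(tvals)))
        peak_mm = voxel_to_mm(affine, coords[peak_i])
        rows.append(
            {
                "term": term,
                "polarity": polarity,
                "cluster_id": new_id,
                "size_voxels": size,
                "volume_ul": size * vox_ul,
                "com_x_mm": com[0],
                "com_y_mm": com[1],
                "com_z_mm": com[2],
                "peak_t": float(tvals[peak_i]),
                "peak_x_mm": peak_mm[0],
                "peak_y_mm": peak_mm[1],
                "peak_z_mm": peak_mm[2],
            }
        )
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return ClusterTable(table=table, labels=out_labels)
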