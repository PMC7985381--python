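"""3D cell segmentation: thresholding, closing, small-particle removal, labeling.

Operates on intensity-inverted reconstructions (cells bright).  The chain is
min/max intensity thresholding, morphological closing with a ball element,
deletion of sub-cellular specks, and connected-component labeling with
deterministic raster-order label assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import ball

from .reconstruct import ReconVolume

__all__ = [
    "LabelVolume",
    "threshold_volume",
    "morph_close",
    "remove_small_particles",
    "label_components",
    "default_min_voxels",
    "segment_volume",
]

log = logging.getLogger(__name__)

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class LabelVolume:
    """Integer-labeled volume: 0 = background, 1..n_labels = cells, no gaps."""

    labels: np.ndarray  # (z, y, x) nonnegative integers
    n_labels: int
    voxel_pitch_um: float
    connectivity: int = 26

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")


def threshold_volume(
    volume: ReconVolume,
    t_min: float | None = None,
    t_max: float | None = None,
) -> np.ndarray:
    """Binary mask of voxels with intensity in [t_min, t_max].

    Defaults: t_min = Otsu threshold of the volume, t_max = volume maximum
    (the chosen values are logged).
    """
    data = volume.data
    if t_min is None:
        t_min = float(threshold_otsu(data))
        log.info("threshold_volume: Otsu t_min = %.6g", t_min)
    if t_max is None:
        t_max = float(data.max())
        log.info("threshold_volume: t_max = volume max = %.6g", t_max)
    if t_min >= t_max:
        raise ValueError("t_min must be < t_max")
    return (data >= t_min) & (data <= t_max)


def morph_close(mask: np.ndarray, radius_voxels: int = 1) -> np.ndarray:
    """3D dilation then erosion with a ball structuring element; radius 0 = identity."""
    if radius_voxels < 0 or int(radius_voxels) != radius_voxels:
        raise ValueError("radius must be a nonnegative integer")
    if radius_voxels == 0:
        return mask.copy()
    selem = ball(radius_voxels)
    dilated = ndimage.binary_dilation(mask, structure=selem)
    return ndimage.binary_erosion(dilated, structure=selem)


def remove_small_particles(mask: np.ndarray, min_voxels: int, connectivity: int = 26) -> np.ndarray:
    """Delete connected components smaller than ``min_voxels`` voxels."""
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    if min_voxels == 0:
        return mask.copy()
    labeled = sk_label(mask, connectivity=_CONNECTIVITY[_check_conn(connectivity)])
    counts = np.bincount(labeled.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return keep[labeled]


def _check_conn(connectivity: int) -> int:
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    return connectivity


def label_components(
    mask: np.ndarray,
    connectivity: int = 26,
    voxel_pitch_um: float = 5.0,
) -> LabelVolume:
    """Connected-component labeling with deterministic raster-scan ordering.

    Labels are renumbered so that label k is the k-th component encountered
    in a flat raster scan of the volume (first-voxel order), making the
    labeling independent of library internals.
    """
    labeled = sk_label(mask, connectivity=_CONNECTIVITY[_check_conn(connectivity)])
    n = int(labeled.max())
    if n:
        flat = labeled.ravel()
        vals, first_idx = np.unique(flat, return_index=True)
        vals, first_idx = vals[vals > 0], first_idx[vals > 0]
        remap = np.zeros(n + 1, dtype=labeled.dtype)
        remap[vals[np.argsort(first_idx, kind="stable")]] = np.arange(1, n + 1)
        labeled = remap[labeled]
    return LabelVolume(labels=labeled, n_labels=n,
                       voxel_pitch_um=voxel_pitch_um, connectivity=connectivity)


def default_min_voxels(voxel_pitch_um: float, min_diameter_um: float = 10.0) -> int:
    """Voxel count of a sphere of the given diameter — the smallest plausible cell."""
    r_vox = (min_diameter_um / 2.0) / voxel_pitch_um
    return max(1, int(round(4.0 / 3.0 * np.pi * r_vox**3)))


def segment_volume(
    volume: ReconVolume,
    t_min: float | None = None,
    t_max: float | None = None,
    close_radius: int = 1,
    min_voxels: int | None = None,
    connectivity: int = 26,
) -> LabelVolume:
    """Full segmentation chain: threshold → close → remove specks → label."""
    if min_voxels is None:
        min_voxels = default_min_voxels(volume.voxel_pitch_um)
        log.info("segment_volume: default min_voxels = %d", min_voxels)
    mask = threshold_volume(volume, t_min, t_max)
    mask = morph_close(mask, close_radius)
    mask = remove_small_particles(mask, min_voxels, connectivity)
    return label_components(mask, connectivity, volume.voxel_pitch_um)
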