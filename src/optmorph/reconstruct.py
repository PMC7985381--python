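"""Filtered back-projection reconstruction with center-of-rotation correction.

Parallel-beam geometry (telecentric illumination).  Projections are
rearranged into per-slice sinograms, the detector-column offset of the
rotation axis is corrected by a subpixel shift, and each slice is
reconstructed by frequency-domain ramp (optionally Hann-apodized) filtering
followed by back-projection.  A registration-based estimator recovers the
axis offset from opposed (θ, θ+180°) projection pairs when no manual value
is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import iradon

from .simulate import ProjectionStack

__all__ = [
    "ReconVolume",
    "build_sinograms",
    "sinograms_to_stack",
    "estimate_cor",
    "estimate_cor_stack",
    "fbp_reconstruct",
    "invert_intensity",
    "fov_mask",
]

FILTERS = {"ramp": "ramp", "hann": "hann", "none": None}


@dataclass
class ReconVolume:
    """3D scalar intensity volume with isotropic voxel pitch in µm."""

    data: np.ndarray  # (z, y, x); y and x extents equal the detector width
    voxel_pitch_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError("volume must be (z, y, x) with square slices")


def build_sinograms(stack: ProjectionStack) -> np.ndarray:
    """Rearrange (angle, row, column) into per-slice sinograms (row, angle, column)."""
    if stack.data.shape[0] == 0:
        raise ValueError("empty stack")
    return np.ascontiguousarray(np.transpose(stack.data, (1, 0, 2)))


def sinograms_to_stack(
    sinograms: np.ndarray,
    angles_deg: np.ndarray,
    pixel_pitch_um: float,
    modality: str = "bright_field",
) -> ProjectionStack:
    """Inverse of :func:`build_sinograms` (lossless permutation)."""
    data = np.ascontiguousarray(np.transpose(sinograms, (1, 0, 2)))
    return ProjectionStack(data, angles_deg, pixel_pitch_um, modality)


def _parabolic_refine(y: np.ndarray, k: int) -> float:
    """Subpixel peak position around integer argmax k of a 1D array."""
    if k <= 0 or k >= len(y) - 1:
        return float(k)
    denom = y[k - 1] - 2.0 * y[k] + y[k + 1]
    if denom == 0:
        return float(k)
    return k + 0.5 * (y[k - 1] - y[k + 1]) / denom


def estimate_cor(
    sinogram: np.ndarray,
    angles_deg: np.ndarray,
    angle_tol_deg: float = 1e-6,
) -> float:
    """Estimate the rotation-axis offset (px) from a single-slice sinogram.

    Each projection at θ is registered, by 1D cross-correlation with
    parabolic subpixel refinement, against the column-mirrored projection at
    θ+180°; the axis offset is half the correlation lag, relative to the
    back-projection center at column ``n // 2``.  The median over all
    opposed pairs is returned.
    """
    sinogram = np.asarray(sinogram, dtype=np.float64)
    angles_deg = np.asarray(angles_deg, dtype=np.float64)
    if sinogram.ndim != 2 or sinogram.shape[0] != len(angles_deg):
        raise ValueError("sinogram must be (n_angles, n_columns) matching angles_deg")
    n_cols = sinogram.shape[1]
    # mirroring p[::-1] reflects about column (n-1)/2; back-projection pivots
    # about n//2, hence the half-pixel bookkeeping term for even widths
    center_bias = (n_cols // 2) - (n_cols - 1) / 2.0

    opposed = {}
    for j, th in enumerate(angles_deg):
        opposed[round((th % 360.0) / max(angle_tol_deg, 1e-9))] = j
    estimates = []
    for i, th in enumerate(angles_deg):
        key = round(((th + 180.0) % 360.0) / max(angle_tol_deg, 1e-9))
        j = opposed.get(key)
        if j is None or j <= i:
            continue
        p = sinogram[i] - sinogram[i].mean()
        q = sinogram[j][::-1] - sinogram[j].mean()
        if not (np.any(p) and np.any(q)):
            continue
        cc = np.correlate(p, q, mode="full")
        k = int(np.argmax(cc))
        lag = _parabolic_refine(cc, k) - (n_cols - 1)
        estimates.append(lag / 2.0 - center_bias)
    if not estimates:
        raise ValueError("no 180°-opposed projection pairs available")
    return float(np.median(estimates))


def estimate_cor_stack(stack: ProjectionStack, n_slices: int = 5) -> float:
    """Median COR estimate over the highest-signal slices of a full stack."""
    sinos = build_sinograms(stack)
    energy = sinos.var(axis=(1, 2))
    rows = np.argsort(energy)[::-1][: min(n_slices, sinos.shape[0])]
    ests = []
    for r in rows:
        if energy[r] == 0:
            continue
        ests.append(estimate_cor(sinos[r], stack.angles_deg))
    if not ests:
        raise ValueError("stack has no usable (non-constant) slices")
    return float(np.median(ests))


def fbp_reconstruct(
    sinograms: np.ndarray,
    angles_deg: np.ndarray,
    cor_offset_px: float = 0.0,
    filter_name: str = "ramp",
    voxel_pitch_um: float = 5.0,
) -> ReconVolume:
    """Slice-wise filtered back-projection of per-slice sinograms.

    Columns are first shifted by −``cor_offset_px`` (linear interpolation) to
    move the rotation axis onto the detector center, then each slice is
    ramp-filtered and back-projected over all angles with π/N weighting.
    Voxels outside the inscribed field-of-view circle are set to 0 (their
    values are undefined in parallel-beam FBP).
    """
    if filter_name not in FILTERS:
        raise ValueError(f"filter_name must be one of {sorted(FILTERS)}")
    sinograms = np.asarray(sinograms, dtype=np.float64)
    angles_deg = np.asarray(angles_deg, dtype=np.float64)
    if sinograms.ndim != 3 or sinograms.shape[1] != len(angles_deg):
        raise ValueError("sinograms must be (n_slices, n_angles, n_columns)")
    n_slices, _, n_cols = sinograms.shape
    if cor_offset_px != 0.0:
        sinograms = ndimage.shift(
            sinograms, (0.0, 0.0, -cor_offset_px), order=1, mode="constant"
        )
    vol = np.empty((n_slices, n_cols, n_cols), dtype=np.float64)
    for z in range(n_slices):
        vol[z] = iradon(
            sinograms[z].T,
            theta=angles_deg,
            filter_name=FILTERS[filter_name],
            interpolation="linear",
            circle=True,
            output_size=n_cols,
        )
    return ReconVolume(
        data=vol,
        voxel_pitch_um=voxel_pitch_um,
        meta={"filter": filter_name, "cor_offset_px": float(cor_offset_px),
              "n_angles": int(len(angles_deg))},
    )


def fov_mask(shape_yx: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the inscribed reconstruction circle of a square slice."""
    n = shape_yx[0]
    c = (n - 1) / 2.0
    yy, xx = np.ogrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= (n / 2.0) ** 2


def invert_intensity(volume: ReconVolume) -> ReconVolume:
    """v → max(v) − v: attenuating cells become bright for segmentation."""
    data = volume.data
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite voxels")
    return ReconVolume(
        data=data.max() - data,
        voxel_pitch_um=volume.voxel_pitch_um,
        meta={**volume.meta, "inverted": True},
    )
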