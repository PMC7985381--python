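"""Per-cell shape descriptors, sample density, and live/dead viability.

Each labeled cell is summarized by its equivalent ellipsoid — the ellipsoid
whose second central moments match the cell's voxel distribution.  For a
continuous solid ellipsoid the covariance eigenvalue along a semi-axis a is
a²/5, so the reported radius is √(5λ) (per eigenvalue λ, scaled to µm): a
digitized ball of radius r then reports radius ≈ r.  The two shape indices
follow the standard radius-ratio definitions:

    elongation = R_largest / R_medium      (≫ 1 for spindle-shaped cells)
    flatness   = R_medium  / R_smallest    (≫ 1 for disk-like cells)

Sample-level quantities are the cell count per analysis volume (cells/mL),
the quantified-to-seeded density fraction, and viability
100·live/(live+dead) from the two fluorescence channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segment import LabelVolume

__all__ = [
    "CellRecord",
    "SampleMetrics",
    "fit_ellipsoid_radii",
    "elongation",
    "flatness",
    "cell_density",
    "density_fraction",
    "viability",
    "summarize_sample",
    "cylinder_volume_ml",
    "SHAPE_FLOOR_VOXELS",
]

UM3_PER_ML = 1e12

SHAPE_FLOOR_VOXELS = 8  # below this, second moments are too coarse for shape


@dataclass
class CellRecord:
    """Morphometrics of one labeled cell."""

    label_id: int
    centroid_um: tuple[float, float, float]  # (z, y, x)
    voxel_count: int
    volume_um3: float
    R_largest_um: float
    R_medium_um: float
    R_smallest_um: float
    elongation: float
    flatness: float
    shape_valid: bool


@dataclass
class SampleMetrics:
    """Sample-level summary for one reconstructed hydrogel volume."""

    n_cells: int
    analysis_volume_ml: float | None
    density_cells_per_ml: float | None
    elongation_median: float
    elongation_q1: float
    elongation_q3: float
    flatness_median: float
    flatness_q1: float
    flatness_q3: float
    group_label: str = ""
    viability_percent: float | None = None


def fit_ellipsoid_radii(
    voxel_coords: np.ndarray,
    voxel_pitch_um: float,
) -> tuple[tuple[float, float, float], bool]:
    """Equivalent-ellipsoid radii (µm, descending) of a voxel coordinate cloud.

    Radii are √5 × the square roots of the covariance eigenvalues of the
    voxel centers (with the pitch²/12 within-voxel variance added), which
    calibrates a digitized ball of radius r to report ≈ r.  Degenerate
    clouds (too few voxels, coplanar/collinear) return ``shape_valid=False``
    with the smallest radius floored at half a voxel.
    """
    coords = np.asarray(voxel_coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("voxel_coords must be (n, 3)")
    n = coords.shape[0]
    floor = voxel_pitch_um / 2.0
    if n < SHAPE_FLOOR_VOXELS:
        r = max(n, 1) ** (1 / 3) * floor
        return (r, r, r), False
    cov_raw = np.cov(coords.T, bias=True)
    # coplanar/collinear voxel sets have a (near-)zero raw eigenvalue
    valid = bool(np.sort(np.linalg.eigvalsh(cov_raw))[0] > 1e-9)
    eigvals = np.sort(np.linalg.eigvalsh(cov_raw + np.eye(3) / 12.0))[::-1]
    radii = np.sqrt(5.0 * np.clip(eigvals, 0.0, None)) * voxel_pitch_um
    radii = np.maximum(radii, floor)
    return (float(radii[0]), float(radii[1]), float(radii[2])), valid


def elongation(r_largest: float, r_medium: float) -> float:
    """Ratio of the largest to the medium equivalent-ellipsoid radius."""
    if r_medium <= 0:
        raise ValueError("R_medium must be positive")
    return r_largest / r_medium


def flatness(r_medium: float, r_smallest: float) -> float:
    """Ratio of the medium to the smallest equivalent-ellipsoid radius."""
    if r_smallest <= 0:
        raise ValueError("R_smallest must be positive")
    return r_medium / r_smallest


def cell_density(n_cells: int, analysis_volume_ml: float) -> float:
    """Cells per mL of analysis volume (exact ratio)."""
    if analysis_volume_ml <= 0:
        raise ValueError("analysis_volume_ml must be positive")
    return n_cells / analysis_volume_ml


def density_fraction(quantified_density: float, initial_density: float) -> int:
    """Quantified density as an integer percent of the seeded density."""
    if initial_density <= 0:
        raise ValueError("initial_density must be positive")
    return int(round(100.0 * quantified_density / initial_density))


def viability(n_live: int, n_dead: int) -> float:
    """Percent live cells, 100·live/(live+dead), to one decimal."""
    if n_live < 0 or n_dead < 0:
        raise ValueError("counts must be nonnegative")
    total = n_live + n_dead
    if total == 0:
        raise ValueError("no cells counted in either channel")
    return round(100.0 * n_live / total, 1)


def cylinder_volume_ml(radius_um: float, height_um: float) -> float:
    """Volume of a cylinder in mL (analysis volume of a tube section)."""
    return float(np.pi * radius_um**2 * height_um / UM3_PER_ML)


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """(median, Q1, Q3) with the linear-interpolation quantile convention."""
    if values.size == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def cell_table(label_volume: LabelVolume) -> pd.DataFrame:
    """One row of morphometrics per labeled cell, in label order."""
    labels = label_volume.labels
    pitch = label_volume.voxel_pitch_um
    records = []
    objects = ndimage.find_objects(labels)
    for k in range(1, label_volume.n_labels + 1):
        sl = objects[k - 1]
        if sl is None:
            continue
        sub = labels[sl] == k
        coords = np.argwhere(sub) + np.array([s.start for s in sl])
        n_vox = coords.shape[0]
        centroid = tuple((coords.mean(axis=0) + 0.5) * pitch)
        (r1, r2, r3), valid = fit_ellipsoid_radii(coords, pitch)
        records.append(dict(
            label_id=k,
            centroid_z_um=centroid[0], centroid_y_um=centroid[1], centroid_x_um=centroid[2],
            voxel_count=n_vox,
            volume_um3=n_vox * pitch**3,
            R_largest_um=r1, R_medium_um=r2, R_smallest_um=r3,
            elongation=elongation(r1, r2),
            flatness=flatness(r2, r3),
            shape_valid=valid,
        ))
    columns = ["label_id", "centroid_z_um", "centroid_y_um", "centroid_x_um",
               "voxel_count", "volume_um3", "R_largest_um", "R_medium_um",
               "R_smallest_um", "elongation", "flatness", "shape_valid"]
    if not records:
        df = pd.DataFrame(columns=columns)
        df["shape_valid"] = df["shape_valid"].astype(bool)
        return df
    return pd.DataFrame.from_records(records, columns=columns)


def summarize_sample(
    label_volume: LabelVolume,
    analysis_volume_ml: float | None = None,
    group_label: str = "",
    viability_percent: float | None = None,
) -> tuple[SampleMetrics, pd.DataFrame]:
    """Per-cell table plus sample summary (median/Q1/Q3 of shape indices)."""
    table = cell_table(label_volume)
    valid = table[table["shape_valid"]] if len(table) else table
    e_med, e_q1, e_q3 = _quartiles(valid["elongation"].to_numpy(dtype=float))
    f_med, f_q1, f_q3 = _quartiles(valid["flatness"].to_numpy(dtype=float))
    density = None
    if analysis_volume_ml is not None:
        density = cell_density(len(table), analysis_volume_ml)
    metrics = SampleMetrics(
        n_cells=len(table),
        analysis_volume_ml=analysis_volume_ml,
        density_cells_per_ml=density,
        elongation_median=e_med, elongation_q1=e_q1, elongation_q3=e_q3,
        flatness_median=f_med, flatness_q1=f_q1, flatness_q3=f_q3,
        group_label=group_label,
        viability_percent=viability_percent,
    )
    return metrics, table
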