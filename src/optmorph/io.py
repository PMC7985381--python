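"""Disk formats: multi-page TIFF stacks with JSON sidecar descriptors,
CSV cell tables, JSON truth scalars and reports."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import SampleMetrics
from .reconstruct import ReconVolume
from .segment import LabelVolume
from .simulate import PhantomTruth, ProjectionStack

__all__ = [
    "save_stack", "load_stack",
    "save_volume", "load_volume",
    "save_labels", "load_labels",
    "save_truth", "load_truth",
    "save_cell_table", "save_metrics",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_stack(path, stack: ProjectionStack, cor_offset_px: float = 0.0) -> None:
    """Projection stack as multi-page grayscale TIFF + JSON acquisition descriptor."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    desc = {
        "angles_deg": stack.angles_deg.tolist(),
        "pixel_pitch_um": stack.pixel_pitch_um,
        "modality": stack.modality,
        "cor_offset_px": cor_offset_px,
    }
    _sidecar(path).write_text(json.dumps(desc, indent=1))


def load_stack(path) -> tuple[ProjectionStack, dict]:
    path = Path(path)
    data = tifffile.imread(path).astype(np.float64)
    desc = json.loads(_sidecar(path).read_text())
    stack = ProjectionStack(
        data=data,
        angles_deg=np.asarray(desc["angles_deg"]),
        pixel_pitch_um=desc["pixel_pitch_um"],
        modality=desc.get("modality", "bright_field"),
    )
    return stack, desc


def save_volume(path, volume: ReconVolume) -> None:
    path = Path(path)
    tifffile.imwrite(path, volume.data.astype(np.float32))
    desc = {"voxel_pitch_um": volume.voxel_pitch_um, **volume.meta}
    _sidecar(path).write_text(json.dumps(desc, indent=1))


def load_volume(path) -> ReconVolume:
    path = Path(path)
    data = tifffile.imread(path).astype(np.float64)
    desc = json.loads(_sidecar(path).read_text())
    pitch = desc.pop("voxel_pitch_um")
    return ReconVolume(data=data, voxel_pitch_um=pitch, meta=desc)


def save_labels(path, label_volume: LabelVolume) -> None:
    path = Path(path)
    if label_volume.n_labels > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit storage")
    tifffile.imwrite(path, label_volume.labels.astype(np.uint16))
    desc = {
        "n_labels": label_volume.n_labels,
        "voxel_pitch_um": label_volume.voxel_pitch_um,
        "connectivity": label_volume.connectivity,
    }
    _sidecar(path).write_text(json.dumps(desc, indent=1))


def load_labels(path) -> LabelVolume:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    desc = json.loads(_sidecar(path).read_text())
    return LabelVolume(labels=labels, n_labels=desc["n_labels"],
                       voxel_pitch_um=desc["voxel_pitch_um"],
                       connectivity=desc.get("connectivity", 26))


def save_truth(csv_path, truth: PhantomTruth) -> None:
    """Ground truth as CSV (one row per cell) + JSON scalars alongside."""
    csv_path = Path(csv_path)
    truth.cells.to_csv(csv_path, index=False)
    scalars = {
        "n_cells": truth.n_cells,
        "analysis_cylinder_volume_ml": truth.analysis_cylinder_volume_ml,
        "realized_density_cells_per_ml": truth.realized_density_cells_per_ml
        if truth.n_cells else 0.0,
        "voxel_pitch_um": truth.voxel_pitch_um,
        "n_live": truth.n_live,
        "n_dead": truth.n_dead,
    }
    _sidecar(csv_path).write_text(json.dumps(scalars, indent=1))


def load_truth(csv_path) -> PhantomTruth:
    csv_path = Path(csv_path)
    cells = pd.read_csv(csv_path)
    scalars = json.loads(_sidecar(csv_path).read_text())
    return PhantomTruth(
        cells=cells,
        analysis_cylinder_volume_ml=scalars["analysis_cylinder_volume_ml"],
        voxel_pitch_um=scalars["voxel_pitch_um"],
    )


def save_cell_table(path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False)


def save_metrics(path, metrics: SampleMetrics) -> None:
    Path(path).write_text(json.dumps(asdict(metrics), indent=1))
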