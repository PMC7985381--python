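"""End-to-end runs: simulate → preprocess → reconstruct → segment → quantify.

A run is driven by a single config mapping (YAML/JSON-friendly) with stage
sub-sections; every stage writes its parameter record and the run manifest
captures seeds, parameters, and SHA-256 hashes of all outputs, so any
artifact is re-derivable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import io as mio
from .morphometry import summarize_sample, viability
from .preprocess import brightness_adjust, homomorphic_filter, median_filter_stack
from .reconstruct import (build_sinograms, estimate_cor_stack, fbp_reconstruct,
                          invert_intensity)
from .segment import segment_volume
from .simulate import (PhantomSpec, default_angles, add_noise,
                       apply_illumination_field, fluorescence_volumes,
                       forward_project, generate_phantom, sample_cells)

__all__ = ["run_pipeline", "make_fixtures", "PRESETS", "spec_from_config"]


# Scenario presets encoding the qualitative contrasts between hydrogel
# formulations: plain gellan gum keeps fibroblasts small and round;
# gelatin-functionalized GG supports elongated cells at higher density;
# Geltrex yields elongated, flattened cells.
PRESETS = {
    "gg_like": dict(
        seeded_density_cells_per_ml=300_000.0,
        semi_axis_range_um=(8.0, 12.0),
    ),
    "gelatin_gg_like": dict(
        seeded_density_cells_per_ml=500_000.0,
        semi_axis_range_um=(8.0, 30.0),
    ),
    "geltrex_like": dict(
        seeded_density_cells_per_ml=300_000.0,
        semi_axis_range_um=(6.0, 28.0),
    ),
    "cor_offset": dict(
        seeded_density_cells_per_ml=300_000.0,
        semi_axis_range_um=(8.0, 14.0),
        cor_offset_px=5.0,
    ),
}

_BASE_GEOMETRY = dict(
    volume_shape_voxels=(96, 96, 96),
    voxel_pitch_um=5.0,
    tube_inner_diameter_um=400.0,
)

DENSITY_SWEEP_LEVELS = (300_000.0, 500_000.0, 1_000_000.0)
DEAD_FRACTION_SWEEP = (0.0, 0.2, 0.4)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def spec_from_config(cfg: dict, seed: int) -> PhantomSpec:
    """PhantomSpec from a config sub-section plus the run seed."""
    fields = {**_BASE_GEOMETRY, **cfg}
    fields.setdefault("rng_seed", seed)
    if "volume_shape_voxels" in fields:
        fields["volume_shape_voxels"] = tuple(fields["volume_shape_voxels"])
    if "semi_axis_range_um" in fields:
        fields["semi_axis_range_um"] = tuple(fields["semi_axis_range_um"])
    return PhantomSpec(**fields)


def make_fixtures(preset_name: str, seed: int, out_dir=None,
                  n_projections: int = 400):
    """Projection-stack fixtures with known ground truth for a named scenario.

    Returns ``{name: (stack, truth, spec)}``; with ``out_dir`` set, each
    fixture is also written as TIFF + JSON descriptor + truth CSV.
    """
    angles = default_angles(n_projections)
    fixtures = {}

    def _simulate(name: str, spec: PhantomSpec):
        vol, truth = generate_phantom(spec)
        stack = forward_project(vol, angles, spec.cor_offset_px, spec.voxel_pitch_um)
        if spec.illumination_amplitude > 0:
            stack = apply_illumination_field(stack, spec.illumination_amplitude,
                                             rng_seed=spec.rng_seed)
        if spec.noise_scale > 0:
            stack = add_noise(stack, spec.noise_scale, rng_seed=spec.rng_seed + 1)
        fixtures[name] = (stack, truth, spec)

    if preset_name in PRESETS:
        _simulate(preset_name, spec_from_config(dict(PRESETS[preset_name]), seed))
    elif preset_name == "density_sweep":
        for i, dens in enumerate(DENSITY_SWEEP_LEVELS):
            spec = spec_from_config(
                dict(seeded_density_cells_per_ml=dens,
                     semi_axis_range_um=(8.0, 14.0)), seed + i)
            _simulate(f"density_{int(dens/1000)}k", spec)
    elif preset_name == "dead_fraction_sweep":
        for i, frac in enumerate(DEAD_FRACTION_SWEEP):
            spec = spec_from_config(
                dict(seeded_density_cells_per_ml=500_000.0,
                     semi_axis_range_um=(8.0, 14.0),
                     dead_fraction=frac, dead_contrast_factor=0.05), seed + i)
            _simulate(f"dead_{int(round(frac*100))}pct", spec)
    else:
        raise ValueError(f"unknown preset {preset_name!r}")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, (stack, truth, spec) in fixtures.items():
            mio.save_stack(out_dir / f"{name}.tiff", stack, spec.cor_offset_px)
            mio.save_truth(out_dir / f"{name}_truth.csv", truth)
    return fixtures


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Execute a full run from a config mapping; returns the manifest dict.

    Config keys:
      modality: "brightfield" | "fluorescence"
      phantom:  PhantomSpec overrides (simulation input)
      preprocess / reconstruct / segment: stage parameter overrides
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    modality = config.get("modality", "brightfield")
    if modality not in ("brightfield", "fluorescence"):
        raise ValueError("modality must be 'brightfield' or 'fluorescence'")
    pre_cfg = config.get("preprocess", {})
    rec_cfg = config.get("reconstruct", {})
    seg_cfg = config.get("segment", {})
    spec = spec_from_config(config.get("phantom", {}), seed)
    angles = default_angles(int(config.get("n_projections", 400)))
    manifest: dict = {"seed": seed, "modality": modality,
                      "config": json.loads(json.dumps(config, default=str)),
                      "stages": {}, "outputs": {}}

    def _reconstruct_and_count(stack, tag: str):
        cor_mode = rec_cfg.get("cor", "auto")
        cor = estimate_cor_stack(stack) if cor_mode == "auto" else float(cor_mode)
        filt = rec_cfg.get("filter", "ramp")
        recon = fbp_reconstruct(build_sinograms(stack), stack.angles_deg,
                                cor_offset_px=cor, filter_name=filt,
                                voxel_pitch_um=stack.pixel_pitch_um)
        # post-log projections reconstruct attenuation directly: cells are
        # already bright, so no intensity inversion is needed before
        # segmentation (inversion applies to intensity-domain recon only)
        labels = segment_volume(
            recon,
            t_min=seg_cfg.get("t_min"), t_max=seg_cfg.get("t_max"),
            close_radius=int(seg_cfg.get("close_radius", 1)),
            min_voxels=seg_cfg.get("min_voxels"),
            connectivity=int(seg_cfg.get("connectivity", 26)),
        )
        mio.save_volume(out_dir / f"recon_{tag}.tiff", recon)
        mio.save_labels(out_dir / f"labels_{tag}.tiff", labels)
        manifest["stages"][f"reconstruct_{tag}"] = {"cor_offset_px": cor, "filter": filt}
        return labels

    truth = sample_cells(spec)
    mio.save_truth(out_dir / "truth.csv", truth)
    analysis_volume = spec.cylinder_volume_ml

    if modality == "brightfield":
        from .simulate import rasterize_cells
        vol = rasterize_cells(truth, spec.volume_shape_voxels, spec.voxel_pitch_um,
                              spec.cell_contrast,
                              spec.cell_contrast * spec.dead_contrast_factor)
        stack = forward_project(vol, angles, spec.cor_offset_px, spec.voxel_pitch_um)
        if spec.illumination_amplitude > 0:
            stack = apply_illumination_field(stack, spec.illumination_amplitude,
                                             rng_seed=spec.rng_seed)
        if spec.noise_scale > 0:
            stack = add_noise(stack, spec.noise_scale, rng_seed=spec.rng_seed + 1)
        mio.save_stack(out_dir / "projections.tiff", stack, spec.cor_offset_px)
        if spec.illumination_amplitude > 0:
            stack = homomorphic_filter(
                stack,
                cutoff_freq=float(pre_cfg.get("cutoff_freq", 0.02)),
                low_gain=float(pre_cfg.get("low_gain", 0.3)),
                high_gain=float(pre_cfg.get("high_gain", 1.0)),
            )
            manifest["stages"]["preprocess"] = {"homomorphic": True}
        labels = _reconstruct_and_count(stack, "bf")
        metrics, table = summarize_sample(labels, analysis_volume, group_label="brightfield")
    else:
        live_vol, dead_vol = fluorescence_volumes(truth, spec)
        counts = {}
        live_labels = None
        for tag, vol in (("live", live_vol), ("dead", dead_vol)):
            if not np.any(vol):  # empty channel: nothing to reconstruct
                counts[tag] = 0
                continue
            stack = forward_project(vol, angles, spec.cor_offset_px,
                                    spec.voxel_pitch_um,
                                    modality=f"fluor_{tag}")
            if spec.noise_scale > 0:
                stack = add_noise(stack, spec.noise_scale, rng_seed=spec.rng_seed + 1)
            stack = median_filter_stack(stack, int(pre_cfg.get("median_window", 3)))
            if np.ptp(stack.data) > 0:
                stack = brightness_adjust(stack)
            mio.save_stack(out_dir / f"projections_{tag}.tiff", stack, spec.cor_offset_px)
            labels = _reconstruct_and_count(stack, tag)
            counts[tag] = labels.n_labels
            if tag == "live":
                live_labels = labels
        viab = viability(counts["live"], counts["dead"])
        if live_labels is None:
            from .segment import LabelVolume
            live_labels = LabelVolume(
                labels=np.zeros(spec.volume_shape_voxels, dtype=np.int32),
                n_labels=0, voxel_pitch_um=spec.voxel_pitch_um)
        metrics, table = summarize_sample(live_labels, analysis_volume,
                                          group_label="fluorescence",
                                          viability_percent=viab)

    mio.save_cell_table(out_dir / "cells.csv", table)
    mio.save_metrics(out_dir / "metrics.json", metrics)
    for p in sorted(out_dir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
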