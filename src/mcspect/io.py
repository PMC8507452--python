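"""File formats and experiment configuration.

Volumes are written as NIfTI (.nii / .nii.gz) or MetaImage (.mha) with
the voxel spacing in mm; projection sets as a .npz archive (frames plus
angles) with a JSON metadata sidecar embedded in the archive; experiment
configurations round-trip through YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .projections import ProjectionSet
from .volume import VoxelVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_projections",
    "load_projections",
    "ExperimentConfig",
]


def save_volume(volume: VoxelVolume, path) -> Path:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([*volume.spacing, 1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.values, affine), str(path))
    elif path.suffix == ".mha":
        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return path


def load_volume(path) -> VoxelVolume:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        origin = tuple(affine[:3, 3])
        return VoxelVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)
    if path.suffix == ".mha":
        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).T
        return VoxelVolume(
            np.ascontiguousarray(values), tuple(img.GetSpacing()), tuple(img.GetOrigin())
        )
    raise ValueError(f"unsupported volume format: {path.name}")


def save_projections(projections: ProjectionSet, path) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        raise ValueError("projection sets are stored as .npz archives")
    meta = {
        "orbit_radius_mm": projections.orbit_radius_mm,
        "pixel_size_mm": projections.pixel_size_mm,
        **projections.meta,
    }
    frames = projections.frames
    if projections.meta.get("mode") == "poisson":
        frames = frames.astype(np.int64)  # counts are integers, store losslessly
    np.savez_compressed(
        path, frames=frames, angles_deg=projections.angles_deg, meta=json.dumps(meta)
    )
    return path


def load_projections(path) -> ProjectionSet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        frames = np.asarray(data["frames"], dtype=float)
        angles = data["angles_deg"]
    if len(frames) != len(angles):
        raise ValueError("corrupt projection archive: frame/angle count mismatch")
    orbit = meta.pop("orbit_radius_mm")
    pixel = meta.pop("pixel_size_mm")
    return ProjectionSet(frames, angles, orbit, pixel, meta)


@dataclass
class ExperimentConfig:
    """Serializable description of a full simulation + reconstruction run."""

    experiment: str = "resolution"  # or "lesion"
    seed: int = 1
    n_seeds: int = 3
    grid_size: int = 64
    grid_slices: int = 32
    voxel_mm: float = 4.42
    n_projections: int = 60
    n_histories: int = 2_000_000
    mc_histories_per_subset: int = 100_000
    medium: str = "water"
    output_dir: str = "results"
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("malformed experiment configuration")
        return cls(**data)
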