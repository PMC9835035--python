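"""NIfTI volume I/O and YAML configuration round-tripping.

Volumes travel as NIfTI-1 files (the de facto standard for this data
class), one file per channel with ``_ip`` / ``_op`` / ``_fat`` / ``_water``
/ ``_labels`` suffixes. Voxel spacing rides in the NIfTI header; affine and
orientation metadata are carried through untouched on read-modify-write.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .fields import DixonChannels, ScalarField3D
from .phantom import LabelMap, PhantomSpec, SwapSpec, TissueRegion

__all__ = [
    "read_volume",
    "write_volume",
    "write_channels",
    "read_channels",
    "write_labels",
    "read_labels",
    "phantom_spec_to_yaml",
    "phantom_spec_from_yaml",
]

CHANNEL_SUFFIXES = ("ip", "op", "fat", "water")


def read_volume(path: str | Path) -> ScalarField3D:
    """Read a 3D NIfTI volume; values and voxel spacing are preserved."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: missing or non-positive voxel spacing {spacing}")
    return ScalarField3D(np.asarray(data, dtype=np.float64), spacing)


def write_volume(field: ScalarField3D, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a field as NIfTI-1; spacing goes into the header zooms."""
    if affine is None:
        affine = np.diag(list(field.spacing) + [1.0])
    img = nib.Nifti1Image(field.values.astype(np.float32), affine)
    img.header.set_zooms(field.spacing)
    nib.save(img, str(path))


def write_channels(channels: DixonChannels, directory: str | Path, stem: str) -> list[Path]:
    """Write the four channels as ``<stem>_<suffix>.nii.gz`` files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for suffix in CHANNEL_SUFFIXES:
        p = directory / f"{stem}_{suffix}.nii.gz"
        write_volume(getattr(channels, suffix), p)
        paths.append(p)
    return paths


def read_channels(directory: str | Path, stem: str) -> DixonChannels:
    directory = Path(directory)
    fields = {s: read_volume(directory / f"{stem}_{s}.nii.gz") for s in CHANNEL_SUFFIXES}
    return DixonChannels(**fields)


def write_labels(labels: LabelMap, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int16), np.diag(list(spacing) + [1.0]))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_labels(path: str | Path) -> LabelMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got shape {data.shape}")
    return LabelMap(np.asarray(np.rint(data), dtype=np.int32))


# ---------------------------------------------------------------------------
# PhantomSpec <-> YAML
# ---------------------------------------------------------------------------

def phantom_spec_to_yaml(spec: PhantomSpec) -> str:
    d = asdict(spec)
    d["shape"] = list(spec.shape)
    d["spacing"] = list(spec.spacing)
    d["regions"] = [
        {
            **asdict(r),
            "center": list(r.center),
            "semi_axes": list(r.semi_axes),
            "fat_fraction_range": (
                None if r.fat_fraction_range is None else list(r.fat_fraction_range)
            ),
        }
        for r in spec.regions
    ]
    d["swap_specs"] = [
        {**asdict(s), "center": list(s.center)} for s in spec.swap_specs
    ]
    return yaml.safe_dump(d, sort_keys=False)


def phantom_spec_from_yaml(text: str) -> PhantomSpec:
    d = yaml.safe_load(text)
    regions = tuple(
        TissueRegion(
            geometry=r["geometry"],
            center=tuple(r["center"]),
            semi_axes=tuple(r["semi_axes"]),
            fat_fraction=float(r["fat_fraction"]),
            intensity=float(r["intensity"]),
            fat_fraction_range=(
                None if r.get("fat_fraction_range") is None
                else tuple(r["fat_fraction_range"])
            ),
        )
        for r in d["regions"]
    )
    swaps = tuple(
        SwapSpec(**{**s, "center": tuple(s.get("center", (0.0, 0.0, 0.0)))})
        for s in d.get("swap_specs", [])
    )
    return PhantomSpec(
        shape=tuple(d["shape"]),
        regions=regions,
        spacing=tuple(d.get("spacing", (2.2, 2.2, 3.0))),
        noise_sigma=float(d.get("noise_sigma", 0.0)),
        texture_amp=float(d.get("texture_amp", 0.0)),
        texture_scale=float(d.get("texture_scale", 5.0)),
        swap_specs=swaps,
        seed=int(d.get("seed", 0)),
    )
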