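"""Readers and writers shared by all stages (NIfTI volumes, CSV tables).

Volumes round-trip through NIfTI-1 with the voxel spacing carried in the
header zooms; masks are written as uint8 NIfTI grids. Missing or degenerate
spacing metadata is an error — spacing is never silently assumed to be 1 mm.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CTVolume, RegionMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "canonicalize",
    "read_table",
    "write_table",
]


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write HU grid + spacing as NIfTI-1; axis order is preserved."""
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.hu.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)
    return path


def read_volume(path: str | Path, slice_axis: int = 0) -> CTVolume:
    """Read a NIfTI volume; spacing comes from the header zooms."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if len(zooms) != 3 or any(
        z is None or not np.isfinite(float(z)) or float(z) <= 0 for z in zooms
    ):
        raise ValueError(
            f"{path}: voxel spacing missing or non-positive in NIfTI header ({zooms}); "
            "refusing to assume 1 mm"
        )
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return CTVolume(hu=data, spacing=tuple(float(z) for z in zooms), slice_axis=slice_axis)


def write_mask(mask: RegionMask, spacing: tuple[float, float, float], path: str | Path) -> Path:
    path = Path(path)
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, path)
    return path


def read_mask(path: str | Path, role: str = "") -> RegionMask:
    img = nib.load(str(path))
    return RegionMask(np.asarray(img.get_fdata()) > 0.5, role=role)


def canonicalize(volume: CTVolume, declared_slice_axis: int) -> CTVolume:
    """Move the declared cranio-caudal axis to axis 0, permuting spacing too."""
    if declared_slice_axis == 0:
        return CTVolume(hu=volume.hu, spacing=volume.spacing, slice_axis=0)
    order = [declared_slice_axis] + [a for a in range(3) if a != declared_slice_axis]
    hu = np.transpose(volume.hu, order)
    spacing = tuple(volume.spacing[a] for a in order)
    return CTVolume(hu=hu, spacing=spacing, slice_axis=0)


#: Feature-group tags accepted in feature-table CSV headers (``tag__name``).
KNOWN_TAGS = ("clinical", "agatston", "fatomics")


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path)
    return path


def read_table(path: str | Path, check_tags: bool = False) -> pd.DataFrame:
    """Read a CSV table; optionally validate ``tag__feature`` column names."""
    frame = pd.read_csv(path, index_col=0)
    if check_tags:
        for col in frame.columns:
            if "__" in col:
                tag = col.split("__", 1)[0]
                if tag not in KNOWN_TAGS:
                    raise ValueError(
                        f"column {col!r} carries unknown feature tag {tag!r}; "
                        f"expected one of {KNOWN_TAGS}"
                    )
    return frame
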