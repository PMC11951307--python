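"""Shared containers for CT volumes and region masks.

Conventions used throughout the package: voxel indices are 0-based; world
coordinates are millimetres, computed as ``index * spacing``; masks are boolean
arrays aligned voxel-for-voxel to their volume; axis 0 of every grid is the
cranio-caudal (slice) axis unless a ``CTVolume`` declares otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: HU threshold above which a voxel can belong to a calcium lesion.
CALCIUM_HU_THRESHOLD = 130.0

#: Adipose HU window [low, high] used for EAT intensity features.
ADIPOSE_WINDOW = (-190.0, -30.0)

ARTERIES = ("LM", "LAD", "LCX", "RCA")

#: Arteries in which positive remodeling is assessed (left main excluded).
PR_ARTERIES = ("LAD", "LCX", "RCA")

SEGMENT_REGIONS = ("proximal", "mid", "distal")


class AlignmentError(ValueError):
    """A mask and volume do not share the same grid."""


@dataclass(frozen=True)
class CTVolume:
    """A 3-D Hounsfield-unit grid with anisotropic voxel spacing.

    Parameters
    ----------
    hu
        3-D array of Hounsfield units.
    spacing
        Voxel spacing in mm, ordered like the array axes.
    slice_axis
        Index of the cranio-caudal axis (default 0).
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 0

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=np.float64)
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if hu.ndim != 3:
            raise ValueError(f"expected a 3-D HU grid, got ndim={hu.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be three positive mm values, got {self.spacing}")
        if not np.all(np.isfinite(hu)):
            raise ValueError("HU grid contains non-finite values")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape  # type: ignore[return-value]

    @property
    def slice_thickness(self) -> float:
        return self.spacing[self.slice_axis]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def in_plane_area(self) -> float:
        """Area of one voxel face perpendicular to the slice axis, in mm^2."""
        axes = [a for a in range(3) if a != self.slice_axis]
        return self.spacing[axes[0]] * self.spacing[axes[1]]


@dataclass(frozen=True)
class RegionMask:
    """A boolean grid aligned to a :class:`CTVolume`.

    ``role`` documents what the region is: ``"pericardium"``, ``"eat"`` or one
    of the artery territory names in :data:`ARTERIES`.
    """

    mask: np.ndarray
    role: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            mask = mask.astype(bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={mask.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.mask.sum())

    def check_aligned(self, volume: CTVolume) -> None:
        if self.shape != volume.shape:
            raise AlignmentError(
                f"mask {self.role!r} has shape {self.shape}, volume has shape {volume.shape}"
            )


def require_aligned(volume: CTVolume, *masks: RegionMask) -> None:
    for m in masks:
        m.check_aligned(volume)
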