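"""Epicardial fat ("fat-omics") feature extraction.

Epicardial adipose tissue (EAT) is the fat enclosed by the pericardium. From a
CT volume and an EAT mask this module computes three feature families:

* **morphological** — EAT volume, principal axis lengths, mean/max fat
  thickness;
* **intensity** — min/max/mean HU, skewness, and HU-histogram bin
  probabilities over the adipose window;
* **spatial** — the same histogram probabilities computed within spatial
  partitions of the EAT: four equally thick cranio-caudal *slabs* of slices,
  and concentric *ribbons* of equal distance-to-pericardial-boundary width
  running from the outer surface inward.

Spatial feature names follow the ``SR{k}_Pro_{a}_{b}`` convention: the
probability that an EAT voxel in ribbon ``k`` (1 = outermost) has HU in
``[-a, -b)``; slab features are named ``SL{k}_Pro_{a}_{b}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import ADIPOSE_WINDOW, CTVolume, RegionMask, require_aligned

__all__ = [
    "EATGeometry",
    "FatomicsVector",
    "assign_slabs_ribbons",
    "extract_features",
    "fat_thickness",
    "default_bin_edges",
    "feature_names",
]

N_SLABS = 4
DEFAULT_N_RIBBONS = 5


class EmptyEATError(ValueError):
    """The EAT mask contains no voxels."""


def default_bin_edges(
    window: tuple[float, float] = ADIPOSE_WINDOW, width: float = 20.0
) -> np.ndarray:
    """Histogram bin edges over the adipose window (default 20-HU bins)."""
    lo, hi = window
    return np.arange(lo, hi + 0.5 * width, width)


def _bin_name(lo: float, hi: float) -> str:
    # [-170, -150) -> "Pro_170_150": absolute HU bounds, outer first
    return f"Pro_{abs(int(lo))}_{abs(int(hi))}"


@dataclass(frozen=True)
class EATGeometry:
    """EAT voxels with their slab and ribbon partition indices.

    ``slab`` and ``ribbon`` are integer grids aligned to the masks, zero
    outside the EAT; inside, slabs run 1 (top) .. 4 (bottom) and ribbons
    1 (outermost) .. ``n_ribbons`` (innermost).
    """

    eat: RegionMask
    pericardium: RegionMask
    slab: np.ndarray
    ribbon: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int
    n_ribbons: int

    def __post_init__(self) -> None:
        eat = self.eat.mask
        for name, arr in (("slab", self.slab), ("ribbon", self.ribbon)):
            if arr.shape != eat.shape:
                raise ValueError(f"{name} grid shape {arr.shape} != EAT shape {eat.shape}")
            if np.any((arr > 0) != eat):
                raise ValueError(f"{name} indices must be positive exactly on EAT voxels")


def assign_slabs_ribbons(
    eat: RegionMask,
    pericardium: RegionMask,
    spacing: tuple[float, float, float],
    n_ribbons: int = DEFAULT_N_RIBBONS,
    slice_axis: int = 0,
) -> EATGeometry:
    """Partition EAT voxels into cranio-caudal slabs and radial ribbons.

    Slabs split the occupied EAT slice range into four equal-thickness bands,
    slab 1 at the top. Ribbons are equal-width bands of Euclidean distance (in
    mm) from the pericardial boundary, measured inside the pericardium;
    ribbon 1 is the outermost band.
    """
    if eat.count() == 0:
        raise EmptyEATError("EAT mask is empty")
    if eat.shape != pericardium.shape:
        raise ValueError(f"EAT shape {eat.shape} != pericardium shape {pericardium.shape}")
    if np.any(eat.mask & ~pericardium.mask):
        raise ValueError("EAT mask is not contained in the pericardium mask")
    if n_ribbons < 1:
        raise ValueError(f"n_ribbons must be >= 1, got {n_ribbons}")

    eat_m = eat.mask

    # Slabs: quarters of the occupied slice range along the cranio-caudal axis.
    occupied = np.flatnonzero(eat_m.any(axis=tuple(a for a in range(3) if a != slice_axis)))
    zmin, zmax = int(occupied[0]), int(occupied[-1])
    n_slices = zmax - zmin + 1
    z = np.arange(eat_m.shape[slice_axis])
    slab_of_slice = np.minimum((z - zmin) * N_SLABS // max(n_slices, 1), N_SLABS - 1) + 1
    shape_ones = [1, 1, 1]
    shape_ones[slice_axis] = -1
    slab = np.where(eat_m, slab_of_slice.reshape(shape_ones), 0).astype(np.int32)

    # Ribbons: Euclidean distance (mm) to the nearest non-pericardium voxel,
    # binned into equal-width bands over the depth range the EAT occupies
    # (the minimum is ~one voxel, not 0, since boundary voxels sit a voxel
    # away from the nearest exterior voxel).
    depth = ndimage.distance_transform_edt(pericardium.mask, sampling=spacing)
    d = depth[eat_m]
    d_min, d_max = float(d.min()), float(d.max())
    if d_max <= d_min:
        idx = np.ones(d.shape, dtype=np.int32)
    else:
        scaled = (d - d_min) / (d_max - d_min) * n_ribbons
        idx = np.minimum(scaled.astype(np.int32), n_ribbons - 1) + 1
    ribbon = np.zeros(eat_m.shape, dtype=np.int32)
    ribbon[eat_m] = idx

    return EATGeometry(
        eat=eat,
        pericardium=pericardium,
        slab=slab,
        ribbon=ribbon,
        spacing=tuple(float(s) for s in spacing),
        slice_axis=slice_axis,
        n_ribbons=int(n_ribbons),
    )


@dataclass(frozen=True)
class FatomicsVector:
    """Named fat-omics features with per-family tags."""

    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values)


def _hist_probs(hu: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    if hu.size == 0:
        return np.zeros(len(bin_edges) - 1)
    counts, _ = np.histogram(hu, bins=bin_edges)
    return counts / hu.size


def feature_names(
    n_ribbons: int = DEFAULT_N_RIBBONS, bin_edges: np.ndarray | None = None
) -> list[str]:
    """The stable, ordered schema of the fat-omics vector."""
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges)
    bins = [_bin_name(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    names = [
        "volume_mm3",
        "principal_axis_1_mm",
        "principal_axis_2_mm",
        "principal_axis_3_mm",
        "mean_thickness_mm",
        "max_thickness_mm",
        "hu_min",
        "hu_max",
        "hu_mean",
        "hu_skewness",
    ]
    names += [b for b in bins]
    names += [f"SR{k}_{b}" for k in range(1, n_ribbons + 1) for b in bins]
    names += [f"SL{k}_{b}" for k in range(1, N_SLABS + 1) for b in bins]
    return names


def extract_features(
    volume: CTVolume,
    geometry: EATGeometry,
    bin_edges: np.ndarray | None = None,
) -> FatomicsVector:
    """Compute the full morphological + intensity + spatial feature vector.

    Probability features of an empty ribbon or slab are emitted as 0 with a
    warning rather than NaN, so downstream models never see missing values
    caused by partition geometry.
    """
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D array")
    require_aligned(volume, geometry.eat)

    eat_m = geometry.eat.mask
    hu = volume.hu[eat_m]
    spacing = np.asarray(geometry.spacing)
    bins = [_bin_name(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]

    feats: dict[str, float] = {}

    # --- morphological ---
    feats["volume_mm3"] = float(eat_m.sum() * np.prod(spacing))
    coords_mm = np.argwhere(eat_m) * spacing  # voxel centres in mm
    centered = coords_mm - coords_mm.mean(axis=0)
    if coords_mm.shape[0] > 1:
        cov = np.cov(centered, rowvar=False)
        eigvals = np.sort(np.clip(np.linalg.eigvalsh(cov), 0, None))[::-1]
    else:
        eigvals = np.zeros(3)
    for i, ev in enumerate(eigvals, start=1):
        feats[f"principal_axis_{i}_mm"] = float(4.0 * np.sqrt(ev))
    mean_t, max_t = fat_thickness(geometry)
    feats["mean_thickness_mm"] = mean_t
    feats["max_thickness_mm"] = max_t

    # --- intensity ---
    feats["hu_min"] = float(hu.min())
    feats["hu_max"] = float(hu.max())
    feats["hu_mean"] = float(hu.mean())
    feats["hu_skewness"] = float(stats.skew(hu)) if hu.size > 2 else 0.0
    for b, p in zip(bins, _hist_probs(hu, edges)):
        feats[b] = float(p)

    # --- spatial: ribbons then slabs ---
    for prefix, index_grid, n_parts in (
        ("SR", geometry.ribbon, geometry.n_ribbons),
        ("SL", geometry.slab, N_SLABS),
    ):
        for k in range(1, n_parts + 1):
            part_hu = volume.hu[index_grid == k]
            if part_hu.size == 0:
                warnings.warn(
                    f"empty partition {prefix}{k}: probability features set to 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
            for b, p in zip(bins, _hist_probs(part_hu, edges)):
                feats[f"{prefix}{k}_{b}"] = float(p)

    return FatomicsVector(values=feats)


def fat_thickness(
    geometry: EATGeometry, angular_step_deg: float = 1.0
) -> tuple[float, float]:
    """Mean and max radial EAT thickness (mm) by per-slice ray casting.

    For every slice containing EAT, rays are cast from the pericardial
    centroid of that slice at ``angular_step_deg`` increments; the thickness
    along a ray is the length of its intersection with the EAT band. The mean
    is taken over rays that hit EAT; the max over all rays and slices.
    """
    eat_m = np.moveaxis(geometry.eat.mask, geometry.slice_axis, 0)
    peri_m = np.moveaxis(geometry.pericardium.mask, geometry.slice_axis, 0)
    sp = list(geometry.spacing)
    sp_inplane = np.array([sp[a] for a in range(3) if a != geometry.slice_axis])

    if geometry.eat.count() == 1:
        # degenerate band: one voxel's in-plane extent by convention
        t = float(sp_inplane.mean())
        return t, t

    angles = np.deg2rad(np.arange(0.0, 360.0, angular_step_deg))
    directions = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    step = 0.25 * sp_inplane.min()

    per_ray: list[float] = []
    max_t = 0.0
    for k in np.flatnonzero(eat_m.reshape(eat_m.shape[0], -1).any(axis=1)):
        sl_eat = eat_m[k]
        source = peri_m[k] if peri_m[k].any() else sl_eat
        centroid = np.argwhere(source).mean(axis=0) * sp_inplane
        extent = np.array(sl_eat.shape) * sp_inplane
        max_r = float(np.linalg.norm(extent))
        n_steps = int(max_r / step) + 1
        radii = (np.arange(n_steps) + 0.5) * step
        for d in directions:
            pts = centroid + radii[:, None] * d
            ij = np.floor(pts / sp_inplane).astype(int)
            valid = (
                (ij[:, 0] >= 0)
                & (ij[:, 0] < sl_eat.shape[0])
                & (ij[:, 1] >= 0)
                & (ij[:, 1] < sl_eat.shape[1])
            )
            inside = np.zeros(n_steps, dtype=bool)
            inside[valid] = sl_eat[ij[valid, 0], ij[valid, 1]]
            t = float(inside.sum()) * step
            if t > 0:
                per_ray.append(t)
                max_t = max(max_t, t)
    mean_t = float(np.mean(per_ray)) if per_ray else 0.0
    return mean_t, max_t
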