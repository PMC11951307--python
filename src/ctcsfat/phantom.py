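"""Voxel phantoms: synthetic CT volumes with pericardium/EAT/lesion masks.

The phantom is deliberately simple geometry — an ellipsoidal "pericardium"
whose outer shell carries epicardial fat, plus spherical calcium lesions
assigned to artery territories — but it exercises every imaging operator in
the package: Agatston lesion detection, slab/ribbon partitioning, and the
fat-omics intensity features. It makes no attempt at cardiac anatomy, gating
or scanner noise.

Rasterization rule: a voxel belongs to a sphere/ellipsoid iff its *centre*
(index * spacing, in mm) lies inside the surface. The same rule is used by
the brute-force test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ADIPOSE_WINDOW, ARTERIES, CTVolume, RegionMask

__all__ = ["LesionSpec", "PhantomSpec", "Phantom", "generate_phantom"]


@dataclass(frozen=True)
class LesionSpec:
    """A spherical calcium lesion inside one artery territory.

    ``peak_hu`` is the HU at the lesion centre; with ``hu_profile="uniform"``
    the whole sphere carries ``peak_hu``, with ``"radial-falloff"`` the HU
    falls linearly to the calcium threshold (130) at the surface. A
    ``peak_hu`` below 130 is allowed only as a deliberate negative control
    (``allow_subthreshold=True``).
    """

    artery: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_hu: float
    hu_profile: str = "uniform"
    allow_subthreshold: bool = False

    def __post_init__(self) -> None:
        if self.artery not in ARTERIES:
            raise ValueError(f"artery must be one of {ARTERIES}, got {self.artery!r}")
        if self.radius_mm <= 0:
            raise ValueError(f"lesion radius must be positive, got {self.radius_mm}")
        if self.hu_profile not in ("uniform", "radial-falloff"):
            raise ValueError(f"unknown hu_profile {self.hu_profile!r}")
        if self.peak_hu < 130 and not self.allow_subthreshold:
            raise ValueError(
                f"lesion peak HU {self.peak_hu} is below the 130 HU calcium threshold; "
                "set allow_subthreshold=True for negative-control lesions"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom volume.

    ``eat_hu_mixture`` is a list of ``(mean_hu, sd_hu, weight)`` Gaussian
    components, truncated to the adipose window, from which EAT voxel HU
    values are drawn; weights must sum to 1 and means must lie inside the
    window. ``eat_fraction`` is the fraction of pericardial-shell voxels
    assigned to EAT (the rest stay at ``background_hu``).
    """

    grid_shape: tuple[int, int, int] = (24, 48, 48)
    voxel_spacing: tuple[float, float, float] = (3.0, 0.68, 0.68)
    pericardium_center_mm: tuple[float, float, float] | None = None
    pericardium_semiaxes_mm: tuple[float, float, float] = (30.0, 14.0, 14.0)
    shell_thickness_mm: float = 4.0
    eat_fraction: float = 1.0
    eat_hu_mixture: tuple[tuple[float, float, float], ...] = (
        (-100.0, 20.0, 0.7),
        (-60.0, 15.0, 0.3),
    )
    lesions: tuple[LesionSpec, ...] = ()
    background_hu: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive integers, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing}")
        if not (0.0 < self.eat_fraction <= 1.0):
            raise ValueError(f"eat_fraction must be in (0, 1], got {self.eat_fraction}")
        if self.shell_thickness_mm <= 0:
            raise ValueError("shell_thickness_mm must be positive")
        weights = [w for _, _, w in self.eat_hu_mixture]
        if not np.isclose(sum(weights), 1.0):
            raise ValueError(f"eat_hu_mixture weights must sum to 1, got {sum(weights)}")
        lo, hi = ADIPOSE_WINDOW
        for mean, sd, _ in self.eat_hu_mixture:
            if not (lo <= mean <= hi):
                raise ValueError(
                    f"mixture mean {mean} HU outside the adipose window [{lo}, {hi}]"
                )
            if sd <= 0:
                raise ValueError(f"mixture sd must be positive, got {sd}")

    @property
    def center_mm(self) -> np.ndarray:
        if self.pericardium_center_mm is not None:
            return np.asarray(self.pericardium_center_mm, dtype=float)
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing) / 2.0


@dataclass(frozen=True)
class Phantom:
    """Generated phantom: volume plus all region masks."""

    volume: CTVolume
    pericardium: RegionMask
    eat: RegionMask
    territories: dict[str, RegionMask]


def _voxel_centers_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _truncated_mixture_sample(
    rng: np.random.Generator,
    n: int,
    mixture: tuple[tuple[float, float, float], ...],
    window: tuple[float, float],
) -> np.ndarray:
    """Draw n HU values from a Gaussian mixture truncated to the window."""
    from scipy.stats import truncnorm

    lo, hi = window
    weights = np.array([w for _, _, w in mixture])
    comp = rng.choice(len(mixture), size=n, p=weights / weights.sum())
    out = np.empty(n)
    for i, (mean, sd, _) in enumerate(mixture):
        sel = comp == i
        k = int(sel.sum())
        if k == 0:
            continue
        a, b = (lo - mean) / sd, (hi - mean) / sd
        out[sel] = truncnorm.rvs(a, b, loc=mean, scale=sd, size=k, random_state=rng)
    return out


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a phantom volume and its masks from a spec.

    Deterministic for a fixed spec (the seed lives in the spec): the same
    spec always produces bit-identical output. Raises if a lesion centre lies
    outside the grid or if lesions of different arteries overlap (their
    territory assignment would be ambiguous).
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.voxel_spacing)
    rng = np.random.default_rng(spec.seed)

    zz, yy, xx = _voxel_centers_mm(shape, spacing)
    center = spec.center_mm
    semi = np.asarray(spec.pericardium_semiaxes_mm, dtype=float)

    # pericardium interior: ellipsoid; EAT candidates: outer shell of it
    norm_out = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    peri = norm_out <= 1.0
    inner_semi = np.maximum(semi - spec.shell_thickness_mm, 1e-6)
    norm_in = (
        ((zz - center[0]) / inner_semi[0]) ** 2
        + ((yy - center[1]) / inner_semi[1]) ** 2
        + ((xx - center[2]) / inner_semi[2]) ** 2
    )
    shell = peri & (norm_in > 1.0)

    if spec.eat_fraction >= 1.0:
        eat = shell
    else:
        eat = shell & (rng.random(shape) < spec.eat_fraction)

    hu = np.full(shape, spec.background_hu, dtype=np.float64)
    n_eat = int(eat.sum())
    if n_eat:
        hu[eat] = _truncated_mixture_sample(rng, n_eat, spec.eat_hu_mixture, ADIPOSE_WINDOW)

    grid_extent = np.asarray(shape) * np.asarray(spacing)
    territory_masks = {a: np.zeros(shape, dtype=bool) for a in ARTERIES}
    claimed = np.full(shape, -1, dtype=np.int8)  # which lesion claimed a voxel
    for li, lesion in enumerate(spec.lesions):
        c = np.asarray(lesion.center_mm, dtype=float)
        if np.any(c < 0) or np.any(c > grid_extent):
            raise ValueError(
                f"lesion {li} ({lesion.artery}) centre {tuple(c)} mm is outside the "
                f"grid extent {tuple(grid_extent)} mm"
            )
        r2 = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        inside = r2 <= lesion.radius_mm**2
        overlap = inside & (claimed >= 0)
        if overlap.any():
            other = spec.lesions[int(claimed[overlap][0])]
            if other.artery != lesion.artery:
                raise ValueError(
                    f"lesions of arteries {other.artery} and {lesion.artery} overlap: "
                    "territory assignment is ambiguous"
                )
        claimed[inside] = li
        territory_masks[lesion.artery] |= inside
        if lesion.hu_profile == "uniform":
            hu[inside] = lesion.peak_hu
        else:
            r = np.sqrt(r2[inside])
            frac = 1.0 - r / lesion.radius_mm
            hu[inside] = 130.0 + (lesion.peak_hu - 130.0) * frac

    # territories include a margin so lesion detection sees whole components
    volume = CTVolume(hu=hu, spacing=spacing, slice_axis=0)
    return Phantom(
        volume=volume,
        pericardium=RegionMask(peri, role="pericardium"),
        eat=RegionMask(eat & ~(claimed >= 0), role="eat"),
        territories={a: RegionMask(m, role=a) for a, m in territory_masks.items()},
    )
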