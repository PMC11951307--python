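"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ctcsfat.core import CTVolume, RegionMask


# ---------------------------------------------------------------------------
# independent Agatston oracle: per-voxel enumeration with BFS components in a
# deliberately different traversal order from the engine's labelling
# ---------------------------------------------------------------------------

def _weight(peak_hu: float) -> int:
    if peak_hu >= 400:
        return 4
    if peak_hu >= 300:
        return 3
    if peak_hu >= 200:
        return 2
    return 1


def brute_force_agatston(
    volume: CTVolume,
    territory: RegionMask,
    threshold: float = 130.0,
    min_area_mm2: float = 1.0,
) -> float:
    """Total Agatston score by exhaustive voxel enumeration (slice-wise BFS)."""
    hu = np.moveaxis(volume.hu, volume.slice_axis, 0)
    mask = np.moveaxis(territory.mask, volume.slice_axis, 0)
    area = volume.in_plane_area()
    thickness_factor = volume.slice_thickness / 3.0
    neighbours = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]

    total = 0.0
    for k in range(hu.shape[0]):
        cand = mask[k] & (hu[k] >= threshold)
        seen = np.zeros_like(cand)
        # traverse in reversed raster order: independent of skimage labelling
        for i in range(cand.shape[0] - 1, -1, -1):
            for j in range(cand.shape[1] - 1, -1, -1):
                if not cand[i, j] or seen[i, j]:
                    continue
                stack = [(i, j)]
                seen[i, j] = True
                comp = []
                while stack:
                    ci, cj = stack.pop()
                    comp.append((ci, cj))
                    for di, dj in neighbours:
                        ni, nj = ci + di, cj + dj
                        if (
                            0 <= ni < cand.shape[0]
                            and 0 <= nj < cand.shape[1]
                            and cand[ni, nj]
                            and not seen[ni, nj]
                        ):
                            seen[ni, nj] = True
                            stack.append((ni, nj))
                comp_area = len(comp) * area
                if comp_area < min_area_mm2:
                    continue
                peak = max(hu[k][c] for c in comp)
                total += comp_area * _weight(peak) * thickness_factor
    return total


def random_calcium_volume(rng: np.random.Generator, shape=(4, 12, 12), spacing=(3.0, 0.5, 0.5)):
    """A small random volume + territory with scattered supra-threshold blobs."""
    hu = rng.normal(40.0, 20.0, size=shape)
    n_seeds = rng.integers(1, 6)
    for _ in range(n_seeds):
        k = rng.integers(0, shape[0])
        i = rng.integers(0, shape[1])
        j = rng.integers(0, shape[2])
        h = rng.uniform(140.0, 900.0)
        r = rng.integers(1, 4)
        hu[k, max(i - r, 0) : i + r, max(j - r, 0) : j + r] = h
    territory = rng.random(shape) < 0.85
    return (
        CTVolume(hu=hu, spacing=spacing),
        RegionMask(territory, role="LAD"),
    )


@pytest.fixture(scope="session")
def small_cohort_frame():
    """A 400-patient default cohort, shared across tests (read-only)."""
    from ctcsfat.cohort import CohortSpec, cohort_to_frame, generate_cohort

    records = generate_cohort(CohortSpec(n_patients=400, seed=11))
    return cohort_to_frame(records)


@pytest.fixture(scope="session")
def shell_phantom():
    """Lesion-free phantom with a clean ellipsoidal EAT shell."""
    from ctcsfat.phantom import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(seed=5))
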