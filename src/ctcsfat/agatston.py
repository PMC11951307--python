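"""Agatston coronary calcium scoring and derived score features.

The Agatston score of a lesion is (lesion area in mm^2) x (density weight),
where the weight is 1/2/3/4 for a peak attenuation of 130-199 / 200-299 /
300-399 / >=400 HU. Lesions are 2-D connected components of supra-threshold
voxels found slice by slice inside an artery territory; scores are rescaled by
``slice_thickness / 3`` so that acquisitions with non-3-mm slices score on the
standard scale. Per-vessel scores are summed over LM, LAD, LCX and RCA into a
panel of derived features: log10(score + 1) transforms, a diffusivity index
measuring how spread out the calcium is across vessels, and a high-CAC flag
for a total score strictly above 1,000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .core import ARTERIES, CALCIUM_HU_THRESHOLD, CTVolume, RegionMask, require_aligned

__all__ = [
    "AgatstonConfig",
    "CalciumLesion",
    "ScorePanel",
    "find_lesions",
    "score_panel",
    "score_volume",
]

#: (HU lower bound, weight) bands; evaluated from highest to lowest.
DENSITY_BANDS = ((400.0, 4), (300.0, 3), (200.0, 2), (130.0, 1))


@dataclass(frozen=True)
class AgatstonConfig:
    """Knobs of the scoring rule; defaults are the standard algorithm."""

    hu_threshold: float = CALCIUM_HU_THRESHOLD
    min_area_mm2: float = 1.0
    connectivity: int = 2  # skimage 2-D connectivity: 2 == 8-neighbour
    reference_thickness_mm: float = 3.0


def density_weight(peak_hu: float, config: AgatstonConfig | None = None) -> int:
    """Return the 1-4 Agatston density weight for a lesion's peak HU."""
    cfg = config or AgatstonConfig()
    if peak_hu < cfg.hu_threshold:
        raise ValueError(f"peak HU {peak_hu} below the lesion threshold {cfg.hu_threshold}")
    for lower, weight in DENSITY_BANDS:
        if peak_hu >= lower:
            return weight
    return 1  # unreachable: peak_hu >= threshold >= 130


@dataclass(frozen=True)
class CalciumLesion:
    """One per-slice connected calcium component inside an artery territory."""

    artery: str
    slice_index: int
    voxel_count: int
    area_mm2: float
    peak_hu: float
    weight: int
    score: float

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"negative Agatston lesion score {self.score}")
        if self.weight not in (1, 2, 3, 4):
            raise ValueError(f"density weight must be 1-4, got {self.weight}")


@dataclass(frozen=True)
class ScorePanel:
    """Per-patient Agatston-derived feature vector.

    ``diffusivity_index`` is 1 minus the ratio of the most affected vessel's
    score to the total; 0 when a single vessel carries all calcium (or none),
    approaching 1 - 1/k when k vessels share it equally. ``high_cac`` flags a
    total strictly greater than 1,000.
    """

    scores: dict[str, float]
    total: float
    log_scores: dict[str, float]
    log_total: float
    diffusivity_index: float
    high_cac: bool

    def as_feature_dict(self) -> dict[str, float]:
        """Flatten into the Agatston feature columns used by the classifier."""
        out: dict[str, float] = {}
        for artery in ARTERIES:
            out[f"{artery}_agatston"] = self.scores[artery]
        out["total_agatston"] = self.total
        for artery in ARTERIES:
            out[f"log_{artery}_agatston"] = self.log_scores[artery]
        out["log_total_agatston"] = self.log_total
        out["diffusivity_index"] = self.diffusivity_index
        out["high_cac"] = float(self.high_cac)
        return out


#: Ordered names of the 12 Agatston-derived features.
AGATSTON_FEATURE_NAMES = tuple(
    [f"{a}_agatston" for a in ARTERIES]
    + ["total_agatston"]
    + [f"log_{a}_agatston" for a in ARTERIES]
    + ["log_total_agatston", "diffusivity_index", "high_cac"]
)


def find_lesions(
    volume: CTVolume,
    territory: RegionMask,
    config: AgatstonConfig | None = None,
    artery: str | None = None,
) -> list[CalciumLesion]:
    """Detect calcium lesions of one artery territory, slice by slice.

    A lesion is a 2-D connected component (8-connectivity by default) of
    territory voxels with HU >= the threshold; components smaller than
    ``min_area_mm2`` are discarded.
    """
    cfg = config or AgatstonConfig()
    require_aligned(volume, territory)
    artery = artery or territory.role or "?"

    hu = np.moveaxis(volume.hu, volume.slice_axis, 0)
    mask = np.moveaxis(territory.mask, volume.slice_axis, 0)
    area_per_voxel = volume.in_plane_area()
    thickness_factor = volume.slice_thickness / cfg.reference_thickness_mm

    lesions: list[CalciumLesion] = []
    candidate = mask & (hu >= cfg.hu_threshold)
    for k in np.flatnonzero(candidate.reshape(candidate.shape[0], -1).any(axis=1)):
        labels = measure.label(candidate[k], connectivity=cfg.connectivity)
        for comp in range(1, labels.max() + 1):
            sel = labels == comp
            n_vox = int(sel.sum())
            area = n_vox * area_per_voxel
            if area < cfg.min_area_mm2:
                continue
            peak = float(hu[k][sel].max())
            w = density_weight(peak, cfg)
            lesions.append(
                CalciumLesion(
                    artery=artery,
                    slice_index=int(k),
                    voxel_count=n_vox,
                    area_mm2=float(area),
                    peak_hu=peak,
                    weight=w,
                    score=float(area * w * thickness_factor),
                )
            )
    return lesions


def score_panel(lesions_by_artery: dict[str, list[CalciumLesion]]) -> ScorePanel:
    """Aggregate per-artery lesions into the derived feature panel.

    Arteries absent from the mapping score 0. Accepts either lesion lists or
    pre-summed per-artery scores (floats) as values.
    """
    unknown = set(lesions_by_artery) - set(ARTERIES)
    if unknown:
        raise ValueError(f"unknown arteries {sorted(unknown)}; expected {ARTERIES}")

    scores: dict[str, float] = {}
    for artery in ARTERIES:
        entry = lesions_by_artery.get(artery, [])
        if isinstance(entry, (int, float)):
            s = float(entry)
        else:
            s = float(sum(lesion.score for lesion in entry))
        if s < 0:
            raise ValueError(f"negative Agatston score {s} for {artery}")
        scores[artery] = s

    total = float(sum(scores.values()))
    log_scores = {a: float(np.log10(s + 1.0)) for a, s in scores.items()}
    diffusivity = 1.0 - max(scores.values()) / total if total > 0 else 0.0
    return ScorePanel(
        scores=scores,
        total=total,
        log_scores=log_scores,
        log_total=float(np.log10(total + 1.0)),
        diffusivity_index=float(diffusivity),
        high_cac=bool(total > 1000.0),
    )


def score_volume(
    volume: CTVolume,
    territories: dict[str, RegionMask],
    config: AgatstonConfig | None = None,
) -> ScorePanel:
    """Convenience: lesion detection plus panel aggregation for one scan."""
    lesions = {
        artery: find_lesions(volume, territory, config, artery=artery)
        for artery, territory in territories.items()
    }
    return score_panel(lesions)
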