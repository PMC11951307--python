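"""Remodeling index and positive-remodeling (PR) labels.

Positive remodeling is outward expansion of the vessel wall at a plaque: the
maximum outer diameter over the plaque exceeds the mean of the reference
diameters immediately proximal and distal to it by more than 10%, i.e. the
remodeling index (RI) is strictly greater than 1.1. PR is assessed per segment
(proximal/mid/distal of LAD, LCX and RCA); a patient is PR-positive if any
segment is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PR_ARTERIES, SEGMENT_REGIONS

__all__ = ["DiameterProfile", "PRLabel", "remodeling_index", "patient_label", "RI_THRESHOLD"]

#: RI above which (strictly) a segment shows positive remodeling.
RI_THRESHOLD = 1.1


@dataclass(frozen=True)
class DiameterProfile:
    """Outer-diameter samples (mm) along one coronary segment.

    ``plaque_span``, ``proximal_ref`` and ``distal_ref`` are half-open index
    intervals ``(start, stop)`` into ``diameters``; the reference intervals
    must be non-empty and disjoint from the plaque span.
    """

    artery: str
    region: str
    diameters: np.ndarray
    plaque_span: tuple[int, int]
    proximal_ref: tuple[int, int]
    distal_ref: tuple[int, int]

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        object.__setattr__(self, "diameters", d)
        if self.artery not in PR_ARTERIES:
            raise ValueError(f"PR is assessed in {PR_ARTERIES}, got artery {self.artery!r}")
        if self.region not in SEGMENT_REGIONS:
            raise ValueError(f"region must be one of {SEGMENT_REGIONS}, got {self.region!r}")
        if d.ndim != 1 or d.size == 0:
            raise ValueError("diameters must be a non-empty 1-D array")
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("diameters must be finite and strictly positive")
        for name, (a, b) in (
            ("plaque_span", self.plaque_span),
            ("proximal_ref", self.proximal_ref),
            ("distal_ref", self.distal_ref),
        ):
            if not (0 <= a < b <= d.size):
                raise ValueError(f"{name} interval ({a}, {b}) is empty or out of bounds")
        p = self.plaque_span
        for name, ref in (("proximal_ref", self.proximal_ref), ("distal_ref", self.distal_ref)):
            if max(p[0], ref[0]) < min(p[1], ref[1]):
                raise ValueError(f"{name} overlaps the plaque span")

    @property
    def segment_id(self) -> tuple[str, str]:
        return (self.artery, self.region)


@dataclass(frozen=True)
class PRLabel:
    """Per-segment remodeling indices plus segment- and patient-level labels."""

    remodeling_index: dict[tuple[str, str], float]
    pr_segment: dict[tuple[str, str], bool]
    pr_patient: bool


def remodeling_index(profile: DiameterProfile) -> float:
    """Max plaque-site outer diameter over the mean of the two reference means.

    The plaque-site diameter is summarised by the maximum over the plaque
    span; the reference diameter is the mean of the proximal-interval mean and
    the distal-interval mean.
    """
    d = profile.diameters
    plaque_max = float(d[slice(*profile.plaque_span)].max())
    prox_mean = float(d[slice(*profile.proximal_ref)].mean())
    dist_mean = float(d[slice(*profile.distal_ref)].mean())
    return plaque_max / ((prox_mean + dist_mean) / 2.0)


def patient_label(profiles: list[DiameterProfile]) -> PRLabel:
    """Label every segment and roll up to the patient-level PR flag.

    A segment is PR iff its RI is strictly greater than :data:`RI_THRESHOLD`;
    the patient is PR iff any segment is.
    """
    if not profiles:
        raise ValueError("at least one diameter profile is required")
    ri: dict[tuple[str, str], float] = {}
    for p in profiles:
        if p.segment_id in ri:
            raise ValueError(f"duplicate segment {p.segment_id}")
        ri[p.segment_id] = remodeling_index(p)
    pr_segment = {sid: r > RI_THRESHOLD for sid, r in ri.items()}
    return PRLabel(
        remodeling_index=ri,
        pr_segment=pr_segment,
        pr_patient=any(pr_segment.values()),
    )
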