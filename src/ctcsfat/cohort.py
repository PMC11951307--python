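"""Tabular cohort simulator and group-comparison summaries.

Generates synthetic patient cohorts with the statistical structure the
remodeling analysis assumes: a Bernoulli positive-remodeling (PR) label at a
configurable prevalence, arm-specific clinical covariates (normal for
continuous, Bernoulli for binary), per-vessel Agatston scores drawn on the
log10 scale so all twelve derived score features stay mutually consistent,
fat-omics features with arm-shifted means, and exponential event times with
the hazard multiplied by exp(log HR) in the PR arm under independent uniform
censoring.

Default parameters come from the packaged calibration file
(``data/table_calibration.yaml``), which transcribes the arm-wise moments of
the baseline-characteristics table this simulator emulates. The calibration
is an approximation: means/SDs and proportions only, with cross-covariate
correlations left at zero.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .agatston import score_panel
from .core import ARTERIES

__all__ = [
    "CovariateSpec",
    "HazardSpec",
    "CohortSpec",
    "CohortRecord",
    "load_default_calibration",
    "generate_cohort",
    "cohort_to_frame",
    "summarize_cohort",
]

DEFAULT_PR_PREVALENCE = 0.324  # observed PR prevalence the simulator targets


@dataclass(frozen=True)
class CovariateSpec:
    """Arm-specific sampling model for one covariate.

    ``kind`` is ``"continuous"`` (normal, parameters ``(mean, sd)`` per arm,
    optionally clipped below) or ``"binary"`` (Bernoulli, parameter = event
    proportion per arm).
    """

    kind: str
    pr_pos: tuple[float, float] | float
    pr_neg: tuple[float, float] | float
    clip_min: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"kind must be continuous or binary, got {self.kind!r}")
        for arm, p in (("pr_pos", self.pr_pos), ("pr_neg", self.pr_neg)):
            if self.kind == "continuous":
                mean, sd = p  # type: ignore[misc]
                if sd < 0:
                    raise ValueError(f"{arm}: sd must be >= 0, got {sd}")
            else:
                if not (0.0 <= float(p) <= 1.0):  # type: ignore[arg-type]
                    raise ValueError(f"{arm}: proportion must be in [0, 1], got {p}")

    def draw(self, rng: np.random.Generator, n: int, positive_arm: bool) -> np.ndarray:
        p = self.pr_pos if positive_arm else self.pr_neg
        if self.kind == "binary":
            return (rng.random(n) < float(p)).astype(float)  # type: ignore[arg-type]
        mean, sd = p  # type: ignore[misc]
        x = rng.normal(mean, sd, size=n)
        if self.clip_min is not None:
            x = np.maximum(x, self.clip_min)
        return x


@dataclass(frozen=True)
class HazardSpec:
    """Exponential event-time model with uniform censoring.

    The baseline hazard (events per person-year) applies to the PR-negative
    arm; the PR-positive arm's hazard is multiplied by ``exp(log_hr)``.
    Censoring times are uniform over ``(0, follow_up_years]``.
    """

    baseline_rate_per_year: float
    log_hr: float
    follow_up_years: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_rate_per_year <= 0:
            raise ValueError("baseline hazard rate must be positive")
        if self.follow_up_years <= 0:
            raise ValueError("follow-up window must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate one cohort."""

    n_patients: int
    pr_prevalence: float = DEFAULT_PR_PREVALENCE
    covariates: dict[str, CovariateSpec] = field(default_factory=dict)
    agatston_log10: dict[str, CovariateSpec] = field(default_factory=dict)
    fatomics: dict[str, CovariateSpec] = field(default_factory=dict)
    hazard: HazardSpec | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not (0.0 < self.pr_prevalence < 1.0):
            raise ValueError(f"pr_prevalence must be in (0, 1), got {self.pr_prevalence}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")

    def with_defaults(self) -> "CohortSpec":
        """Fill empty models from the packaged calibration."""
        cal = load_default_calibration()
        return replace(
            self,
            covariates=self.covariates or cal["covariates"],
            agatston_log10=self.agatston_log10 or cal["agatston_log10"],
            fatomics=self.fatomics or cal["fatomics"],
            hazard=self.hazard or cal["hazard"],
        )


@dataclass(frozen=True)
class CohortRecord:
    """One simulated patient."""

    patient_id: int
    pr: bool
    clinical: dict[str, float]
    agatston: dict[str, float]
    fatomics: dict[str, float]
    time_years: float
    event: bool


def _as_cov_spec(kind: str, entry: dict) -> CovariateSpec:
    def _param(v):
        return tuple(v) if isinstance(v, (list, tuple)) else float(v)

    return CovariateSpec(
        kind=kind,
        pr_pos=_param(entry["pr_pos"]),
        pr_neg=_param(entry["pr_neg"]),
        clip_min=entry.get("clip_min"),
    )


def load_default_calibration() -> dict:
    """Load the packaged arm-wise calibration (covariates, scores, hazard)."""
    ref = importlib.resources.files("ctcsfat").joinpath("data/table_calibration.yaml")
    raw = yaml.safe_load(ref.read_text())
    covariates = {
        name: _as_cov_spec(entry["kind"], entry) for name, entry in raw["covariates"].items()
    }
    agatston = {
        a: _as_cov_spec("continuous", entry) for a, entry in raw["agatston_log10"].items()
    }
    fatomics = {
        name: _as_cov_spec("continuous", entry) for name, entry in raw["fatomics"].items()
    }
    h = raw["hazard"]
    hazard = HazardSpec(
        baseline_rate_per_year=float(h["baseline_rate_per_year"]),
        log_hr=float(h["log_hr"]),
        follow_up_years=float(h["follow_up_years"]),
    )
    return {
        "covariates": covariates,
        "agatston_log10": agatston,
        "fatomics": fatomics,
        "hazard": hazard,
    }


def _draw_by_arm(
    rng: np.random.Generator, spec: CovariateSpec, pr: np.ndarray
) -> np.ndarray:
    """Draw one covariate for all patients, arm by arm."""
    n = pr.size
    out = np.empty(n)
    out[pr] = spec.draw(rng, int(pr.sum()), positive_arm=True)
    out[~pr] = spec.draw(rng, int((~pr).sum()), positive_arm=False)
    return out


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Simulate a cohort; same spec (incl. seed) reproduces it exactly."""
    spec = spec.with_defaults()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    pr = rng.random(n) < spec.pr_prevalence

    clinical = {
        name: _draw_by_arm(rng, cov, pr) for name, cov in spec.covariates.items()
    }

    # vessel scores drawn on the log10(score+1) scale, truncated at 0
    vessel_scores: dict[str, np.ndarray] = {}
    for artery in ARTERIES:
        cov = spec.agatston_log10[artery]
        log_s = np.maximum(_draw_by_arm(rng, cov, pr), 0.0)
        vessel_scores[artery] = np.power(10.0, log_s) - 1.0

    fat = {name: _draw_by_arm(rng, cov, pr) for name, cov in spec.fatomics.items()}
    # probability-type fat-omics features live in [0, 1]
    for name, x in fat.items():
        if name.startswith(("SR", "SL")):
            fat[name] = np.clip(x, 0.0, 1.0)

    hz = spec.hazard
    assert hz is not None
    rate = hz.baseline_rate_per_year * np.exp(hz.log_hr * pr.astype(float))
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(0.0, hz.follow_up_years, size=n)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    if spec.missing_rate > 0:
        for name in clinical:
            miss = rng.random(n) < spec.missing_rate
            clinical[name] = np.where(miss, np.nan, clinical[name])

    records = []
    for i in range(n):
        panel = score_panel({a: float(vessel_scores[a][i]) for a in ARTERIES})
        records.append(
            CohortRecord(
                patient_id=i,
                pr=bool(pr[i]),
                clinical={k: float(v[i]) for k, v in clinical.items()},
                agatston=panel.as_feature_dict(),
                fatomics={k: float(v[i]) for k, v in fat.items()},
                time_years=float(time[i]),
                event=bool(event[i]),
            )
        )
    return records


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Flatten records into a patient x column DataFrame.

    Feature columns are prefixed by group tag (``clinical__``, ``agatston__``,
    ``fatomics__``); label and outcome columns are unprefixed.
    """
    rows = []
    for r in records:
        row: dict[str, float] = {"patient_id": r.patient_id, "pr": float(r.pr)}
        row.update({f"clinical__{k}": v for k, v in r.clinical.items()})
        row.update({f"agatston__{k}": v for k, v in r.agatston.items()})
        row.update({f"fatomics__{k}": v for k, v in r.fatomics.items()})
        row["time_years"] = r.time_years
        row["event"] = float(r.event)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def generate_diameter_profiles(
    pr_patient: bool, rng: np.random.Generator, n_samples: int = 30
) -> list:
    """Draw the nine per-segment diameter profiles consistent with a PR label.

    Each major PR artery (LAD, LCX, RCA) contributes proximal/mid/distal
    segments with smoothly tapering reference diameters. A PR-positive
    patient gets at least one segment whose plaque bulge pushes the
    remodeling index above the 1.1 threshold; PR-negative patients stay at or
    below it.
    """
    from .core import PR_ARTERIES, SEGMENT_REGIONS
    from .remodeling import DiameterProfile

    profiles = []
    seg_ids = [(a, rgn) for a in PR_ARTERIES for rgn in SEGMENT_REGIONS]
    hot = rng.integers(0, len(seg_ids)) if pr_patient else -1
    for si, (artery, region) in enumerate(seg_ids):
        base = float(rng.uniform(2.5, 4.5))
        taper = np.linspace(1.0, 0.9, n_samples)
        d = base * taper * (1.0 + rng.normal(0.0, 0.005, n_samples))
        third = n_samples // 3
        if si == hot:
            ri_target = float(rng.uniform(1.15, 1.5))
        elif pr_patient:
            ri_target = float(rng.uniform(0.95, 1.08))
        else:
            ri_target = float(rng.uniform(0.95, 1.05))
        prox = (0, third)
        plaque = (third, 2 * third)
        dist = (2 * third, n_samples)
        ref_mean = (d[slice(*prox)].mean() + d[slice(*dist)].mean()) / 2.0
        bulge_center = (plaque[0] + plaque[1]) // 2
        d[bulge_center] = ri_target * ref_mean
        d = np.abs(d)
        profiles.append(
            DiameterProfile(
                artery=artery, region=region, diameters=d,
                plaque_span=plaque, proximal_ref=prox, distal_ref=dist,
            )
        )
    return profiles


def _continuous_row(x_pos: np.ndarray, x_neg: np.ndarray) -> tuple[str, str, float, str]:
    x_pos = x_pos[~np.isnan(x_pos)]
    x_neg = x_neg[~np.isnan(x_neg)]
    s_pos = f"{x_pos.mean():.2f} ± {x_pos.std(ddof=1):.2f}"
    s_neg = f"{x_neg.mean():.2f} ± {x_neg.std(ddof=1):.2f}"
    if x_pos.std(ddof=1) == 0 and x_neg.std(ddof=1) == 0:
        # identical constants: no evidence of a difference by convention
        p = 1.0 if x_pos.mean() == x_neg.mean() else 0.0
        return s_pos, s_neg, p, ""
    t = stats.ttest_ind(x_pos, x_neg, equal_var=True)
    return s_pos, s_neg, float(t.pvalue), ""


def _binary_row(x_pos: np.ndarray, x_neg: np.ndarray) -> tuple[str, str, float, str]:
    x_pos = x_pos[~np.isnan(x_pos)]
    x_neg = x_neg[~np.isnan(x_neg)]
    k_pos, n_pos = int(x_pos.sum()), x_pos.size
    k_neg, n_neg = int(x_neg.sum()), x_neg.size
    s_pos = f"{k_pos}/{n_pos} ({100 * k_pos / max(n_pos, 1):.1f}%)"
    s_neg = f"{k_neg}/{n_neg} ({100 * k_neg / max(n_neg, 1):.1f}%)"
    table = np.array([[k_pos, n_pos - k_pos], [k_neg, n_neg - k_neg]])
    if np.any(table.sum(axis=0) == 0):
        return s_pos, s_neg, np.nan, "chi-square not applicable (zero margin)"
    chi2 = stats.chi2_contingency(table, correction=False)
    return s_pos, s_neg, float(chi2.pvalue), ""


def summarize_cohort(records: list[CohortRecord]) -> pd.DataFrame:
    """Arm-wise covariate summaries with two-sided group-comparison p-values.

    Continuous covariates are compared by Student's t-test and reported as
    mean +/- SD; binary ones by the Pearson chi-square test and reported as
    count/arm-size (%). Mirrors the layout of a baseline-characteristics
    table.
    """
    pr = np.array([r.pr for r in records])
    if pr.all() or not pr.any():
        raise ValueError("both PR arms must be non-empty to summarize")

    names = list(records[0].clinical)
    rows = []
    for name in names:
        x = np.array([r.clinical[name] for r in records])
        finite = x[~np.isnan(x)]
        is_binary = np.isin(finite, (0.0, 1.0)).all()
        fn = _binary_row if is_binary else _continuous_row
        s_pos, s_neg, p, note = fn(x[pr], x[~pr])
        rows.append(
            {
                "feature": name,
                "kind": "binary" if is_binary else "continuous",
                "pr_pos": s_pos,
                "pr_neg": s_neg,
                "p_value": p,
                "note": note,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
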