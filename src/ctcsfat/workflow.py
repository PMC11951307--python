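"""End-to-end orchestration: phantoms -> features -> models -> survival.

``run_end_to_end`` wires the stages together on synthetic inputs and writes
every intermediate as CSV plus a JSON manifest (config hash, seeds, package
versions), so a rerun with the same config reproduces the deterministic
outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agatston import score_volume
from .cohort import CohortSpec, cohort_to_frame, generate_cohort, summarize_cohort
from .fatomics import assign_slabs_ribbons, extract_features
from .phantom import LesionSpec, PhantomSpec, generate_phantom
from .pipeline import (
    FeatureTable,
    compare_models,
    cross_validate,
    select_features,
)
from .survival import SurvivalInput, cox_fit

__all__ = ["RunConfig", "run_end_to_end"]

_ALLOWED_KEYS = {
    "n_patients", "pr_prevalence", "seed", "n_phantoms", "n_repetitions",
    "n_folds", "backend", "models", "n_ribbons", "threshold", "out_dir",
    "select_per_fold", "missing_rate",
}


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one full synthetic run."""

    n_patients: int = 600
    pr_prevalence: float = 0.324
    seed: int = 0
    n_phantoms: int = 2
    n_repetitions: int = 5
    n_folds: int = 5
    backend: str = "boosted_trees_catboost_style"
    models: tuple[int, ...] = (1, 2, 3)
    n_ribbons: int = 5
    threshold: float = 0.5
    select_per_fold: bool = False
    missing_rate: float = 0.0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(int(m) for m in raw["models"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _demo_phantom_spec(seed: int) -> PhantomSpec:
    rng = np.random.default_rng(seed)
    lesions = []
    arteries = ["LAD", "LCX", "RCA"]
    centers = [(36.0, 10.0, 16.0), (36.0, 22.0, 6.0), (36.0, 26.0, 26.0)]
    for artery, c in zip(arteries, centers):
        if rng.random() < 0.8:
            lesions.append(
                LesionSpec(
                    artery=artery, center_mm=c,
                    radius_mm=float(rng.uniform(1.5, 3.0)),
                    peak_hu=float(rng.uniform(150, 800)),
                )
            )
    return PhantomSpec(grid_shape=(24, 48, 48), voxel_spacing=(3.0, 0.68, 0.68),
                       lesions=tuple(lesions), seed=seed)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_end_to_end(config: RunConfig) -> dict:
    """Run every stage on synthetic data and write a results bundle.

    Returns a dict with the in-memory results (summary frames, fits) and the
    paths of everything written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    with _stage("phantom-imaging"):
        rows = []
        for i in range(config.n_phantoms):
            ph = generate_phantom(_demo_phantom_spec(config.seed + i))
            panel = score_volume(ph.volume, ph.territories)
            geo = assign_slabs_ribbons(
                ph.eat, ph.pericardium, ph.volume.spacing, n_ribbons=config.n_ribbons
            )
            fat = extract_features(ph.volume, geo)
            row = {"phantom": i, **panel.as_feature_dict(), **fat.values}
            rows.append(row)
        phantom_df = pd.DataFrame(rows).set_index("phantom")
        phantom_df.to_csv(out / "phantom_features.csv")
        results["phantom_features"] = phantom_df

    with _stage("cohort-simulation"):
        spec = CohortSpec(
            n_patients=config.n_patients, pr_prevalence=config.pr_prevalence,
            missing_rate=config.missing_rate, seed=config.seed,
        )
        records = generate_cohort(spec)
        frame = cohort_to_frame(records)
        frame.to_csv(out / "cohort.csv")
        summary = summarize_cohort(records)
        summary.to_csv(out / "cohort_summary.csv")
        results["cohort_summary"] = summary

    with _stage("feature-selection"):
        table3 = FeatureTable.from_cohort_frame(frame, model=3)
        sel = select_features(table3, seed=config.seed)
        sel_df = pd.DataFrame(
            {
                "feature": sel.selected_features,
                "importance": [sel.importance[f] for f in sel.selected_features],
            }
        ).set_index("feature")
        sel_df.to_csv(out / "selected_features.csv")
        results["selection"] = sel

    with _stage("cross-validation"):
        metrics_rows = []
        oof = {}
        for model in config.models:
            table = FeatureTable.from_cohort_frame(frame, model=model)
            ev = cross_validate(
                table, backend=config.backend,
                n_repetitions=config.n_repetitions, n_folds=config.n_folds,
                seed=config.seed, threshold=config.threshold,
                select_per_fold=config.select_per_fold,
            )
            oof[model] = ev.oof_scores
            for metric, row in ev.summary().iterrows():
                metrics_rows.append(
                    {"model": model, "metric": metric,
                     "mean_pct": row["mean"], "sd_pct": row["sd"]}
                )
        metrics_df = pd.DataFrame(metrics_rows)
        metrics_df.to_csv(out / "cv_metrics.csv", index=False)
        results["cv_metrics"] = metrics_df

    with _stage("model-comparison"):
        comp_rows = []
        y = FeatureTable.from_cohort_frame(frame, model=3).y
        pairs = [(a, b) for a, b in ((1, 2), (2, 3)) if a in oof and b in oof]
        for a, b in pairs:
            comp = compare_models(y, oof[b], oof[a], threshold=config.threshold)
            comp_rows.append({"model_a": b, "model_b": a, **comp})
        comp_df = pd.DataFrame(comp_rows)
        comp_df.to_csv(out / "model_comparisons.csv", index=False)
        results["model_comparisons"] = comp_df

    with _stage("survival"):
        time = frame["time_years"].to_numpy()
        event = frame["event"].to_numpy().astype(bool)
        actual = frame["pr"].to_numpy().astype(bool)
        best_model = max(oof)
        predicted = oof[best_model] >= config.threshold
        surv_rows = []
        fits = {}
        for name, group in (("actual_pr", actual), ("predicted_pr", predicted)):
            fit = cox_fit(SurvivalInput(time=time, event=event, group=group))
            fits[name] = fit
            surv_rows.append(
                {"covariate": name, "hr": fit.hr, "ci_low": fit.ci_low,
                 "ci_high": fit.ci_high, "c_index": fit.c_index,
                 "logrank_p": fit.logrank_p}
            )
            for glabel, curve in fit.km_curves.items():
                curve.to_csv(out / f"km_{name}_{glabel}.csv")
        surv_df = pd.DataFrame(surv_rows).set_index("covariate")
        surv_df.to_csv(out / "survival_fits.csv")
        results["survival"] = surv_df
        results["survival_fits"] = fits

    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    results["manifest"] = manifest
    return results
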