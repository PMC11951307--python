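"""Kaplan-Meier stratification and Cox modeling of MACE.

MACE (major adverse cardiovascular events) is treated as a composite
time-to-first-event outcome with right censoring. Patients are stratified by
a binary covariate — the actual positive-remodeling label or the classifier's
predicted one — and compared with the product-limit (Kaplan-Meier) estimator
and log-rank test; the association is quantified by a univariable Cox
proportional-hazards model reporting the hazard ratio, Wald 95% CI, Harrell's
concordance index and the log-rank p-value. Ties are handled by Efron's
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index

__all__ = ["SurvivalInput", "SurvivalFit", "km_fit", "cox_fit"]


@dataclass(frozen=True)
class SurvivalInput:
    """Follow-up time (years), event indicator and binary group per patient."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=bool)
        g = np.asarray(self.group, dtype=bool)
        if not (t.shape == e.shape == g.shape) or t.ndim != 1:
            raise ValueError("time, event and group must be 1-D arrays of equal length")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("follow-up times must be finite and non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        object.__setattr__(self, "group", g)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_years": self.time, "event": self.event.astype(int),
             "group": self.group.astype(int)}
        )


@dataclass(frozen=True)
class SurvivalFit:
    """Cox fit summary for a binary covariate."""

    hr: float
    ci_low: float
    ci_high: float
    c_index: float
    logrank_p: float
    km_curves: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("hazard-ratio CI does not bracket the point estimate")


def _km_curve(kmf: KaplanMeierFitter) -> pd.DataFrame:
    curve = kmf.survival_function_.copy()
    curve.columns = ["survival"]
    ci = kmf.confidence_interval_survival_function_
    curve["ci_low"] = ci.iloc[:, 0].to_numpy()
    curve["ci_high"] = ci.iloc[:, 1].to_numpy()
    return curve


def km_fit(inp: SurvivalInput) -> tuple[dict[str, pd.DataFrame], float | None]:
    """Kaplan-Meier curves per group plus the two-sided log-rank p-value.

    With a single represented group, curves are returned and the p-value is
    ``None`` (no contrast to test).
    """
    curves: dict[str, pd.DataFrame] = {}
    for label, sel in (("group0", ~inp.group), ("group1", inp.group)):
        if sel.any():
            kmf = KaplanMeierFitter()
            kmf.fit(inp.time[sel], inp.event[sel], label=label)
            curves[label] = _km_curve(kmf)
    if len(curves) < 2:
        return curves, None
    lr = logrank_test(
        inp.time[inp.group], inp.time[~inp.group],
        event_observed_A=inp.event[inp.group], event_observed_B=inp.event[~inp.group],
    )
    return curves, float(lr.p_value)


def cox_fit(inp: SurvivalInput) -> SurvivalFit:
    """Univariable Cox proportional-hazards fit on the binary group.

    Returns the partial-likelihood hazard ratio with Wald 95% CI, Harrell's
    C-index of the fitted risk scores, and the log-rank p-value. Ties are
    handled by Efron's approximation. Complete separation of events (all
    events in one group with no comparable risk sets) surfaces as lifelines'
    convergence error, re-raised with context.
    """
    if not inp.group.any() or inp.group.all():
        raise ValueError("both groups must be represented for a Cox fit")
    if not inp.event[inp.group].any() or not inp.event[~inp.group].any():
        raise ValueError(
            "no events in one group: the partial-likelihood estimate does not "
            "converge (complete separation)"
        )

    df = inp.to_frame()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time_years", event_col="event")
    except Exception as err:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model did not converge: {err}") from err

    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    hr = float(np.exp(beta))
    with np.errstate(over="ignore"):  # extreme separation -> infinite CI bound
        ci_low, ci_high = float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))
    c_index = float(
        concordance_index(inp.time, -cph.predict_partial_hazard(df), inp.event)
    )
    curves, logrank_p = km_fit(inp)
    return SurvivalFit(
        hr=hr, ci_low=ci_low, ci_high=ci_high, c_index=c_index,
        logrank_p=float(logrank_p) if logrank_p is not None else np.nan,
        km_curves=curves,
    )
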