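"""Feature table assembly, elastic-net selection, classification and CV.

The modeling pipeline mirrors a three-model design: *Model 1* uses clinical
covariates only, *Model 2* adds the Agatston-derived score features, and
*Model 3* adds the fat-omics features. Features are selected by elastic-net
penalized logistic regression (mixing parameter alpha = 0.5, a 100-value
log-spaced lambda path from the all-zero lambda_max downward, 5-fold CV to
pick lambda), and the selected features feed a gradient-boosted classifier
evaluated by repeated stratified 5-fold cross-validation. Model pairs are
compared with McNemar's test on discordant classifications and DeLong's test
on AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline

__all__ = [
    "FeatureTable",
    "SelectionResult",
    "CVEvaluation",
    "BOOSTED_TREE_DEFAULTS",
    "MODEL_GROUPS",
    "select_features",
    "make_classifier",
    "train_classifier",
    "cross_validate",
    "binary_metrics",
    "compare_models",
    "delong_test",
    "mcnemar_test",
]

GROUP_TAGS = ("clinical", "agatston", "fatomics")

#: Feature-group composition of the three models.
MODEL_GROUPS = {
    1: ("clinical",),
    2: ("clinical", "agatston"),
    3: ("clinical", "agatston", "fatomics"),
}

#: Gradient-boosting defaults (CatBoost-style parameterization mapped onto
#: xgboost): 100 iterations, learning rate 0.01, depth 6, L2 leaf
#: regularization 3, per-level feature subsampling 0.75, 64 histogram bins,
#: Bernoulli row subsampling at 0.6, log-loss objective, one thread.
BOOSTED_TREE_DEFAULTS = {
    "n_estimators": 100,
    "learning_rate": 0.01,
    "max_depth": 6,
    "reg_lambda": 3.0,
    "colsample_bylevel": 0.75,
    "max_bin": 64,
    "subsample": 0.6,
    "objective": "binary:logistic",
    "tree_method": "hist",
    "n_jobs": 1,
}

BACKENDS = ("boosted_trees_catboost_style", "random_forest", "svm", "xgboost_style")


@dataclass(frozen=True)
class FeatureTable:
    """Patient x feature matrix with per-column group tags and PR labels."""

    X: pd.DataFrame
    y: np.ndarray
    tags: dict[str, str]

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            dupes = self.X.columns[self.X.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        missing = set(self.X.columns) - set(self.tags)
        if missing:
            raise ValueError(f"features without a group tag: {sorted(missing)}")
        bad = {c: t for c, t in self.tags.items() if t not in GROUP_TAGS}
        if bad:
            raise ValueError(f"unknown group tags {bad}; expected {GROUP_TAGS}")
        y = np.asarray(self.y)
        object.__setattr__(self, "y", y.astype(int))
        if len(y) != len(self.X):
            raise ValueError("label vector length does not match the table")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    @classmethod
    def from_cohort_frame(cls, frame: pd.DataFrame, model: int = 3) -> "FeatureTable":
        """Build the Model-1/2/3 table from a ``cohort_to_frame`` DataFrame."""
        groups = MODEL_GROUPS[model]
        cols, tags = [], {}
        for col in frame.columns:
            for tag in groups:
                prefix = f"{tag}__"
                if col.startswith(prefix):
                    cols.append(col)
                    tags[col] = tag
        return cls(X=frame[cols], y=frame["pr"].to_numpy(), tags=tags)

    def subset(self, features: list[str]) -> "FeatureTable":
        return FeatureTable(
            X=self.X[features], y=self.y, tags={f: self.tags[f] for f in features}
        )


@dataclass(frozen=True)
class SelectionResult:
    """Elastic-net selection outcome.

    ``importance`` is the absolute standardized coefficient at the CV-optimal
    penalty, with optional bootstrap confidence intervals.
    """

    selected_features: list[str]
    importance: dict[str, float]
    importance_ci: dict[str, tuple[float, float]]
    alpha: float
    lambda_path: np.ndarray
    lambda_opt: float
    cv_loss: np.ndarray


def _lambda_path(Xs: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int,
                 min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced penalty path from lambda_max (all coefficients zero) down.

    For penalized logistic regression lambda_max = max_j |x_j'(y - ybar)| /
    (n * alpha): at this penalty the null model is stationary.
    """
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(Xs.T @ resid).max() / (n * max(alpha, 1e-3))
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambda)


def _fit_enet_path(Xs, y, lambdas, alpha, tol=1e-4):
    """Coefficients along the path (warm-started saga), shape (L, p)."""
    n = len(y)
    clf = LogisticRegression(
        solver="saga", l1_ratio=alpha, warm_start=True,
        max_iter=2000, tol=tol, fit_intercept=True, random_state=0,
    )
    coefs = np.empty((len(lambdas), Xs.shape[1]))
    intercepts = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        clf.set_params(C=1.0 / (n * lam))
        clf.fit(Xs, y)
        coefs[i] = clf.coef_[0]
        intercepts[i] = clf.intercept_[0]
    return coefs, intercepts


def select_features(
    table: FeatureTable,
    alpha: float = 0.5,
    n_lambda: int = 100,
    n_folds: int = 5,
    seed: int = 0,
    n_bootstrap: int = 0,
) -> SelectionResult:
    """Elastic-net logistic feature selection with a CV-tuned penalty.

    Features are standardized internally; constant columns are dropped with a
    warning. The penalty path runs from lambda_max (all coefficients zero) in
    100 log-spaced steps; the optimum minimizes mean validation log-loss over
    stratified folds. Selected features are those with nonzero coefficients
    at the optimum, ordered by absolute standardized coefficient. With
    ``n_bootstrap > 0``, per-feature importance CIs come from bootstrap
    resampling of the selection run.
    """
    y = table.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need at least two patients in each class")
    if n_folds > counts.min():
        raise ValueError(f"n_folds={n_folds} exceeds the smaller class count {counts.min()}")

    X = table.X.to_numpy(dtype=float)
    X = SimpleImputer(strategy="median").fit_transform(X)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(table.X.columns, keep) if not k]
        warnings.warn(f"dropping constant features: {dropped}", RuntimeWarning, stacklevel=2)
    names = [c for c, k in zip(table.X.columns, keep) if k]
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    lambdas = _lambda_path(Xs, y, alpha, n_lambda)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_loss = np.zeros(len(lambdas))
    for tr, va in skf.split(Xs, y):
        coefs, icept = _fit_enet_path(Xs[tr], y[tr], lambdas, alpha, tol=1e-3)
        logits = Xs[va] @ coefs.T + icept
        p = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        loss = -(y[va, None] * np.log(p + eps) + (1 - y[va, None]) * np.log(1 - p + eps))
        cv_loss += loss.mean(axis=0)
    cv_loss /= n_folds
    lam_opt = float(lambdas[int(np.argmin(cv_loss))])

    coefs, _ = _fit_enet_path(Xs, y, lambdas[lambdas >= lam_opt], alpha)
    beta = coefs[-1]
    importance = {n: abs(b) for n, b in zip(names, beta) if b != 0.0}
    order = sorted(importance, key=importance.get, reverse=True)

    ci: dict[str, tuple[float, float]] = {}
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = {n: [] for n in names}
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(y), len(y))
            if len(np.unique(y[idx])) < 2:
                continue
            bc, _ = _fit_enet_path(Xs[idx], y[idx], np.array([lam_opt]), alpha, tol=1e-3)
            for n_, b in zip(names, bc[0]):
                boot[n_].append(abs(b))
        for n_ in order:
            draws = np.array(boot[n_])
            if draws.size:
                ci[n_] = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))

    return SelectionResult(
        selected_features=order,
        importance=importance,
        importance_ci=ci,
        alpha=alpha,
        lambda_path=lambdas,
        lambda_opt=lam_opt,
        cv_loss=cv_loss,
    )


def make_classifier(backend: str, seed: int = 0, hyperparams: dict | None = None):
    """Instantiate a classifier pipeline (median imputation built in)."""
    hp = dict(hyperparams or {})
    if backend == "boosted_trees_catboost_style":
        from xgboost import XGBClassifier

        params = {**BOOSTED_TREE_DEFAULTS, **hp}
        model = XGBClassifier(random_state=seed, **params)
    elif backend == "xgboost_style":
        from xgboost import XGBClassifier

        model = XGBClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=seed,
            n_jobs=1, tree_method="hist", **hp,
        )
    elif backend == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        model = RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=seed, n_jobs=1, **hp
        )
    elif backend == "svm":
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        model = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(probability=True, random_state=seed, **hp)),
            ]
        )
    else:
        raise ValueError(f"unknown backend {backend!r}; expected one of {BACKENDS}")
    return Pipeline([("impute", SimpleImputer(strategy="median")), ("model", model)])


def train_classifier(
    table: FeatureTable,
    features: list[str] | None = None,
    backend: str = "boosted_trees_catboost_style",
    hyperparams: dict | None = None,
    seed: int = 0,
    n_folds: int = 5,
):
    """Fit a classifier and return it with out-of-fold probability scores.

    Out-of-fold scores come from an internal stratified K-fold: each
    patient's score is produced by a model that never saw that patient.
    """
    feats = features or list(table.X.columns)
    missing = set(feats) - set(table.X.columns)
    if missing:
        raise ValueError(f"features not in table: {sorted(missing)}")
    X = table.X[feats].to_numpy(dtype=float)
    y = table.y

    oof = np.empty(len(y))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, va in skf.split(X, y):
        clf = make_classifier(backend, seed=seed, hyperparams=hyperparams)
        clf.fit(X[tr], y[tr])
        oof[va] = clf.predict_proba(X[va])[:, 1]

    final = make_classifier(backend, seed=seed, hyperparams=hyperparams)
    final.fit(X, y)
    return final, oof


def binary_metrics(y: np.ndarray, score: np.ndarray, threshold: float = 0.5) -> dict:
    """Sensitivity/specificity/accuracy at a threshold, plus AUC."""
    y = np.asarray(y).astype(int)
    pred = (np.asarray(score) >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / len(y)
    auc = roc_auc_score(y, score) if len(np.unique(y)) == 2 else np.nan
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc, "auc": auc}


@dataclass(frozen=True)
class CVEvaluation:
    """Per-repetition CV metrics with a mean +/- SD summary."""

    metrics: pd.DataFrame  # one row per repetition
    n_repetitions: int
    n_folds: int
    oof_scores: np.ndarray  # out-of-fold scores of the last repetition
    y: np.ndarray

    def summary(self, as_percent: bool = True) -> pd.DataFrame:
        scale = 100.0 if as_percent else 1.0
        rows = []
        for m in ("sensitivity", "specificity", "accuracy", "auc"):
            vals = self.metrics[m] * scale
            rows.append({"metric": m, "mean": vals.mean(), "sd": vals.std(ddof=1)})
        return pd.DataFrame(rows).set_index("metric")


def cross_validate(
    table: FeatureTable,
    backend: str = "boosted_trees_catboost_style",
    features: list[str] | None = None,
    hyperparams: dict | None = None,
    n_repetitions: int = 25,
    n_folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    select_per_fold: bool = False,
    selection_kwargs: dict | None = None,
) -> CVEvaluation:
    """Repeated stratified K-fold cross-validation.

    With ``select_per_fold=True`` elastic-net selection is re-run inside each
    training fold (leak-free); otherwise the supplied ``features`` (or all
    columns) are used throughout, which matches a select-once-on-all-data
    reading of the original protocol. The operating point for
    sensitivity/specificity is a fixed probability threshold (default 0.5).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = table.y
    feats_all = features or list(table.X.columns)

    rows = []
    oof = np.empty(len(y))
    for rep in range(n_repetitions):
        rep_seed = seed + rep
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        for tr, va in skf.split(table.X, y):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                raise ValueError("a fold lacks one class; reduce n_folds")
            if select_per_fold:
                sub = FeatureTable(
                    X=table.X.iloc[tr], y=y[tr],
                    tags={c: table.tags[c] for c in table.X.columns},
                )
                sel = select_features(sub, seed=rep_seed, **(selection_kwargs or {}))
                feats = sel.selected_features or feats_all
            else:
                feats = feats_all
            clf = make_classifier(backend, seed=rep_seed, hyperparams=hyperparams)
            clf.fit(table.X.iloc[tr][feats].to_numpy(dtype=float), y[tr])
            oof[va] = clf.predict_proba(table.X.iloc[va][feats].to_numpy(dtype=float))[:, 1]
        rows.append(binary_metrics(y, oof, threshold))

    return CVEvaluation(
        metrics=pd.DataFrame(rows),
        n_repetitions=n_repetitions,
        n_folds=n_folds,
        oof_scores=oof.copy(),
        y=y.copy(),
    )


# ---------------------------------------------------------------------------
# model comparison: McNemar on paired classifications, DeLong on paired AUCs
# ---------------------------------------------------------------------------


def mcnemar_test(correct_a: np.ndarray, correct_b: np.ndarray) -> dict:
    """McNemar chi-square test on discordant pairs (no continuity correction).

    ``correct_a``/``correct_b`` are boolean per-patient correctness vectors of
    the two models on the same patients. With zero discordant pairs the
    p-value is 1 by convention.
    """
    a = np.asarray(correct_a, dtype=bool)
    c_b = np.asarray(correct_b, dtype=bool)
    if a.shape != c_b.shape:
        raise ValueError("paired vectors must have equal length")
    b = int((a & ~c_b).sum())  # A right, B wrong
    c = int((~a & c_b).sum())  # A wrong, B right
    if b + c == 0:
        return {"statistic": 0.0, "p_value": 1.0, "b": b, "c": c}
    chi2 = (b - c) ** 2 / (b + c)
    return {"statistic": float(chi2), "p_value": float(stats.chi2.sf(chi2, df=1)), "b": b, "c": c}


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks as used by the DeLong fast algorithm."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_auc_cov(y: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance matrix for k paired score vectors."""
    pos = scores[:, y == 1]
    neg = scores[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    tx = np.array([_midrank(pos[r]) for r in range(k)])
    ty = np.array([_midrank(neg[r]) for r in range(k)])
    tz = np.array([_midrank(np.concatenate([pos[r], neg[r]])) for r in range(k)])
    aucs = (tz[:, :m].sum(axis=1) / (m * n)) - (m + 1.0) / (2.0 * n)
    v01 = (tz[:, :m] - tx) / n
    v10 = 1.0 - (tz[:, m:] - ty) / m
    s01 = np.cov(v01)
    s10 = np.cov(v10)
    cov = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, cov


def delong_test(y: np.ndarray, scores_a: np.ndarray, scores_b: np.ndarray) -> dict:
    """DeLong two-sided test for the difference of two correlated AUCs."""
    y = np.asarray(y).astype(int)
    s = np.vstack([np.asarray(scores_a, float), np.asarray(scores_b, float)])
    if len(np.unique(y)) != 2:
        raise ValueError("DeLong test needs both classes present")
    aucs, cov = _delong_auc_cov(y, s)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = aucs[0] - aucs[1]
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = delta / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": float(aucs[0]), "auc_b": float(aucs[1]), "z": float(z), "p_value": float(p)}


def compare_models(
    y: np.ndarray,
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    threshold: float = 0.5,
) -> dict:
    """Paired comparison of two models' out-of-fold scores on one cohort."""
    y = np.asarray(y).astype(int)
    pred_a = np.asarray(scores_a) >= threshold
    pred_b = np.asarray(scores_b) >= threshold
    mc = mcnemar_test(pred_a == y.astype(bool), pred_b == y.astype(bool))
    if np.array_equal(np.asarray(scores_a, float), np.asarray(scores_b, float)):
        dl = {"auc_a": np.nan, "auc_b": np.nan, "z": 0.0, "p_value": 1.0}
        aucs, _ = _delong_auc_cov(y, np.vstack([scores_a, scores_a]).astype(float))
        dl["auc_a"] = dl["auc_b"] = float(aucs[0])
    else:
        dl = delong_test(y, scores_a, scores_b)
    return {"mcnemar_p": mc["p_value"], "mcnemar_stat": mc["statistic"],
            "delong_p": dl["p_value"], "delong_z": dl["z"],
            "auc_a": dl["auc_a"], "auc_b": dl["auc_b"]}
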