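"""Classification metrics, the repeated-split protocol, and subgroup reports.

Metrics follow the standard definitions: accuracy = (TP+TN)/n,
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), and
F1 = 2 TP / (2 TP + FP + FN), which equals the harmonic mean of precision
and sensitivity whenever both are defined.  AUC is the area under the ROC
curve with midrank tie handling (equivalently the concordance probability
of a positive/negative pair, ties counted one half).

The repeated protocol mirrors the development procedure of the classifier:
R independent stratified 80/20 train/validation splits, a fresh model per
repetition, internal (and optionally external) evaluation, with a
mean and 95 % confidence interval per metric and the externally evaluated
single best repetition selected by internal-validation AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = [
    "ConfusionMatrix",
    "EvalMetrics",
    "RepeatedRunSummary",
    "compute_metrics",
    "repeated_protocol",
    "subgroup_report",
]

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "f1")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else float("nan")


@dataclass
class EvalMetrics:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    n: int
    subgroup: str | None = None
    confusion: ConfusionMatrix | None = None

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def compute_metrics(
    y_true,
    proba,
    threshold: float = 0.5,
    subgroup: str | None = None,
) -> EvalMetrics:
    """All metrics from true labels and positive-class probabilities.

    Classification is strict (``proba > threshold``).  With a single-class
    truth vector the AUC is undefined and reported as NaN with a warning;
    the threshold-based metrics are still returned.
    """
    y_true = np.asarray(y_true).astype(int)
    proba = np.asarray(proba, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    y_pred = (proba > threshold).astype(int)
    cm = ConfusionMatrix.from_predictions(y_true, y_pred)
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class labels: AUC undefined, reported as NaN")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_true, proba))
    return EvalMetrics(
        auc=auc,
        accuracy=cm.accuracy,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        f1=cm.f1,
        n=cm.total,
        subgroup=subgroup,
        confusion=cm,
    )


def roc_points(y_true, proba) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(y_true, proba)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class RepeatedRunSummary:
    """Per-repetition metrics with mean and 95 % CI, plus the best repetition."""

    per_repetition: pd.DataFrame
    mean: dict[str, float]
    ci: dict[str, tuple[float, float]] | None
    best_repetition: int
    best_internal: EvalMetrics
    best_external: EvalMetrics | None = None
    external_per_repetition: pd.DataFrame | None = None
    external_mean: dict[str, float] | None = None
    external_ci: dict[str, tuple[float, float]] | None = None


def _summarize(df: pd.DataFrame, method: str, rng: np.random.Generator):
    mean = {m: float(np.nanmean(df[m])) for m in METRIC_NAMES}
    r = len(df)
    if r < 2:
        warnings.warn("fewer than 2 repetitions: confidence intervals unavailable")
        return mean, None
    ci: dict[str, tuple[float, float]] = {}
    for m in METRIC_NAMES:
        vals = df[m].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            ci[m] = (float("nan"), float("nan"))
            continue
        if method == "normal":
            half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals))
            ci[m] = (float(vals.mean() - half), float(vals.mean() + half))
        elif method == "bootstrap":
            boots = np.array(
                [rng.choice(vals, size=len(vals), replace=True).mean() for _ in range(2000)]
            )
            ci[m] = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        else:
            raise ValueError(f"unknown CI method {method!r}")
    return mean, ci


def repeated_protocol(
    X,
    y,
    estimator,
    n_repeats: int = 50,
    test_size: float = 0.2,
    X_external=None,
    y_external=None,
    threshold: float = 0.5,
    ci_method: str = "normal",
    random_state: int | None = None,
) -> RepeatedRunSummary:
    """Repeated stratified train/validation splits with a fresh model each time.

    ``estimator`` is any scikit-learn-style classifier with
    ``predict_proba``; it is cloned per repetition and, when it exposes a
    ``random_state`` parameter, reseeded per repetition for independent
    initializations.
    """
    y = np.asarray(y).astype(int)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(random_state)
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_size,
        random_state=int(rng.integers(2**31 - 1)),
    )
    internal_rows, external_rows = [], []
    best_auc, best_rep = -np.inf, -1
    best_internal: EvalMetrics | None = None
    best_external: EvalMetrics | None = None
    for rep, (tr, va) in enumerate(splitter.split(np.zeros(len(y)), y)):
        est = clone(estimator)
        if "random_state" in est.get_params():
            est.set_params(random_state=int(rng.integers(2**31 - 1)))
        est.fit(X[tr], y[tr])
        proba = est.predict_proba(X[va])[:, 1]
        internal = compute_metrics(y[va], proba, threshold)
        internal_rows.append({"repetition": rep, **internal.as_dict(), "n": internal.n})
        external = None
        if X_external is not None:
            proba_ext = est.predict_proba(X_external)[:, 1]
            external = compute_metrics(y_external, proba_ext, threshold)
            external_rows.append({"repetition": rep, **external.as_dict(), "n": external.n})
        if np.isfinite(internal.auc) and internal.auc > best_auc:
            best_auc, best_rep = internal.auc, rep
            best_internal, best_external = internal, external

    df = pd.DataFrame(internal_rows)
    mean, ci = _summarize(df, ci_method, rng)
    ext_df = pd.DataFrame(external_rows) if external_rows else None
    ext_mean = ext_ci = None
    if ext_df is not None:
        ext_mean, ext_ci = _summarize(ext_df, ci_method, rng)
    return RepeatedRunSummary(
        per_repetition=df,
        mean=mean,
        ci=ci,
        best_repetition=best_rep,
        best_internal=best_internal,
        best_external=best_external,
        external_per_repetition=ext_df,
        external_mean=ext_mean,
        external_ci=ext_ci,
    )


def subgroup_report(
    y_true,
    proba,
    subgroups,
    threshold: float = 0.5,
) -> list[EvalMetrics]:
    """One metric set per diagnosis subgroup plus the overall row.

    Subgroups lacking one class report the defined metrics only (AUC NaN).
    """
    y_true = np.asarray(y_true).astype(int)
    proba = np.asarray(proba, dtype=float)
    subgroups = np.asarray(subgroups)
    out = [compute_metrics(y_true, proba, threshold, subgroup="overall")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tag in pd.unique(subgroups):
            m = subgroups == tag
            out.append(compute_metrics(y_true[m], proba[m], threshold, subgroup=str(tag)))
    return out
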