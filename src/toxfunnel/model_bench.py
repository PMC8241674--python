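"""Endpoint classifier benchmarking with exact leave-one-out sampling.

Five classifier families (AdaBoost, kNN, Gaussian naive Bayes, random
forest, RBF SVM) are trained per cardiotoxicity endpoint. Evaluation uses
exact leave-one-out (n folds): each compound is scored by a model trained
on all others, descriptors are z-scored on the training fold only, and the
held-out probabilities are aggregated into confusion counts (threshold
0.5) and ROC/AUC. The positive class is "toxic" (label 1) throughout.

Default hyperparameters are deliberately modest (RF: 10 trees with sqrt
features per split; kNN: k=5 Euclidean; SVM: RBF C=1; AdaBoost: 50
stumps) and are recorded, with the seed, in every report.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ENDPOINTS",
    "ALGORITHMS",
    "LabeledDataset",
    "ClassifierSpec",
    "EvalReport",
    "RocCurve",
    "EndpointModelSuite",
    "confusion_metrics",
    "roc_auc",
    "loo_evaluate",
    "external_evaluate",
    "train_endpoint_suite",
    "build_classifier",
]

ENDPOINTS = (
    "arrhythmia",
    "cardiac_failure",
    "heart_block",
    "hypertension",
    "myocardial_infarction",
)

ALGORITHMS = ("ada_boost", "knn", "naive_bayes", "random_forest", "svm")

_DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "ada_boost": {"n_estimators": 50, "max_depth": 1},
    "knn": {"n_neighbors": 5, "metric": "minkowski", "p": 2},
    "naive_bayes": {},
    "random_forest": {"n_estimators": 10, "max_features": "sqrt"},
    "svm": {"kernel": "rbf", "C": 1.0},
}


@dataclass
class LabeledDataset:
    """Descriptor matrix plus binary labels for one endpoint (1 = toxic)."""

    endpoint: str
    X: pd.DataFrame
    y: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        if not (len(self.ids) == len(self.X) == len(self.y)):
            raise ValueError("ids, X and y must have equal length")

    @property
    def n(self) -> int:
        return len(self.y)

    def require_two_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise ValueError(f"endpoint {self.endpoint!r}: both classes must be present")


@dataclass(frozen=True)
class ClassifierSpec:
    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unsupported algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )

    def resolved_hyperparameters(self) -> dict:
        hp = dict(_DEFAULT_HYPERPARAMS[self.algorithm])
        hp.update(self.hyperparameters)
        return hp


def build_classifier(spec: ClassifierSpec) -> Pipeline:
    """z-score + classifier pipeline; the scaler is fitted per training fold."""
    hp = spec.resolved_hyperparameters()
    if spec.algorithm == "ada_boost":
        clf = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=hp.pop("max_depth")),
            random_state=spec.seed,
            **hp,
        )
    elif spec.algorithm == "knn":
        clf = KNeighborsClassifier(**hp)
    elif spec.algorithm == "naive_bayes":
        clf = GaussianNB(**hp)
    elif spec.algorithm == "random_forest":
        clf = RandomForestClassifier(random_state=spec.seed, **hp)
    else:  # svm
        clf = SVC(probability=True, random_state=spec.seed, **hp)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class EvalReport:
    """Confusion counts and derived metrics; positive class = toxic.

    Metrics with a zero denominator are NaN (undefined), never 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    sensitivity: float
    specificity: float
    overall_accuracy: float
    precision: float
    per_sample_scores: dict[str, float]
    scheme: str  # "loo" or "external"
    spec: ClassifierSpec | None = None
    skipped_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        d = {
            "positive_class": "toxic",
            "scheme": self.scheme,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "overall_accuracy": self.overall_accuracy,
            "precision": self.precision,
            "per_sample_scores": self.per_sample_scores,
            "skipped_ids": self.skipped_ids,
        }
        if self.spec is not None:
            d["classifier"] = {
                "algorithm": self.spec.algorithm,
                "hyperparameters": self.spec.resolved_hyperparameters(),
                "seed": self.spec.seed,
            }
        return d


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(
    tp: int,
    fp: int,
    tn: int,
    fn: int,
    auc: float = float("nan"),
    per_sample_scores: dict[str, float] | None = None,
    scheme: str = "loo",
    spec: ClassifierSpec | None = None,
) -> EvalReport:
    """Derive sensitivity/specificity/accuracy/precision from counts."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    n = tp + fp + tn + fn
    return EvalReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        auc=auc,
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        overall_accuracy=_safe_div(tp + tn, n),
        precision=_safe_div(tp, tp + fp),
        per_sample_scores=per_sample_scores or {},
        scheme=scheme,
        spec=spec,
    )


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve via threshold sweep; AUC is the trapezoidal area.

    With ties counted 1/2, the AUC equals the Mann-Whitney concordance
    probability P(score_pos > score_neg) + P(score_pos = score_neg)/2.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_trapezoid_auc(fpr, tpr)))


def _scores_to_report(
    ids: Sequence[str],
    y: np.ndarray,
    scores: np.ndarray,
    scheme: str,
    spec: ClassifierSpec | None,
    threshold: float,
    skipped: list[str],
) -> EvalReport:
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    auc_val = roc_auc(scores, y).auc if len(np.unique(y)) == 2 else float("nan")
    report = confusion_metrics(
        tp, fp, tn, fn,
        auc=auc_val,
        per_sample_scores={i: float(v) for i, v in zip(ids, scores)},
        scheme=scheme,
        spec=spec,
    )
    report.skipped_ids = skipped
    return report


def loo_evaluate(
    data: LabeledDataset, spec: ClassifierSpec, threshold: float = 0.5
) -> EvalReport:
    """Exact leave-one-out: retrain on all-but-one, score the held-out sample.

    Single-class training folds (possible when one class has a single
    member) are handled per algorithm: classifiers that can fit one class
    score the held-out sample with that class's degenerate probability;
    algorithms that cannot skip the fold with a warning, and the id is
    listed in ``skipped_ids``. Deterministic given ``spec.seed``.
    """
    if data.n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    data.require_two_classes()
    X = data.X.to_numpy(dtype=float)
    y = data.y
    kept_ids: list[str] = []
    kept_y: list[int] = []
    scores: list[float] = []
    skipped: list[str] = []
    for i in range(data.n):
        mask = np.ones(data.n, dtype=bool)
        mask[i] = False
        model = build_classifier(spec)
        try:
            model.fit(X[mask], y[mask])
        except ValueError as exc:
            warnings.warn(
                f"LOO fold for {data.ids[i]!r} not trainable "
                f"({exc}); skipped",
                stacklevel=2,
            )
            skipped.append(data.ids[i])
            continue
        proba = model.predict_proba(X[i: i + 1])[0]
        classes = list(model.classes_)
        score = float(proba[classes.index(1)]) if 1 in classes else 0.0
        scores.append(score)
        kept_ids.append(data.ids[i])
        kept_y.append(y[i])
    return _scores_to_report(
        kept_ids, np.asarray(kept_y), np.asarray(scores), "loo", spec, threshold, skipped
    )


def external_evaluate(
    model: Pipeline,
    train_columns: Sequence[str],
    validation: LabeledDataset,
    spec: ClassifierSpec | None = None,
    threshold: float = 0.5,
) -> EvalReport:
    """Score an external validation set with a model trained on the full set."""
    if validation.n == 0:
        raise ValueError("validation set is empty")
    missing = [c for c in train_columns if c not in validation.X.columns]
    if missing:
        raise ValueError(f"validation set lacks training descriptor columns: {missing}")
    X = validation.X.loc[:, list(train_columns)].to_numpy(dtype=float)
    scores = model.predict_proba(X)[:, 1]
    return _scores_to_report(
        validation.ids, validation.y, scores, "external", spec, threshold, []
    )


class EndpointModelSuite:
    """Fitted per-endpoint models with their descriptor columns and spec."""

    def __init__(
        self,
        models: dict[str, Pipeline],
        columns: list[str],
        spec: ClassifierSpec,
        threshold: float = 0.5,
    ):
        self.models = models
        self.columns = columns
        self.spec = spec
        self.threshold = threshold

    @property
    def endpoints(self) -> list[str]:
        return list(self.models)

    def predict_proba(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-endpoint toxicity probabilities, one row per compound."""
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"descriptor matrix lacks columns: {missing}")
        arr = X.loc[:, self.columns].to_numpy(dtype=float)
        out = {ep: m.predict_proba(arr)[:, 1] for ep, m in self.models.items()}
        return pd.DataFrame(out, index=X.index)

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "columns": self.columns,
            "threshold": self.threshold,
            "endpoints": self.endpoints,
            "classifier": {
                "algorithm": self.spec.algorithm,
                "hyperparameters": self.spec.resolved_hyperparameters(),
                "seed": self.spec.seed,
            },
            "positive_class": "toxic",
        }
        with open(os.path.join(directory, "suite.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
        for ep, model in self.models.items():
            joblib.dump(model, os.path.join(directory, f"{ep}.joblib"))

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "EndpointModelSuite":
        with open(os.path.join(directory, "suite.json")) as fh:
            meta = json.load(fh)
        spec = ClassifierSpec(
            algorithm=meta["classifier"]["algorithm"],
            hyperparameters=meta["classifier"]["hyperparameters"],
            seed=meta["classifier"]["seed"],
        )
        models = {
            ep: joblib.load(os.path.join(directory, f"{ep}.joblib"))
            for ep in meta["endpoints"]
        }
        return cls(models, meta["columns"], spec, meta["threshold"])


def train_endpoint_suite(
    datasets: Mapping[str, LabeledDataset],
    spec: ClassifierSpec,
    endpoints: Sequence[str] = ENDPOINTS,
    threshold: float = 0.5,
) -> EndpointModelSuite:
    """Fit one model per endpoint on its full training set."""
    missing = [ep for ep in endpoints if ep not in datasets]
    if missing:
        raise ValueError(f"missing datasets for endpoints: {missing}")
    columns: list[str] | None = None
    models: dict[str, Pipeline] = {}
    for ep in endpoints:
        data = datasets[ep]
        data.require_two_classes()
        if columns is None:
            columns = list(data.X.columns)
        elif list(data.X.columns) != columns:
            raise ValueError(
                f"endpoint {ep!r} descriptor columns differ from {columns}"
            )
        model = build_classifier(spec)
        model.fit(data.X.to_numpy(dtype=float), data.y)
        models[ep] = model
    assert columns is not None
    return EndpointModelSuite(models, columns, spec, threshold)
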