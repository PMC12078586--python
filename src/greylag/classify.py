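"""Classifier evaluation: confusion counts, the six standard binary
metrics, small seeded learners (1-NN, decision tree, MLP), and
GGO-driven hyperparameter search.

Note on specificity: it is implemented as ``TN / (TN + FP)`` — the
ability to recognize negatives — never with the sensitivity formula.
Metrics with a zero denominator are reported as NaN with a warning,
not silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.exceptions import ConvergenceWarning

from .ggo import GGOConfig, run_ggo
from .select import FeatureTable

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "HyperparameterDimension",
    "HyperparameterSpace",
    "TABLE_METRIC_NAMES",
    "confusion",
    "metric_report",
    "train_predict",
    "ggo_tune",
]

TABLE_METRIC_NAMES = [
    "Accuracy",
    "Sensitivity",
    "Specificity",
    "P-Value",
    "N-Value",
    "F1-score",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float

    def to_dict(self) -> dict[str, float]:
        return dict(zip(TABLE_METRIC_NAMES,
                        [self.accuracy, self.sensitivity, self.specificity,
                         self.ppv, self.npv, self.f1]))


def confusion(pred: Sequence, truth: Sequence, positive_class) -> ConfusionCounts:
    """Confusion counts for a binary problem with an explicit positive
    class (osteoarthritis by convention in the KOA pipeline)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth vectors differ in length")
    labels = np.unique(np.concatenate([pred, truth]))
    if len(labels) > 2:
        raise ValueError("confusion counts are defined for binary labels only")
    p = pred == positive_class
    t = truth == positive_class
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        TN=int(np.sum(~p & ~t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def metric_report(c: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, specificity, PPV, NPV and F1 from the
    confusion counts.  Zero-denominator metrics come back NaN."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    return MetricReport(
        accuracy=(c.TP + c.TN) / c.total,
        sensitivity=_ratio(c.TP, c.TP + c.FN, "sensitivity"),
        specificity=_ratio(c.TN, c.TN + c.FP, "specificity"),
        ppv=_ratio(c.TP, c.TP + c.FP, "PPV"),
        npv=_ratio(c.TN, c.TN + c.FN, "NPV"),
        f1=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "F1"),
    )


# ---------------------------------------------------------------------------
# Learners
# ---------------------------------------------------------------------------

def _build_learner(kind: str, hyper: dict):
    if kind == "nn1":
        return KNeighborsClassifier(n_neighbors=int(hyper.get("k", 1)))
    if kind == "tree":
        return DecisionTreeClassifier(
            max_depth=hyper.get("max_depth"),
            random_state=int(hyper.get("seed", 0)),
        )
    if kind == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(int(hyper.get("hidden", 16)),),
            alpha=float(hyper.get("alpha", 1e-4)),
            max_iter=int(hyper.get("max_iter", 500)),
            random_state=int(hyper.get("seed", 0)),
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_predict(
    classifier_kind: str,
    hyper: dict,
    train: FeatureTable,
    eval: FeatureTable,
) -> np.ndarray:
    """Fit the named learner (seeded where stochastic) on the training
    table and predict labels for the evaluation table."""
    if not set(np.unique(eval.labels)) <= set(np.unique(train.labels)):
        raise ValueError("evaluation labels must be covered by training labels")
    model = _build_learner(classifier_kind, hyper or {})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(train.values, train.labels)
        return model.predict(eval.values)


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

@dataclass
class HyperparameterDimension:
    """One searchable hyperparameter.

    kind: 'continuous' (linear map), 'integer' (linear map + round) or
    'categorical' (index snap into ``choices``).
    """

    name: str
    lower: float = 0.0
    upper: float = 1.0
    kind: str = "continuous"
    choices: list | None = None

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if not self.choices:
                raise ValueError("categorical dimension needs choices")
            self.lower, self.upper = 0.0, float(len(self.choices) - 1)
        if self.kind != "categorical" and self.lower >= self.upper:
            raise ValueError(f"dimension {self.name!r} needs lower < upper")

    def decode(self, unit: float):
        value = self.lower + float(np.clip(unit, 0.0, 1.0)) * (self.upper - self.lower)
        if self.kind == "continuous":
            return value
        idx = int(np.floor(value + 0.5))
        if self.kind == "integer":
            return idx
        return self.choices[min(idx, len(self.choices) - 1)]


@dataclass
class HyperparameterSpace:
    dimensions: list[HyperparameterDimension]

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("hyperparameter space must be non-empty")

    def decode(self, position: np.ndarray) -> dict:
        return {d.name: d.decode(u) for d, u in zip(self.dimensions, position)}

    def midpoint(self) -> dict:
        return self.decode(np.full(len(self.dimensions), 0.5))


def ggo_tune(
    space: HyperparameterSpace,
    classifier_kind: str,
    train: FeatureTable,
    val: FeatureTable,
    cfg: GGOConfig,
    positive_class=None,
) -> tuple[dict, MetricReport]:
    """GGO search over unit-box-encoded hyperparameters, minimizing the
    validation error of the decoded learner.  Returns the best decoded
    assignment and its validation metric report."""
    import dataclasses as _dc
    cfg = _dc.replace(cfg, bounds=tuple((0.0, 1.0) for _ in space.dimensions))

    cache: dict[tuple, float] = {}

    def objective(position: np.ndarray) -> float:
        hyper = space.decode(position)
        key = tuple(sorted(hyper.items()))
        if key not in cache:
            pred = train_predict(classifier_kind, hyper, train, val)
            cache[key] = float(np.mean(pred != val.labels))
        return cache[key]

    result = run_ggo(objective, cfg)
    best_hyper = space.decode(result.best_position)
    pred = train_predict(classifier_kind, best_hyper, train, val)
    if positive_class is None:
        positive_class = sorted(np.unique(val.labels).tolist())[-1]
    report = metric_report(confusion(pred, val.labels, positive_class))
    return best_hyper, report
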