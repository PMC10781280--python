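"""Evaluation metrics and the speed/RMSE optimal-model selection rule.

Beyond the usual confusion-matrix metrics, candidate models are compared
on probability-RMSE — the root-mean-squared error between predicted class
probabilities and the binary labels, which separates models that all reach
the same thresholded accuracy — and on training speed.  The selection rule
reflects a real-time deployment priority: among candidates that reach the
accuracy floor, the fastest-training model wins, with RMSE as the
tie-break; a slower model is not preferred merely for a lower RMSE.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import UsageError

__all__ = [
    "ClassificationMetrics",
    "EvalReport",
    "SelectionVerdict",
    "probability_rmse",
    "classification_metrics",
    "make_report",
    "evaluate_model",
    "select_optimal",
]


def probability_rmse(probabilities, labels) -> float:
    """sqrt(mean((p_i - y_i)**2)) over predicted probabilities and labels."""
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    y = np.asarray(labels, dtype=np.float64).ravel()
    if p.size == 0 or p.size != y.size:
        raise UsageError("probabilities and labels must be non-empty, equal-length")
    return float(np.sqrt(np.mean((p - y) ** 2)))


@dataclass
class ClassificationMetrics:
    """Confusion matrix at a threshold plus the derived ratio metrics.

    Ratios with a 0/0 denominator are reported as 0 (with a warning), the
    documented degenerate-class convention.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float
    n_eval: int

    @property
    def confusion(self) -> np.ndarray:
        """2x2 counts [[TN, FP], [FN, TP]] (rows: true 0/1; cols: pred 0/1)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=np.int64)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is 0/0; reporting 0 by convention", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(probabilities, labels, threshold: float = 0.5) -> ClassificationMetrics:
    """Threshold the probabilities and compute the confusion-derived metrics."""
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(np.int64)
    if p.size == 0 or p.size != y.size:
        raise UsageError("probabilities and labels must be non-empty, equal-length")
    pred = (p >= threshold).astype(np.int64)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    n = p.size
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "F1")
    return ClassificationMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=(tp + tn) / n,
        precision=precision,
        recall=recall,
        f1=f1,
        threshold=threshold,
        n_eval=n,
    )


@dataclass
class EvalReport:
    """Per-model evaluation record used by the selection rule."""

    model_id: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    rmse: float
    training_seconds: float
    n_eval: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


def make_report(
    model_id: str,
    metrics: ClassificationMetrics,
    rmse: float,
    training_seconds: float,
) -> EvalReport:
    return EvalReport(
        model_id=model_id,
        accuracy=metrics.accuracy,
        precision=metrics.precision,
        recall=metrics.recall,
        f1=metrics.f1,
        tp=metrics.tp,
        fp=metrics.fp,
        fn=metrics.fn,
        tn=metrics.tn,
        rmse=rmse,
        training_seconds=training_seconds,
        n_eval=metrics.n_eval,
    )


def evaluate_model(model, X, y, model_id: str, training_seconds: float = float("nan")) -> EvalReport:
    """Run the model on (X, y) and assemble the full report."""
    Xf = np.asarray(X, np.float32) / 255.0 if np.asarray(X).dtype == np.uint8 else np.asarray(X, np.float32)
    p = model.predict_proba(Xf)
    return make_report(
        model_id,
        classification_metrics(p, y),
        probability_rmse(p, y),
        training_seconds,
    )


@dataclass
class SelectionVerdict:
    selected: EvalReport
    ranking: list[EvalReport]
    accuracy_floor: float
    floor_met: bool
    rationale: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected": self.selected.model_id,
                "accuracy_floor": self.accuracy_floor,
                "floor_met": self.floor_met,
                "rationale": self.rationale,
                "ranking": [dataclasses.asdict(r) for r in self.ranking],
            },
            indent=1,
        )


def select_optimal(reports: list[EvalReport], accuracy_floor: float = 1.0) -> SelectionVerdict:
    """Rank candidates: accuracy floor, then training speed, then RMSE.

    Candidates meeting the floor are ordered by training seconds ascending
    (real-time priority) with RMSE as tie-break; the ordering is invariant
    to the input order.  If no candidate meets the floor the best-accuracy
    candidate is selected with an explicit warning in the rationale.
    """
    if not reports:
        raise UsageError("select_optimal requires at least one report")
    eligible = [r for r in reports if r.accuracy >= accuracy_floor]
    if eligible:
        ranking = sorted(eligible, key=lambda r: (r.training_seconds, r.rmse, r.model_id))
        ranking += sorted(
            [r for r in reports if r.accuracy < accuracy_floor],
            key=lambda r: (-r.accuracy, r.training_seconds, r.model_id),
        )
        rationale = (
            f"{len(eligible)}/{len(reports)} candidates met the accuracy floor "
            f"{accuracy_floor}; selected the fastest-training of those "
            f"({ranking[0].model_id}, {ranking[0].training_seconds:.0f} s), "
            "with RMSE as tie-break"
        )
        return SelectionVerdict(ranking[0], ranking, accuracy_floor, True, rationale)
    warnings.warn("no candidate met the accuracy floor; falling back to best accuracy")
    ranking = sorted(reports, key=lambda r: (-r.accuracy, r.training_seconds, r.model_id))
    rationale = (
        f"WARNING: no candidate reached the accuracy floor {accuracy_floor}; "
        f"selected the best-accuracy candidate {ranking[0].model_id}"
    )
    return SelectionVerdict(ranking[0], ranking, accuracy_floor, False, rationale)
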