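"""Top-k evaluation: ranked predictions, per-class metrics, confusion matrices.

An embryo's final condition often spans several states (e.g. edema together
with blood stasis), so besides the usual argmax (Top-1) evaluation a
prediction is also scored as correct if the true class appears among the
two or three highest-probability classes (Top-2 / Top-3).

Attribution rule for k > 1 (each sample contributes exactly once, so
confusion rows always sum to the true class counts): if the true class is
within the top k, the sample is a true positive for its class and lands on
the confusion diagonal; otherwise it is a false negative for the true class
and a false positive for the Top-1 predicted class only.

Per-class precision, recall and F1 use the standard definitions with the
0/0 -> 0 convention; macro averages are unweighted means over the five
classes; accuracy is the fraction of Top-k-correct samples (the trace of
the confusion matrix over the total).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phenotypes import N_CLASSES, PhenotypeClass
from .synthetic import LabeledImage


@dataclasses.dataclass(frozen=True)
class TopKPrediction:
    """All five classes ranked by descending probability for one image."""

    image_id: str
    ranked_classes: tuple[PhenotypeClass, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ranked_classes) != N_CLASSES or len(set(self.ranked_classes)) != N_CLASSES:
            raise ValueError("ranking must cover all five classes exactly once")
        p = np.asarray(self.probabilities)
        if len(p) != N_CLASSES or np.any(p < 0) or np.any(p > 1):
            raise ValueError("need five probabilities in [0, 1]")
        if np.any(np.diff(p) > 1e-12):
            raise ValueError("probabilities must be non-increasing")

    def top(self, k: int) -> tuple[PhenotypeClass, ...]:
        _validate_k(k)
        return self.ranked_classes[:k]


def _validate_k(k: int) -> None:
    if not 1 <= k <= N_CLASSES:
        raise ValueError(f"k must lie in [1, {N_CLASSES}]")


def rank_probabilities(probs: np.ndarray, image_id: str = "") -> TopKPrediction:
    """Build a ranked prediction from one probability vector.

    Ties are broken by ascending class index (stable descending sort).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (N_CLASSES,):
        raise ValueError(f"expected a length-{N_CLASSES} probability vector")
    order = np.argsort(-probs, kind="stable")
    return TopKPrediction(
        image_id=image_id,
        ranked_classes=tuple(PhenotypeClass(int(i)) for i in order),
        probabilities=tuple(float(probs[i]) for i in order),
    )


def predict_topk(model, img: LabeledImage | np.ndarray, k: int = 1) -> TopKPrediction:
    """Rank a model's class probabilities for one image (all 5 classes kept;
    ``k`` is validated so the caller's downstream slice is legal)."""
    _validate_k(k)
    pixels = img.pixels if isinstance(img, LabeledImage) else np.asarray(img)
    probs = model.predict_proba(pixels[None, ...])[0]
    image_id = img.provenance if isinstance(img, LabeledImage) else ""
    return rank_probabilities(probs, image_id=image_id)


def is_correct_topk(pred: TopKPrediction, true_class: PhenotypeClass, k: int) -> bool:
    """True iff the true class is among the k highest-ranked classes."""
    _validate_k(k)
    return PhenotypeClass(true_class) in pred.top(k)


def confusion_topk(
    preds: Sequence[TopKPrediction], truths: Sequence[PhenotypeClass], k: int
) -> np.ndarray:
    """5x5 count matrix under the Top-k attribution rule (rows = truth)."""
    _validate_k(k)
    if len(preds) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    matrix = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for pred, truth in zip(preds, truths):
        truth = PhenotypeClass(truth)
        if truth in pred.top(k):
            matrix[truth, truth] += 1
        else:
            matrix[truth, pred.ranked_classes[0]] += 1
    return matrix


def macro_average(per_class_values: Sequence[float]) -> float:
    """Unweighted arithmetic mean over the five classes."""
    values = np.asarray(per_class_values, dtype=float)
    if values.shape != (N_CLASSES,):
        raise ValueError(f"expected exactly {N_CLASSES} values")
    return float(values.mean())


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    """Per-class and macro metrics plus the confusion matrix for one k."""

    k: int
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    confusion: np.ndarray
    n_samples: int

    def rounded(self, decimals: int = 2) -> dict:
        """Metrics rounded for reporting (raw values stay on the dataclass)."""
        r = lambda v: round(float(v), decimals)
        return {
            "k": self.k,
            "per_class": {
                cls.display_name: {
                    "precision": r(self.precision[cls]),
                    "recall": r(self.recall[cls]),
                    "f1": r(self.f1[cls]),
                }
                for cls in PhenotypeClass
            },
            "macro": {
                "precision": r(self.macro_precision),
                "recall": r(self.macro_recall),
                "f1": r(self.macro_f1),
            },
            "accuracy": r(self.accuracy),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": cls.display_name,
                "precision": self.precision[cls],
                "recall": self.recall[cls],
                "f1": self.f1[cls],
            }
            for cls in PhenotypeClass
        ]
        rows.append(
            {
                "class": "Average",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            }
        )
        return pd.DataFrame(rows)

    def save(self, stem: str | Path) -> None:
        """Write CSV (per-class), JSON (full) and a PNG confusion heatmap."""
        stem = Path(stem)
        self.to_frame().to_csv(stem.with_suffix(".csv"), index=False)
        payload = self.rounded()
        payload["confusion"] = self.confusion.tolist()
        payload["n_samples"] = self.n_samples
        stem.with_suffix(".json").write_text(json.dumps(payload, indent=2))
        plot_confusion(self.confusion, self.k, stem.with_suffix(".png"))


def compute_report(
    preds: Sequence[TopKPrediction], truths: Sequence[PhenotypeClass], k: int
) -> EvaluationReport:
    """Score a prediction set under the Top-k rule."""
    if not preds:
        raise ValueError("prediction set must be non-empty")
    if len(preds) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    matrix = confusion_topk(preds, truths, k)
    tp = np.diag(matrix).astype(float)
    fn = matrix.sum(axis=1) - np.diag(matrix)
    fp = matrix.sum(axis=0) - np.diag(matrix)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    f1 = np.array([f1_score(p, r) for p, r in zip(precision, recall)])
    return EvaluationReport(
        k=k,
        precision=tuple(precision),
        recall=tuple(recall),
        f1=tuple(f1),
        macro_precision=macro_average(precision),
        macro_recall=macro_average(recall),
        macro_f1=macro_average(f1),
        accuracy=float(np.trace(matrix) / matrix.sum()),
        confusion=matrix,
        n_samples=len(preds),
    )


def evaluate_model(
    model, images: Sequence[LabeledImage], ks: Sequence[int] = (1, 2, 3)
) -> dict[int, EvaluationReport]:
    """Predict once, score under every requested k."""
    for k in ks:
        _validate_k(k)
    probs = model.predict_proba(images)
    preds = [rank_probabilities(p, image_id=str(i)) for i, p in enumerate(probs)]
    truths = [img.label for img in images]
    return {k: compute_report(preds, truths, k) for k in ks}


def plot_confusion(matrix: np.ndarray, k: int, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(matrix, cmap="Blues")
    names = [cls.display_name for cls in PhenotypeClass]
    ax.set_xticks(range(N_CLASSES), names, rotation=45, ha="right")
    ax.set_yticks(range(N_CLASSES), names)
    ax.set_xlabel("Predicted class")
    ax.set_ylabel("True class")
    ax.set_title(f"Confusion matrix (Top-{k})")
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            ax.text(j, i, str(matrix[i, j]), ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
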