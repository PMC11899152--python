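"""Health-outcome prediction head, task losses and evaluation metrics.

The head is a two-layer feed-forward network on the final fused vector with
a softmax output for classification or a linear output for regression.

Evaluation follows the sentiment-benchmark conventions for continuous
assessment scores in [-3, 3]:

* MAE — mean absolute error of the raw scores;
* PCC — Pearson correlation between predicted and true scores;
* Acc-2 — accuracy after the sign split (negative vs non-negative);
* F1 — F1 on that binary split (macro-averaged for multiclass tasks);
* Acc-7 — accuracy after rounding scores to integers clipped to [-3, 3]
  (bin edges at half-integers, 7 bins);
* a predicted-by-true confusion matrix.

For categorical tasks the report carries overall accuracy, macro-F1 and the
confusion matrix; the score-based fields stay unset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1

from ._tensor import Tensor
from .nn import FeedForward, Module, softmax

__all__ = [
    "PredictionOutput",
    "MetricReport",
    "PredictionHead",
    "classification_loss",
    "regression_loss",
    "evaluate",
]


@dataclass
class PredictionOutput:
    """Predicted class probabilities (with logits) or real scores."""

    probabilities: np.ndarray | None = None
    logits: np.ndarray | None = None
    scores: np.ndarray | None = None

    def predicted_classes(self) -> np.ndarray:
        if self.probabilities is None:
            raise ValueError("no class probabilities present")
        return self.probabilities.argmax(axis=-1)


@dataclass
class MetricReport:
    """Evaluation metrics; percentage metrics are on the 0-100 scale."""

    mae: float | None = None
    pcc: float | None = None
    acc2: float | None = None
    f1: float | None = None
    acc7: float | None = None
    accuracy: float | None = None
    macro_f1: float | None = None
    confusion_matrix: np.ndarray | None = None
    n: int = 0

    def as_dict(self) -> dict:
        out = {
            "mae": self.mae,
            "pcc": self.pcc,
            "acc2": self.acc2,
            "f1": self.f1,
            "acc7": self.acc7,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "n": self.n,
        }
        if self.confusion_matrix is not None:
            out["confusion_matrix"] = self.confusion_matrix.tolist()
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def plot_confusion(self, path: str | Path) -> None:
        """Render the confusion matrix as a heat map image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(self.confusion_matrix, cmap="viridis")
        ax.set_xlabel("true class")
        ax.set_ylabel("predicted class")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


class PredictionHead(Module):
    """MLP head: fused vector -> class probabilities or real score."""

    def __init__(
        self,
        d_in: int,
        hidden: int,
        task: str,
        n_classes: int | None,
        rng: np.random.Generator,
        dropout: float = 0.2,
    ):
        super().__init__()
        if task not in ("classification", "regression"):
            raise ValueError(f"unknown task {task!r}")
        self.task = task
        n_out = n_classes if task == "classification" else 1
        self.net = FeedForward(d_in, hidden, n_out, rng, dropout=dropout)

    def __call__(self, xi_final: Tensor) -> Tensor:
        """Logits (classification) or raw scores (regression)."""
        out = self.net(xi_final)
        if self.task == "regression":
            out = out.reshape(out.shape[0])
        return out

    def predict(self, xi_final: Tensor) -> PredictionOutput:
        out = self(xi_final)
        if self.task == "classification":
            probs = softmax(out, axis=-1)
            return PredictionOutput(probabilities=probs.data.copy(), logits=out.data.copy())
        return PredictionOutput(scores=out.data.copy())

    def param_norm_sq(self) -> Tensor:
        total = None
        for p in self.parameters():
            term = (p.reshape(p.size) ** 2).sum()
            total = term if total is None else total + term
        return total


LOG_FLOOR = 1e-12


def classification_loss(probabilities, labels, lam: float = 0.0, head_param_norm_sq=None):
    """Mean cross-entropy with a clamped log, plus the head L2 regulariser."""
    labels = np.asarray(labels)
    n_classes = probabilities.shape[-1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label index out of range")
    one_hot = np.eye(n_classes)[labels.astype(int)]
    picked = (probabilities * one_hot).sum(axis=-1)
    if isinstance(picked, Tensor):
        loss = -(picked.clip_min(LOG_FLOOR).log()).mean()
    else:
        loss = float(-np.log(np.maximum(picked, LOG_FLOOR)).mean())
    if lam != 0.0:
        if head_param_norm_sq is None:
            raise ValueError("lam != 0 requires the head parameter norm")
        loss = loss + (lam / 2.0) * head_param_norm_sq
    return loss


def regression_loss(predictions, targets, lam: float = 0.0, head_param_norm_sq=None):
    """Mean squared error plus the head L2 regulariser."""
    targets = np.asarray(targets, dtype=float)
    if predictions.shape != targets.shape:
        raise ValueError(f"shape mismatch: {predictions.shape} vs {targets.shape}")
    loss = ((predictions - targets) ** 2).mean()
    if isinstance(loss, np.floating):
        loss = float(loss)
    if lam != 0.0:
        if head_param_norm_sq is None:
            raise ValueError("lam != 0 requires the head parameter norm")
        loss = loss + (lam / 2.0) * head_param_norm_sq
    return loss


def _bin7(scores: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, clipped to [-3, 3] (7 bins)."""
    return np.clip(np.rint(scores), -3, 3).astype(int)


def evaluate(predictions, truth, task: str = "regression") -> MetricReport:
    """Score a set of predictions against ground truth.

    ``predictions`` is a score vector (regression) or an (n, C) probability
    matrix / class-index vector (classification). Needs >= 2 samples for the
    correlation; a constant truth vector leaves PCC unset with a warning.
    """
    truth = np.asarray(truth)
    n = len(truth)
    if task == "regression":
        scores = np.asarray(predictions, dtype=float)
        if scores.shape != truth.shape:
            raise ValueError("prediction/truth shape mismatch")
        mae = float(np.abs(scores - truth).mean())
        if n >= 2 and np.ptp(truth) > 0 and np.ptp(scores) > 0:
            pcc = float(stats.pearsonr(scores, truth)[0])
        else:
            warnings.warn("PCC undefined for constant inputs; omitted from the report")
            pcc = None
        pred_sign = (scores >= 0).astype(int)
        true_sign = (truth >= 0).astype(int)
        acc2 = float((pred_sign == true_sign).mean() * 100)
        f1 = float(_sk_f1(true_sign, pred_sign, average="binary", zero_division=0) * 100)
        pred_bin, true_bin = _bin7(scores), _bin7(truth)
        acc7 = float((pred_bin == true_bin).mean() * 100)
        labels7 = np.arange(-3, 4)
        conf = _sk_confusion(true_bin, pred_bin, labels=labels7).T  # predicted x true
        return MetricReport(mae=mae, pcc=pcc, acc2=acc2, f1=f1, acc7=acc7,
                            confusion_matrix=conf, n=n)

    preds = np.asarray(predictions)
    pred_cls = preds.argmax(axis=-1) if preds.ndim == 2 else preds.astype(int)
    labels = np.arange(max(int(truth.max()), int(pred_cls.max())) + 1)
    accuracy = float((pred_cls == truth).mean() * 100)
    macro_f1 = float(_sk_f1(truth, pred_cls, average="macro", zero_division=0) * 100)
    conf = _sk_confusion(truth, pred_cls, labels=labels).T  # predicted x true
    acc2 = accuracy if len(labels) == 2 else None
    return MetricReport(accuracy=accuracy, macro_f1=macro_f1, f1=macro_f1,
                        acc2=acc2, confusion_matrix=conf, n=n)


class GenerativeHooks:
    """No-op interface for downstream generative outputs.

    Placeholder hooks for a consultation summary, a health-state avatar and
    a natural-language explanation; this package never implements them.
    """

    def summary(self, xi_final: np.ndarray) -> None:
        return None

    def avatar(self, prediction, environment: np.ndarray) -> None:
        return None

    def explanation(self, prediction, xi_final: np.ndarray, environment: np.ndarray) -> None:
        return None
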