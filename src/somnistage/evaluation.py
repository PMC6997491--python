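"""Agreement statistics for sleep staging: accuracy, sensitivity, Cohen's Kappa.

With confusion counts ``C[i][j]`` (rows = true stage, columns = predicted),
row sums ``a_i``, column sums ``b_i`` and ``num`` total epochs:

    accuracy       = trace(C) / num
    sensitivity_i  = C[i][i] / a_i
    Pe             = sum_i a_i * b_i / num**2
    Kappa          = (accuracy - Pe) / (1 - Pe)

Undefined quantities (a stage absent from the truth, or Pe = 1) are reported
as missing values — never silently as 0 — so averages cannot be inflated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .record import STAGE_NAMES, STAGES


def confusion(true_labels, predicted_labels) -> np.ndarray:
    """5x5 count matrix; rows are the true stage, columns the predicted stage."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("true and predicted label sequences must be equal-length 1-D")
    if len(t) == 0:
        raise ValueError("label sequences must be non-empty")
    if t.min() < 0 or t.max() > 4 or p.min() < 0 or p.max() > 4:
        raise ValueError("stage labels must lie in 0..4")
    cm = np.zeros((5, 5), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Fraction of accurately scored epochs: trace / total."""
    cm = _check_cm(cm)
    return float(np.trace(cm)) / float(cm.sum())


def sensitivity(cm: np.ndarray, stage: int) -> float | None:
    """Per-stage recall ``C[i][i]/a_i``; None (with a warning) if stage absent."""
    cm = _check_cm(cm)
    if stage not in STAGES:
        raise ValueError("stage must be in 0..4")
    a_i = cm[stage].sum()
    if a_i == 0:
        warnings.warn(f"stage {STAGE_NAMES[stage]} absent from truth; sensitivity undefined",
                      stacklevel=2)
        return None
    return float(cm[stage, stage]) / float(a_i)


def expected_agreement(cm: np.ndarray) -> float:
    """Chance agreement from the marginals: ``Pe = sum_i a_i*b_i / num^2``."""
    cm = _check_cm(cm)
    a = cm.sum(axis=1).astype(float)
    b = cm.sum(axis=0).astype(float)
    num = cm.sum()
    return float((a * b).sum() / num**2)


def kappa(cm: np.ndarray) -> float | None:
    """Cohen's Kappa ``(accuracy - Pe)/(1 - Pe)``; None when Pe = 1."""
    pe = expected_agreement(cm)
    if pe >= 1.0 - 1e-15:
        warnings.warn("expected agreement is 1 (single-class margins); Kappa undefined",
                      stacklevel=2)
        return None
    return (accuracy(cm) - pe) / (1.0 - pe)


def _check_cm(cm) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.shape != (5, 5):
        raise ValueError("confusion matrix must be 5x5")
    if np.any(cm < 0):
        raise ValueError("confusion counts must be nonnegative")
    if cm.sum() == 0:
        raise ValueError("confusion matrix must contain at least one epoch")
    return cm


@dataclass
class EvalResult:
    """Bundle of the agreement statistics for one evaluation."""

    confusion_matrix: np.ndarray
    accuracy: float
    sensitivity: list[float | None]
    expected_agreement: float
    kappa: float | None
    coverage: float = 1.0  # fraction of the night's epochs actually evaluated

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": np.asarray(self.confusion_matrix).tolist(),
            "accuracy": self.accuracy,
            "sensitivity": {
                STAGE_NAMES[i]: (None if s is None else float(s))
                for i, s in enumerate(self.sensitivity)
            },
            "expected_agreement": self.expected_agreement,
            "kappa": None if self.kappa is None else float(self.kappa),
            "coverage": self.coverage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalResult":
        sens = [d["sensitivity"][name] for name in STAGE_NAMES]
        return cls(
            np.asarray(d["confusion_matrix"], dtype=int),
            float(d["accuracy"]),
            [None if s is None else float(s) for s in sens],
            float(d["expected_agreement"]),
            None if d["kappa"] is None else float(d["kappa"]),
            float(d.get("coverage", 1.0)),
        )


def evaluate(true_labels, predicted_labels, coverage: float = 1.0) -> EvalResult:
    """All agreement statistics for one truth/prediction pair."""
    cm = confusion(true_labels, predicted_labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sens = [sensitivity(cm, s) for s in STAGES]
        k = kappa(cm)
    return EvalResult(cm, accuracy(cm), sens, expected_agreement(cm), k, coverage)


def report(result: EvalResult, json_path, csv_path=None,
           plot_path=None, true_labels=None, predicted_labels=None) -> None:
    """Write the metrics JSON, a per-stage CSV table, and optionally a
    true-vs-predicted hypnogram overlay plot."""
    with open(json_path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    if csv_path is not None:
        cm = np.asarray(result.confusion_matrix)
        pd.DataFrame(
            {
                "stage": STAGE_NAMES,
                "true_epochs": cm.sum(axis=1),
                "predicted_epochs": cm.sum(axis=0),
                "sensitivity": [np.nan if s is None else s for s in result.sensitivity],
            }
        ).to_csv(csv_path, index=False)
    if plot_path is not None:
        if true_labels is None or predicted_labels is None:
            raise ValueError("hypnogram plot needs the true and predicted label sequences")
        plot_hypnograms(true_labels, predicted_labels, plot_path)


def plot_hypnograms(true_labels, predicted_labels, path) -> None:
    """Stacked step plots of the true and predicted hypnograms over the night."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    fig, axes = plt.subplots(2, 1, figsize=(10, 4), sharex=True)
    for ax, y, title in zip(axes, (t, p), ("ground truth", "predicted")):
        ax.step(np.arange(len(y)), y, where="post", lw=0.8)
        ax.set_yticks(range(5), STAGE_NAMES)
        ax.invert_yaxis()
        ax.set_ylabel(title)
    axes[1].set_xlabel("epoch (30 s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
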