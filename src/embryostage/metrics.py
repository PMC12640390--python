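"""Classification metrics for single-frame stage predictions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .ontology import ALL_STAGES, RARE_STAGES, StageLabel, parse_label

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "classification_metrics",
    "inverse_class_frequency_weights",
]

DEFAULT_EXCLUDE: frozenset[StageLabel] = frozenset(
    parse_label(n) for n in RARE_STAGES
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Raw counts and row-normalised percentages, rows/columns in ordinal order.

    Rows with zero support appear in ``zero_support`` and carry NaN in
    the percentage matrix.
    """

    counts: np.ndarray
    percentages: np.ndarray
    labels: tuple[StageLabel, ...]
    zero_support: tuple[StageLabel, ...]


def confusion_matrix(
    y_true: list[StageLabel], y_pred: list[StageLabel]
) -> ConfusionMatrix:
    """17x17 confusion matrix; percentages are row-normalised to 100."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if len(y_true) == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    ordinals = list(range(len(ALL_STAGES)))
    counts = _sk_confusion(
        [s.ordinal for s in y_true], [s.ordinal for s in y_pred], labels=ordinals
    )
    support = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / support[:, None]
    zero = tuple(ALL_STAGES[i] for i in np.flatnonzero(support == 0))
    return ConfusionMatrix(counts, pct, ALL_STAGES, zero)


def classification_metrics(
    y_true: list[StageLabel],
    y_pred: list[StageLabel],
    exclude: frozenset[StageLabel] = DEFAULT_EXCLUDE,
) -> dict[str, float]:
    """Accuracy plus macro-averaged precision/recall/F1.

    Frames whose *true* label is in ``exclude`` (default: the rare tHB
    stage) are dropped first.  Macro averages run over classes with
    nonzero support in the retained truth; unsupported classes are
    skipped, not scored as zero.
    """
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    keep = [i for i, t in enumerate(y_true) if t not in exclude]
    if not keep:
        raise ValueError("no frames left after exclusion")
    t = np.array([y_true[i].ordinal for i in keep])
    p = np.array([y_pred[i].ordinal for i in keep])
    supported = sorted(set(t.tolist()))
    precision, recall, f1, _ = precision_recall_fscore_support(
        t, p, labels=supported, average="macro", zero_division=0
    )
    return {
        "accuracy": float(np.mean(t == p)),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
    }


def inverse_class_frequency_weights(counts: np.ndarray) -> np.ndarray:
    """Per-class loss weights ``w_c = (N/K) / n_c``.

    With this normalisation the count-weighted mean weight is 1, so the
    overall loss scale is unchanged: ``sum(w_c * n_c) == N``.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or len(counts) == 0:
        raise ValueError("counts must be a non-empty 1-D array")
    if np.any(counts <= 0):
        bad = np.flatnonzero(counts <= 0).tolist()
        raise ValueError(
            f"classes at positions {bad} have zero samples; exclude them before "
            "computing inverse-frequency weights"
        )
    n_total = counts.sum()
    return (n_total / len(counts)) / counts
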