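"""Delineation performance metrics.

Node-level confusion matrices, one-vs-rest per-class sensitivity / precision
/ specificity / accuracy / F1, macro and micro summaries, and precision-
recall curves with trapezoidal AUC.  The zero-padding class can be excluded
(``waveforms_only``) so padded window tails do not inflate the scores; PAD
stays part of the training target regardless.

Metrics with a zero denominator (e.g. sensitivity of a class absent from the
truth) are reported as ``None`` and listed in ``undefined`` — never silently
coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .records import CLASS_NAMES, N_CLASSES, PAD, LabelMask


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValidationError("counts must be K x K matching class_names")
        if (self.counts < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _flatten_labels(y) -> np.ndarray:
    if isinstance(y, LabelMask):
        return y.classes
    arrs = []
    for item in y if isinstance(y, (list, tuple)) else [y]:
        arrs.append(item.classes if isinstance(item, LabelMask) else np.asarray(item))
    return np.concatenate([a.ravel() for a in arrs]).astype(np.int64)


def confusion_matrix(y_true, y_pred, classes: int = N_CLASSES, *,
                     waveforms_only: bool = False) -> ConfusionMatrix:
    """Node-level confusion matrix over flattened label streams.

    ``y_true``/``y_pred`` may be arrays, :class:`LabelMask` objects, or lists
    of either.  With ``waveforms_only`` the positions whose *true* class is
    PAD are dropped before counting.
    """
    t = _flatten_labels(y_true)
    p = _flatten_labels(y_pred)
    if t.size != p.size:
        raise ValidationError(f"length mismatch: {t.size} true vs {p.size} predicted")
    if t.size and (max(t.max(), p.max()) >= classes or min(t.min(), p.min()) < 0):
        raise ValidationError(f"labels outside 0..{classes - 1}")
    if waveforms_only:
        keep = t != PAD
        t, p = t[keep], p[keep]
    counts = np.bincount(t * classes + p, minlength=classes * classes)
    names = CLASS_NAMES[:classes] if classes <= N_CLASSES else tuple(map(str, range(classes)))
    return ConfusionMatrix(counts.reshape(classes, classes), tuple(names))


@dataclass
class ClassMetrics:
    """One-vs-rest metrics for a single class, fractions in [0, 1].

    A metric whose denominator is zero is ``None`` and named in
    ``undefined``.
    """

    sensitivity: float | None
    precision: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None
    undefined: tuple[str, ...] = field(default_factory=tuple)


def _ratio(num: int, den: int):
    return num / den if den else None


def class_metrics(cm: ConfusionMatrix, k: int) -> ClassMetrics:
    """One-vs-rest metrics for class ``k`` from a confusion matrix."""
    K = cm.counts.shape[0]
    if not 0 <= k < K:
        raise ValidationError(f"class index {k} outside 0..{K - 1}")
    tp = int(cm.counts[k, k])
    fn = int(cm.counts[k].sum()) - tp
    fp = int(cm.counts[:, k].sum()) - tp
    tn = cm.total - tp - fn - fp
    sens = _ratio(tp, tp + fn)
    prec = _ratio(tp, tp + fp)
    spec = _ratio(tn, tn + fp)
    acc = _ratio(tp + tn, cm.total)
    f1 = (2 * prec * sens / (prec + sens)
          if prec is not None and sens is not None and (prec + sens) > 0 else None)
    undefined = tuple(
        name for name, v in
        (("sensitivity", sens), ("precision", prec), ("specificity", spec),
         ("accuracy", acc), ("f1", f1))
        if v is None
    )
    return ClassMetrics(sens, prec, spec, acc, f1, undefined)


def macro_metrics(cm: ConfusionMatrix, classes=None) -> dict[str, float]:
    """Arithmetic mean of per-class metrics over ``classes`` (default all).

    Classes with an undefined value for a metric are excluded from that
    metric's mean.
    """
    classes = range(cm.counts.shape[0]) if classes is None else classes
    per = [class_metrics(cm, k) for k in classes]
    out = {}
    for name in ("sensitivity", "precision", "specificity", "accuracy", "f1"):
        vals = [getattr(m, name) for m in per if getattr(m, name) is not None]
        out[name] = float(np.mean(vals)) if vals else None
    return out


def micro_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Micro-averaged (pooled-count) one-vs-rest metrics."""
    K = cm.counts.shape[0]
    tp = fp = fn = tn = 0
    for k in range(K):
        m_tp = int(cm.counts[k, k])
        m_fn = int(cm.counts[k].sum()) - m_tp
        m_fp = int(cm.counts[:, k].sum()) - m_tp
        tp += m_tp
        fn += m_fn
        fp += m_fp
        tn += cm.total - m_tp - m_fn - m_fp
    sens = _ratio(tp, tp + fn)
    prec = _ratio(tp, tp + fp)
    f1 = 2 * prec * sens / (prec + sens) if prec and sens else None
    return {
        "sensitivity": sens,
        "precision": prec,
        "specificity": _ratio(tn, tn + fp),
        "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
        "f1": f1,
    }


def pr_curve(scores, y_true, positive_class: int | None = None):
    """Precision-recall curve and trapezoidal AUC.

    ``scores`` are per-node probabilities of the positive class; ``y_true``
    is a binary indicator stream (or, with ``positive_class`` given, a class
    stream that is binarized first).  One (recall, precision) point is
    emitted at every distinct score threshold, recall nondecreasing.
    """
    s = np.asarray(scores, dtype=float).ravel()
    t = _flatten_labels(y_true)
    if positive_class is not None:
        t = (t == positive_class).astype(int)
    if s.size != t.size:
        raise ValidationError(f"length mismatch: {s.size} scores vs {t.size} labels")
    if s.size and (s.min() < 0 or s.max() > 1):
        raise ValidationError("scores must lie in [0, 1]")
    n_pos = int(t.sum())
    if n_pos == 0 or n_pos == t.size:
        raise ValidationError("P-R curve undefined when truth is all one class")

    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    tp_cum = np.cumsum(t_sorted)
    fp_cum = np.cumsum(1 - t_sorted)
    # threshold boundaries: last occurrence of each distinct score
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    idx = np.concatenate((distinct, [s_sorted.size - 1]))
    recall = tp_cum[idx] / n_pos
    precision = tp_cum[idx] / (tp_cum[idx] + fp_cum[idx])
    points = list(zip(recall.tolist(), precision.tolist()))
    # integrate from recall 0 (precision anchored at the first point)
    r = np.concatenate(([0.0], recall))
    p = np.concatenate(([precision[0]], precision))
    auc = float(np.trapezoid(p, r))
    return points, auc
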