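"""Evaluation metrics for motion-state perception.

Classification metrics (accuracy, macro precision/recall/F1 from
one-vs-rest counts, mean average precision over classes from ranked
scores), temporal metrics (prediction Stability — one minus the mean
frame-to-frame Euclidean distance of successive probability vectors — and
segmental F1@k with interval-overlap matching, the standard score of the
action-segmentation literature), and the confusion matrix.

All rates are reported on [0, 1]; multiply by 100 only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "compute_metrics", "average_precision",
           "stability_score", "segments_from_labels", "segmental_f1",
           "confusion_matrix"]


@dataclass
class MetricsReport:
    accuracy: float
    precision: float           # macro
    recall: float              # macro
    f1: float                  # macro
    map: float = float("nan")
    f1_at_25: float = float("nan")
    stability: float = float("nan")
    per_class_ap: np.ndarray = field(default_factory=lambda: np.array([]))
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), int))

    def to_dict(self) -> dict:
        return {k: (float(v) if np.isscalar(v) or getattr(v, "ndim", 1) == 0
                    else np.asarray(v).tolist())
                for k, v in self.__dict__.items()}


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    return M


def _prf_macro(y_true, y_pred, classes):
    """One-vs-rest precision/recall/F1, macro-averaged over classes."""
    ps, rs, fs = [], [], []
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    for c in classes:
        tp = int(((y_pred == c) & (y_true == c)).sum())
        fp = int(((y_pred == c) & (y_true != c)).sum())
        fn = int(((y_pred != c) & (y_true == c)).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        ps.append(p); rs.append(r); fs.append(f)
    return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))


def average_precision(y_bin: np.ndarray, scores: np.ndarray,
                      eleven_point: bool = False) -> float:
    """AP = integral of the precision-recall step curve (all-point form);
    optionally the 11-point interpolated variant."""
    y_bin = np.asarray(y_bin, dtype=bool)
    n_pos = int(y_bin.sum())
    if n_pos == 0:
        return float("nan")
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y_sorted = y_bin[order]
    tp = np.cumsum(y_sorted)
    precision = tp / np.arange(1, len(y_sorted) + 1)
    recall = tp / n_pos
    if eleven_point:
        ap = 0.0
        for r in np.linspace(0, 1, 11):
            mask = recall >= r - 1e-12
            ap += precision[mask].max() if mask.any() else 0.0
        return ap / 11.0
    # sum of precision at each new positive (exact step integral)
    return float(precision[y_sorted].sum() / n_pos)


def stability_score(prob_seqs) -> float:
    """1 - mean_t ||y_t - y_{t-1}|| (Euclidean) over probability sequences,
    averaged over windows.  Constant predictions give exactly 1."""
    vals = []
    for probs in prob_seqs:
        probs = np.asarray(probs, dtype=float)
        if probs.shape[0] < 2:
            vals.append(1.0)
            continue
        d = np.linalg.norm(np.diff(probs, axis=0), axis=1)
        vals.append(1.0 - d.mean())
    return float(np.mean(vals))


def segments_from_labels(labels: np.ndarray):
    """Run-length encode a label sequence into (label, start, end) with
    half-open [start, end) intervals."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def segmental_f1(true_seqs, pred_seqs, overlap: float = 0.25) -> float:
    """Segmental F1@k: predicted segments count as true positives when
    their interval IoU with an unmatched same-label ground-truth segment
    reaches ``overlap`` (greedy one-to-one matching)."""
    tp = fp = fn = 0
    for y_true, y_pred in zip(true_seqs, pred_seqs):
        gt = segments_from_labels(y_true)
        pr = segments_from_labels(y_pred)
        used = [False] * len(gt)
        for lab, s, e in pr:
            best, best_j = 0.0, -1
            for j, (gl, gs, ge) in enumerate(gt):
                if used[j] or gl != lab:
                    continue
                inter = max(0, min(e, ge) - max(s, gs))
                union = max(e, ge) - min(s, gs)
                iou = inter / union if union else 0.0
                if iou > best:
                    best, best_j = iou, j
            if best >= overlap and best_j >= 0:
                tp += 1
                used[best_j] = True
            else:
                fp += 1
        fn += used.count(False)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return 2 * p * r / (p + r) if p + r else 0.0


def compute_metrics(y_true, y_pred, scores: np.ndarray | None = None,
                    phase_true=None, phase_pred=None, phase_probs=None,
                    classes=None, eleven_point_map: bool = False
                    ) -> MetricsReport:
    """Aggregate report for one evaluation run.

    Parameters
    ----------
    y_true, y_pred : per-window action labels.
    scores : [N, C] ranked class scores for mean average precision.
    phase_true, phase_pred : sequences of per-window frame-level phase
        labels for segmental F1@25.
    phase_probs : sequences of per-window phase probability arrays [T, P]
        for the Stability metric.
    classes : explicit class list (defaults to classes present in y_true).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    if classes is None:
        classes = np.unique(y_true)
    classes = np.asarray(classes)

    acc = float((y_true == y_pred).mean())
    prec, rec, f1 = _prf_macro(y_true, y_pred, classes)

    per_ap = np.array([])
    mAP = float("nan")
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape[0] != y_true.shape[0]:
            raise ValueError("scores/labels length mismatch")
        per_ap = np.array([
            average_precision(y_true == c, scores[:, i], eleven_point_map)
            for i, c in enumerate(classes)])
        mAP = float(np.nanmean(per_ap))

    f1_25 = float("nan")
    if phase_true is not None and phase_pred is not None:
        f1_25 = segmental_f1(phase_true, phase_pred, overlap=0.25)

    stab = float("nan")
    if phase_probs is not None:
        stab = stability_score(phase_probs)

    return MetricsReport(
        accuracy=acc, precision=prec, recall=rec, f1=f1, map=mAP,
        f1_at_25=f1_25, stability=stab, per_class_ap=per_ap,
        confusion=confusion_matrix(y_true, y_pred, classes))
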