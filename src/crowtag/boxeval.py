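"""Detection evaluation by interval IoU matching.

Predicted vocalization boxes are paired one-to-one with annotated boxes,
class-agnostically, using the intersection-over-union of their time
intervals: a pair is admissible only when its IoU strictly exceeds the
threshold (default 0.5).  Among admissible pairings the matcher maximizes
the number of pairs and, among maximal pairings, the total IoU — solved
exactly as a linear assignment on the thresholded IoU graph, so the result
is deterministic and independent of input row order.

Labels are compared after matching: a matched pair with agreeing labels is
a true positive for that class; with differing labels it counts as a false
negative for the annotated class and a false positive for the predicted
class.  The Unknown label is neutral throughout: unmatched Unknown
annotations are not penalized, pairs involving an Unknown annotation
contribute nothing, and predictions labelled Unknown (maximum class
probability at or below 0.5) do not enter the four-class scores.

Per-class precision, recall and F1 are computed from the tallied counts,
and macro metrics are their unweighted means over the four scored classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .formats_io import CLASSES, UNKNOWN_LABEL, EventBox, SelectionTable


@dataclass(frozen=True)
class EvalConfig:
    """Matching and scoring configuration.

    ``iou_threshold`` is compared strictly (a pair with IoU exactly equal to
    the threshold is rejected).  ``classes`` are the scored classes; the
    ``unknown_label`` is neutral in scoring.
    """

    iou_threshold: float = 0.5
    classes: tuple[str, ...] = CLASSES
    unknown_label: str = UNKNOWN_LABEL

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_threshold <= 1.0:
            raise ValueError(f"iou_threshold outside (0, 1]: {self.iou_threshold}")
        if len(self.classes) != 4:
            raise ValueError("exactly 4 scored classes expected")


@dataclass
class MatchResult:
    """One-to-one pairing between annotation and prediction indices.

    ``pairs`` holds (annotation index, prediction index, iou) triples; the
    unmatched index lists partition the remainder of both inputs.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_annotations: list[int]
    unmatched_predictions: list[int]


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


@dataclass
class MetricsTable:
    """Per-class and macro precision/recall/F1 derived from match counts.

    Zero-denominator metrics are 0 by convention and the affected
    (class, metric) pairs are listed in ``zero_denominator``.
    """

    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    zero_denominator: list[tuple[str, str]] = field(default_factory=list)


def interval_iou(a: EventBox, b: EventBox) -> float:
    """Intersection-over-union of two time intervals (symmetric, in [0, 1]).

    Half-open intervals: boxes that merely touch at an endpoint have IoU 0.
    """
    if a.duration_s <= 0 or b.duration_s <= 0:
        raise ValueError("zero-length interval has undefined IoU")
    inter = min(a.stop_s, b.stop_s) - max(a.start_s, b.start_s)
    if inter <= 0:
        return 0.0
    union = max(a.stop_s, b.stop_s) - min(a.start_s, b.start_s)
    return inter / union


def _match_group(
    annotations: Sequence[EventBox],
    predictions: Sequence[EventBox],
    threshold: float,
) -> list[tuple[int, int, float]]:
    """Optimal one-to-one pairing within one file's boxes.

    Weight each admissible (IoU > threshold) edge as ``iou + B`` with B
    larger than any achievable total IoU, so the assignment maximizes pair
    count first and total IoU second.
    """
    n, m = len(annotations), len(predictions)
    if n == 0 or m == 0:
        return []
    iou = np.zeros((n, m))
    for i, a in enumerate(annotations):
        for j, p in enumerate(predictions):
            iou[i, j] = interval_iou(a, p)
    valid = iou > threshold
    bonus = float(min(n, m)) + 1.0
    weights = np.where(valid, iou + bonus, 0.0)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    return [
        (int(i), int(j), float(iou[i, j]))
        for i, j in zip(rows, cols)
        if valid[i, j]
    ]


def match_boxes(
    annotations: SelectionTable,
    predictions: SelectionTable,
    cfg: EvalConfig = EvalConfig(),
) -> MatchResult:
    """Match predictions to annotations one-to-one under the IoU threshold.

    Matching is computed per ``file_id`` independently (timebases are
    file-local); indices in the result refer to row positions in the input
    tables.  Raises if the two tables cover different file_id sets (only
    checked when both are nonempty, so a run with every event missed is
    still evaluable).
    """
    ann_files = annotations.file_ids()
    pred_files = predictions.file_ids()
    if len(annotations) and len(predictions) and ann_files != pred_files:
        raise ValueError(
            f"mismatched file_id sets: annotations {sorted(map(str, ann_files))} "
            f"vs predictions {sorted(map(str, pred_files))}"
        )
    pairs: list[tuple[int, int, float]] = []
    for fid in sorted(ann_files | pred_files, key=str):
        ai = [i for i, b in enumerate(annotations) if b.file_id == fid]
        pi = [j for j, b in enumerate(predictions) if b.file_id == fid]
        local = _match_group(
            [annotations[i] for i in ai],
            [predictions[j] for j in pi],
            cfg.iou_threshold,
        )
        pairs.extend((ai[i], pi[j], iou) for i, j, iou in local)
    pairs.sort()
    matched_a = {i for i, _, _ in pairs}
    matched_p = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_annotations=[i for i in range(len(annotations)) if i not in matched_a],
        unmatched_predictions=[j for j in range(len(predictions)) if j not in matched_p],
    )


def confusion_counts(
    match: MatchResult,
    annotations: SelectionTable,
    predictions: SelectionTable,
    cfg: EvalConfig = EvalConfig(),
) -> dict[str, ClassCounts]:
    """Tally per-class TP/FP/FN from a match, with neutral Unknown handling."""
    for box in list(annotations) + list(predictions):
        if box.label not in cfg.classes and box.label != cfg.unknown_label:
            raise ValueError(f"label {box.label!r} outside allowed set")
    counts = {c: ClassCounts() for c in cfg.classes}
    unk = cfg.unknown_label
    for i, j, _ in match.pairs:
        true, pred = annotations[i].label, predictions[j].label
        if true == unk or pred == unk:
            continue  # neutral: no credit, no penalty
        if true == pred:
            counts[true].tp += 1
        else:
            counts[true].fn += 1
            counts[pred].fp += 1
    for i in match.unmatched_annotations:
        label = annotations[i].label
        if label != unk:
            counts[label].fn += 1
    for j in match.unmatched_predictions:
        label = predictions[j].label
        if label != unk:
            counts[label].fp += 1
    return counts


def detection_counts(
    match: MatchResult,
    annotations: SelectionTable,
    cfg: EvalConfig = EvalConfig(),
) -> ClassCounts:
    """Class-blind detection-level counts (Unknown annotations still neutral
    when missed)."""
    c = ClassCounts(tp=len(match.pairs), fp=len(match.unmatched_predictions))
    c.fn = sum(
        1 for i in match.unmatched_annotations
        if annotations[i].label != cfg.unknown_label
    )
    return c


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float, list[str]]:
    flags = []
    if tp + fp == 0:
        precision, _ = 0.0, flags.append("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, _ = 0.0, flags.append("recall")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, _ = 0.0, flags.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1, flags


def compute_metrics(
    counts: Mapping[str, ClassCounts] | Mapping[str, tuple[int, int, int]],
    cfg: EvalConfig = EvalConfig(),
) -> MetricsTable:
    """Per-class precision/recall/F1 and their macro (unweighted) means.

    ``counts`` maps each scored class to a :class:`ClassCounts` or a
    ``(tp, fp, fn)`` triple.  Zero denominators yield 0 and are flagged.
    """
    per_class: dict[str, dict[str, float]] = {}
    zero_flags: list[tuple[str, str]] = []
    for cls in cfg.classes:
        c = counts[cls]
        tp, fp, fn = (c.tp, c.fp, c.fn) if isinstance(c, ClassCounts) else c
        if min(tp, fp, fn) < 0:
            raise ValueError(f"negative count for class {cls!r}")
        precision, recall, f1, flags = _prf(tp, fp, fn)
        zero_flags.extend((cls, m) for m in flags)
        per_class[cls] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1,
        }
    return MetricsTable(
        per_class=per_class,
        macro_precision=float(np.mean([per_class[c]["precision"] for c in cfg.classes])),
        macro_recall=float(np.mean([per_class[c]["recall"] for c in cfg.classes])),
        macro_f1=float(np.mean([per_class[c]["f1"] for c in cfg.classes])),
        zero_denominator=zero_flags,
    )


def evaluate(
    annotations: SelectionTable,
    predictions: SelectionTable,
    cfg: EvalConfig = EvalConfig(),
) -> MetricsTable:
    """Match, tally and score in one call."""
    match = match_boxes(annotations, predictions, cfg)
    return compute_metrics(confusion_counts(match, annotations, predictions, cfg), cfg)
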