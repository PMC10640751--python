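"""Semantic and instance segmentation metrics for organ-labeled clouds.

Semantic metrics are the per-class Precision, Recall, F1 and IoU computed
from a point-level confusion table and macro-averaged over classes.
Instance metrics follow the coverage family used for leaf instance
segmentation:

* ``mCov`` — mean over ground-truth instances of the best IoU achieved by
  any predicted instance of the same class;
* ``mWCov`` — the same, with each ground-truth instance weighted by its
  share of the class's points;
* ``mPrec`` / ``mRec`` — fraction of predicted (resp. ground-truth)
  instances matched at IoU > 0.5, averaged over the instance-bearing
  classes.

A small-cluster filter is provided to mirror the usual inference
post-processing step: predicted instances smaller than 1% of the mean
predicted-instance size are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionTable",
    "SemanticReport",
    "InstancePartition",
    "InstanceReport",
    "confusion",
    "semantic_report",
    "instance_iou",
    "coverage",
    "prec_rec_instances",
    "instance_report",
    "filter_small_clusters",
    "partition_from_labels",
]


@dataclass
class ConfusionTable:
    """Per-class TP/FP/FN point counts for ``C`` semantic classes."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        self.tp = np.asarray(self.tp, dtype=np.int64)
        self.fp = np.asarray(self.fp, dtype=np.int64)
        self.fn = np.asarray(self.fn, dtype=np.int64)
        if not (self.tp.shape == self.fp.shape == self.fn.shape):
            raise ValueError("tp, fp, fn must have equal length")
        if min(self.tp.min(initial=0), self.fp.min(initial=0),
               self.fn.min(initial=0)) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.tp)


@dataclass
class SemanticReport:
    """Per-class and macro-averaged semantic metrics, all in [0, 1]."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    iou: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_iou: float


@dataclass
class InstancePartition:
    """Instances as disjoint point-index sets, each with a semantic class.

    ``groups`` maps instance id -> array of point indices; ``class_of``
    maps instance id -> semantic class.
    """

    groups: dict = field(default_factory=dict)
    class_of: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for gid, idx in self.groups.items():
            pts = set(np.asarray(idx).tolist())
            if seen & pts:
                raise ValueError(f"instance {gid} overlaps another instance")
            seen |= pts
        missing = set(self.groups) - set(self.class_of)
        if missing:
            raise ValueError(f"instances without a class: {sorted(missing)}")

    @property
    def classes(self) -> list[int]:
        return sorted({self.class_of[g] for g in self.groups})

    def by_class(self, c: int) -> list:
        return [g for g in self.groups if self.class_of[g] == c]

    def sizes(self) -> dict:
        return {g: len(self.groups[g]) for g in self.groups}


@dataclass
class InstanceReport:
    """Instance-level summary metrics, all in [0, 1]."""

    mcov: float
    mwcov: float
    mprec: float
    mrec: float
    n_instance_classes: int


def partition_from_labels(
    ins: np.ndarray, sem: np.ndarray | None = None
) -> InstancePartition:
    """Build a partition from label vectors; ``ins < 0`` points are skipped.

    When ``sem`` is given each instance's class is the majority semantic
    label of its points (ties to the smallest label); otherwise all
    instances share class 0.
    """
    ins = np.asarray(ins)
    groups: dict = {}
    class_of: dict = {}
    for gid in np.unique(ins):
        if gid < 0:
            continue
        idx = np.flatnonzero(ins == gid)
        groups[int(gid)] = idx
        if sem is None:
            class_of[int(gid)] = 0
        else:
            uniq, counts = np.unique(np.asarray(sem)[idx],
                                     return_counts=True)
            class_of[int(gid)] = int(uniq[np.argmax(counts)])
    return InstancePartition(groups=groups, class_of=class_of)


# ---------------------------------------------------------------------------
# semantic metrics
# ---------------------------------------------------------------------------

def confusion(pred_sem, gt_sem, n_classes: int) -> ConfusionTable:
    """Point-level per-class confusion counts."""
    pred = np.asarray(pred_sem, dtype=np.int64)
    gt = np.asarray(gt_sem, dtype=np.int64)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt label vectors differ in length")
    for name, arr in (("pred", pred), ("gt", gt)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    hit = pred == gt
    np.add.at(tp, gt[hit], 1)
    np.add.at(fp, pred[~hit], 1)
    np.add.at(fn, gt[~hit], 1)
    return ConfusionTable(tp=tp, fp=fp, fn=fn)


def _safe_div(num, den):
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def semantic_report(
    table: ConfusionTable, average: str = "macro"
) -> SemanticReport:
    """Precision, Recall, F1, IoU per class plus the class average.

    Classes absent from both prediction and ground truth
    (``TP + FP + FN = 0``) are excluded from the macro mean; within a
    class an empty denominator scores 0. ``average="micro"`` pools the
    counts over classes instead.
    """
    tp, fp, fn = (
        table.tp.astype(float), table.fp.astype(float), table.fn.astype(float)
    )
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    iou = _safe_div(tp, tp + fp + fn)
    present = (tp + fp + fn) > 0
    if average == "macro":
        if not present.any():
            raise ValueError("no class has any point")
        means = [m[present].mean() for m in (precision, recall, f1, iou)]
    elif average == "micro":
        p = _safe_div(tp.sum(), tp.sum() + fp.sum()).item()
        r = _safe_div(tp.sum(), tp.sum() + fn.sum()).item()
        means = [
            p, r,
            0.0 if p + r == 0 else 2 * p * r / (p + r),
            _safe_div(tp.sum(), tp.sum() + fp.sum() + fn.sum()).item(),
        ]
    else:
        raise ValueError("average must be 'macro' or 'micro'")
    return SemanticReport(
        precision=precision, recall=recall, f1=f1, iou=iou,
        macro_precision=float(means[0]), macro_recall=float(means[1]),
        macro_f1=float(means[2]), macro_iou=float(means[3]),
    )


# ---------------------------------------------------------------------------
# instance metrics
# ---------------------------------------------------------------------------

def instance_iou(a, b) -> float:
    """IoU of two point-index sets; both empty is an error."""
    sa, sb = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    union = sa | sb
    if not union:
        raise ValueError("IoU of two empty sets is undefined")
    return len(sa & sb) / len(union)


def _best_ious(gt: InstancePartition, pred: InstancePartition, c: int):
    """Per GT instance of class c: best IoU over predictions of class c."""
    gids = gt.by_class(c)
    pids = pred.by_class(c)
    best = {}
    for g in gids:
        best[g] = max(
            (instance_iou(gt.groups[g], pred.groups[p]) for p in pids),
            default=0.0,
        )
    return best


def coverage(
    gt: InstancePartition, pred: InstancePartition
) -> tuple[float, float]:
    """(mCov, mWCov): per-class best-IoU coverage, macro-averaged.

    Within each instance-bearing class, every ground-truth instance
    contributes its best IoU against the predicted instances of that class
    (0 when nothing overlaps); mCov averages these uniformly, mWCov weights
    each instance by its share of the class's ground-truth points. The
    per-class values are then averaged over classes.
    """
    if not gt.groups:
        raise ValueError("ground truth has no instances")
    covs, wcovs = [], []
    for c in gt.classes:
        best = _best_ious(gt, pred, c)
        sizes = np.array([len(gt.groups[g]) for g in best], dtype=float)
        vals = np.array(list(best.values()))
        covs.append(vals.mean())
        wcovs.append(float((sizes / sizes.sum()) @ vals))
    return float(np.mean(covs)), float(np.mean(wcovs))


def prec_rec_instances(
    gt: InstancePartition,
    pred: InstancePartition,
    iou_threshold: float = 0.5,
) -> tuple[float, float]:
    """(mPrec, mRec) at the given IoU threshold, averaged over classes.

    A predicted instance is a true positive when its IoU with some
    ground-truth instance of the same class exceeds the threshold. With a
    threshold above 0.5 such matches are automatically one-to-one (two
    predictions cannot each cover more than half of the same instance), so
    no explicit assignment step is needed. A class with no predicted
    instances contributes precision 0.
    """
    if not gt.groups:
        raise ValueError("ground truth has no instances")
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must lie in (0, 1)")
    precs, recs = [], []
    for c in gt.classes:
        gids = gt.by_class(c)
        pids = pred.by_class(c)
        tp = 0
        matched_gt: set[int] = set()
        for p in pids:
            for g in gids:
                if instance_iou(gt.groups[g], pred.groups[p]) > iou_threshold:
                    tp += 1
                    # IoU > 0.5 pairings are mutually exclusive
                    assert g not in matched_gt
                    matched_gt.add(g)
                    break
        precs.append(tp / len(pids) if pids else 0.0)
        recs.append(tp / len(gids))
    return float(np.mean(precs)), float(np.mean(recs))


def instance_report(
    gt: InstancePartition,
    pred: InstancePartition,
    iou_threshold: float = 0.5,
) -> InstanceReport:
    """All four instance metrics in one pass."""
    mcov, mwcov = coverage(gt, pred)
    mprec, mrec = prec_rec_instances(gt, pred, iou_threshold=iou_threshold)
    return InstanceReport(
        mcov=mcov, mwcov=mwcov, mprec=mprec, mrec=mrec,
        n_instance_classes=len(gt.classes),
    )


def filter_small_clusters(
    pred: InstancePartition, fraction: float = 0.01
) -> InstancePartition:
    """Drop predicted instances smaller than ``fraction`` of the mean size.

    The mean instance size is computed before any removal, matching the
    over-segmentation guard applied after embedding clustering at
    inference time.
    """
    if not pred.groups:
        raise ValueError("prediction has no instances")
    sizes = pred.sizes()
    mean_size = np.mean(list(sizes.values()))
    keep = [g for g in pred.groups if sizes[g] >= fraction * mean_size]
    return InstancePartition(
        groups={g: pred.groups[g] for g in keep},
        class_of={g: pred.class_of[g] for g in keep},
    )
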