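"""Per-exam evaluation metrics, patient-grouped folds, and CV aggregation.

Metrics are computed per examination (the full 3D volume, CSF = positive
class) from voxel-wise confusion counts. Cross-validation folds are built at
the patient level so no patient's exams can appear in both training and
validation; patients with multiple exams are additionally spread over
distinct folds from each other so every fold keeps a comparable exam count.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .volume_io import MaskVolume

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "FoldPlan",
    "METRIC_NAMES",
    "confusion_counts",
    "compute_metrics",
    "evaluate_exam",
    "make_grouped_folds",
    "aggregate_cv",
    "run_crossval",
    "summarize_crossval",
]

METRIC_NAMES = ("dice", "iou", "accuracy", "precision", "recall", "volumetric_similarity")


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-wise confusion counts for one exam (CSF = positive)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """The six per-exam evaluation metrics, each in [0, 1]."""

    dice: float
    iou: float
    accuracy: float
    precision: float
    recall: float
    volumetric_similarity: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(pred: MaskVolume, truth: MaskVolume) -> ConfusionCounts:
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    p = pred.labels.astype(bool)
    t = truth.labels.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, both_empty: bool) -> float:
    # zero-denominator convention: 1.0 when neither mask contains CSF, else 0.0
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Dice, IoU, accuracy, precision, recall and volumetric similarity.

    ``volumetric_similarity = 1 − |FP − FN| / (2·TP + FP + FN)`` — agreement
    of segmented volumes irrespective of overlap location.
    """
    both_empty = (c.tp + c.fp == 0) and (c.tp + c.fn == 0)
    dice = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, both_empty)
    iou = _ratio(c.tp, c.tp + c.fp + c.fn, both_empty)
    accuracy = _ratio(c.tp + c.tn, c.total, both_empty)
    precision = _ratio(c.tp, c.tp + c.fp, both_empty)
    recall = _ratio(c.tp, c.tp + c.fn, both_empty)
    if 2 * c.tp + c.fp + c.fn == 0:
        vs = 1.0 if both_empty else 0.0
    else:
        vs = 1.0 - abs(c.fp - c.fn) / (2 * c.tp + c.fp + c.fn)
    return MetricSet(
        dice=dice,
        iou=iou,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        volumetric_similarity=vs,
    )


def evaluate_exam(pred: MaskVolume, truth: MaskVolume) -> MetricSet:
    return compute_metrics(confusion_counts(pred, truth))


# ---------------------------------------------------------------------------
# patient-grouped folds


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every patient to exactly one of ``k`` folds."""

    assignments: dict[str, int]
    k: int

    def fold_of(self, patient_id: str) -> int:
        return self.assignments[patient_id]

    def exams_per_fold(self, exams: list[tuple[str, str]]) -> list[int]:
        counts = [0] * self.k
        for patient_id, _ in exams:
            counts[self.assignments[patient_id]] += 1
        return counts


def make_grouped_folds(
    exams: list[tuple[str, str]], k: int = 10, seed: int = 0
) -> FoldPlan:
    """Build a patient-grouped k-fold plan.

    All exams of one patient share a single fold. Patients with more than
    one exam are assigned first, in decreasing exam count, to pairwise
    distinct folds; the remaining single-exam patients are shuffled (seeded)
    and each is placed on the fold with the fewest exams so far, keeping
    per-fold exam counts balanced. Deterministic given the seed.
    """
    exam_counts: dict[str, int] = {}
    for patient_id, _ in exams:
        exam_counts[patient_id] = exam_counts.get(patient_id, 0) + 1
    multi = sorted(
        (p for p, n in exam_counts.items() if n > 1),
        key=lambda p: (-exam_counts[p], p),
    )
    if len(multi) > k:
        raise ValueError(
            f"{len(multi)} patients with multiple exams exceed k={k} folds; "
            "they must occupy pairwise distinct folds"
        )
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    counts = [0] * k
    for fold, patient in enumerate(multi):
        assignments[patient] = fold
        counts[fold] += exam_counts[patient]
    singles = sorted(p for p, n in exam_counts.items() if n == 1)
    rng.shuffle(singles)
    for patient in singles:
        fold = int(np.argmin(counts))
        assignments[patient] = fold
        counts[fold] += 1
    return FoldPlan(assignments=assignments, k=k)


# ---------------------------------------------------------------------------
# aggregation (per-exam → per-fold means → overall mean/std)


def aggregate_cv(
    per_fold: dict[int, list[MetricSet]],
) -> tuple[dict[int, MetricSet], MetricSet, MetricSet]:
    """Fold means, then overall mean and std across fold means.

    Each exam is weighted equally within its fold; the spread across folds
    is the sample standard deviation (0.0 for a single fold).
    """
    if not per_fold:
        raise ValueError("no folds to aggregate")
    fold_means: dict[int, MetricSet] = {}
    for fold, metric_sets in per_fold.items():
        if not metric_sets:
            raise ValueError(f"fold {fold} has no exams")
        fold_means[fold] = MetricSet(
            **{
                name: float(np.mean([getattr(m, name) for m in metric_sets]))
                for name in METRIC_NAMES
            }
        )
    stacked = {
        name: np.array([getattr(m, name) for m in fold_means.values()])
        for name in METRIC_NAMES
    }
    overall_mean = MetricSet(**{n: float(v.mean()) for n, v in stacked.items()})
    overall_std = MetricSet(
        **{n: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for n, v in stacked.items()}
    )
    return fold_means, overall_mean, overall_std


# ---------------------------------------------------------------------------
# cross-validation orchestration


def run_crossval(
    cohort,
    k: int,
    model_config,
    train_config,
    seed: int = 0,
    postprocess: bool = True,
) -> pd.DataFrame:
    """Train/evaluate one model per fold on a cohort of labelled exams.

    ``cohort`` is a list of ``(patient_id, exam_id, CTVolume, MaskVolume)``.
    Returns a tidy DataFrame with one row per exam and postprocessing
    condition; feed it to :func:`summarize_crossval` for the aggregate table.
    """
    from .model import build_model, predict_exam
    from .postprocess import postprocess_exam
    from .training import train

    plan = make_grouped_folds([(p, e) for p, e, _, _ in cohort], k=k, seed=seed)
    rows = []
    for fold in range(k):
        train_exams = [
            (ct, mask) for p, _, ct, mask in cohort if plan.fold_of(p) != fold
        ]
        val = [(p, e, ct, mask) for p, e, ct, mask in cohort if plan.fold_of(p) == fold]
        if not val:
            continue
        model = build_model(model_config, seed=seed + fold)
        model, _ = train(model, train_exams, train_config)
        for patient_id, exam_id, ct, truth in val:
            _, pred = predict_exam(model, ct, window=train_config.window)
            variants = {"raw": pred}
            if postprocess:
                variants["postprocessed"] = postprocess_exam(pred)
            for condition, mask in variants.items():
                row = {
                    "fold": fold,
                    "patient_id": patient_id,
                    "exam_id": exam_id,
                    "condition": condition,
                }
                row.update(evaluate_exam(mask, truth).as_dict())
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_crossval(per_exam: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-exam table: fold means, then mean/std across folds."""
    out = []
    for condition, group in per_exam.groupby("condition"):
        per_fold = {
            fold: [
                MetricSet(**{n: float(row[n]) for n in METRIC_NAMES})
                for _, row in g.iterrows()
            ]
            for fold, g in group.groupby("fold")
        }
        _, mean, std = aggregate_cv(per_fold)
        for name in METRIC_NAMES:
            out.append(
                {
                    "metric": name,
                    "condition": condition,
                    "mean": getattr(mean, name),
                    "std": getattr(std, name),
                }
            )
    return pd.DataFrame(out)
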