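"""Confusion counts, the six metrics, grouped folds, CV aggregation."""

import numpy as np
import pytest

from csfseg.metrics_eval import (
    METRIC_NAMES,
    ConfusionCounts,
    FoldPlan,
    MetricSet,
    aggregate_cv,
    compute_metrics,
    confusion_counts,
    make_grouped_folds,
)
from csfseg.volume_io import MaskVolume


def confusion_oracle(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Triple-loop reference implementation."""
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            for k in range(pred.shape[2]):
                p, t = pred[i, j, k], truth[i, j, k]
                if p and t:
                    tp += 1
                elif p and not t:
                    fp += 1
                elif not p and t:
                    fn += 1
                else:
                    tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def check_fold_plan(plan: FoldPlan, exams: list[tuple[str, str]], tolerance: int = 2):
    """Brute-force validity checker for a fold plan."""
    patients = {p for p, _ in exams}
    assert set(plan.assignments) == patients
    assert all(0 <= f < plan.k for f in plan.assignments.values())
    # grouping: trivially held since assignment is per patient; verify the
    # multi-exam patients sit on pairwise distinct folds
    counts: dict[str, int] = {}
    for p, _ in exams:
        counts[p] = counts.get(p, 0) + 1
    multi_folds = [plan.assignments[p] for p, n in counts.items() if n > 1]
    assert len(multi_folds) == len(set(multi_folds))
    per_fold = plan.exams_per_fold(exams)
    assert sum(per_fold) == len(exams)
    assert max(per_fold) - min(per_fold) <= tolerance


class TestConfusionCounts:
    def test_perfect_prediction(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels.ravel()[:7] = 1
        m = MaskVolume(labels, spacing=(1, 1, 1))
        c = confusion_counts(m, m)
        assert (c.tp, c.fp, c.fn, c.tn) == (7, 0, 0, 57)

    def test_complement_prediction(self):
        labels = (np.random.default_rng(0).random((4, 4, 4)) < 0.5).astype(np.uint8)
        a = MaskVolume(labels, spacing=(1, 1, 1))
        b = MaskVolume(1 - labels, spacing=(1, 1, 1))
        c = confusion_counts(a, b)
        assert c.tp == 0 and c.tn == 0
        assert c.total == 64

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((4, 4, 4)) < 0.4).astype(np.uint8)
        truth = (rng.random((4, 4, 4)) < 0.4).astype(np.uint8)
        got = confusion_counts(
            MaskVolume(pred, spacing=(1, 1, 1)), MaskVolume(truth, spacing=(1, 1, 1))
        )
        assert got == confusion_oracle(pred, truth)

    def test_shape_mismatch(self):
        a = MaskVolume(np.zeros((2, 2, 2), dtype=np.uint8), spacing=(1, 1, 1))
        b = MaskVolume(np.zeros((2, 2, 3), dtype=np.uint8), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            confusion_counts(a, b)


class TestComputeMetrics:
    def test_hand_computed_case(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=59))
        assert m.dice == pytest.approx(0.75)
        assert m.iou == pytest.approx(0.6)
        assert m.accuracy == pytest.approx(62 / 64)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.volumetric_similarity == pytest.approx(1.0)

    def test_identical_nonempty_masks_all_ones(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=54))
        assert all(getattr(m, n) == 1.0 for n in METRIC_NAMES)

    def test_both_empty_convention(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=64))
        assert all(getattr(m, n) == 1.0 for n in METRIC_NAMES)

    def test_empty_prediction_nonempty_truth(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=59))
        assert m.dice == 0.0 and m.precision == 0.0 and m.recall == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_dice_iou_identity_and_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        pred = (rng.random((4, 4, 4)) < 0.4).astype(np.uint8)
        truth = (rng.random((4, 4, 4)) < 0.4).astype(np.uint8)
        pv = MaskVolume(pred, spacing=(1, 1, 1))
        tv = MaskVolume(truth, spacing=(1, 1, 1))
        m = compute_metrics(confusion_counts(pv, tv))
        assert m.dice == pytest.approx(2 * m.iou / (1 + m.iou), abs=1e-12)
        assert m.dice >= m.iou
        # swapping pred and truth swaps precision/recall, keeps the rest
        s = compute_metrics(confusion_counts(tv, pv))
        assert s.dice == pytest.approx(m.dice, abs=1e-12)
        assert s.iou == pytest.approx(m.iou, abs=1e-12)
        assert s.accuracy == pytest.approx(m.accuracy, abs=1e-12)
        assert s.volumetric_similarity == pytest.approx(m.volumetric_similarity, abs=1e-12)
        assert s.precision == pytest.approx(m.recall, abs=1e-12)
        assert s.recall == pytest.approx(m.precision, abs=1e-12)


class TestGroupedFolds:
    @staticmethod
    def cohort_63_80():
        # 63 patients / 80 exams: 7 patients x3 exams, 3 x2, 53 x1
        exams = []
        for p in range(7):
            exams += [(f"P{p:02d}", f"P{p:02d}-E{j}") for j in range(3)]
        for p in range(7, 10):
            exams += [(f"P{p:02d}", f"P{p:02d}-E{j}") for j in range(2)]
        for p in range(10, 63):
            exams.append((f"P{p:02d}", f"P{p:02d}-E0"))
        return exams

    def test_patient_grouping_and_balance_at_study_scale(self):
        exams = self.cohort_63_80()
        assert len(exams) == 80
        plan = make_grouped_folds(exams, k=10, seed=0)
        check_fold_plan(plan, exams)

    def test_all_exams_of_one_patient_share_a_fold(self):
        exams = [("A", "A-0"), ("A", "A-1"), ("A", "A-2"), ("B", "B-0"), ("C", "C-0")]
        plan = make_grouped_folds(exams, k=3, seed=0)
        folds = {plan.fold_of(p) for p, _ in exams if p == "A"}
        assert len(folds) == 1

    def test_deterministic_given_seed(self):
        exams = self.cohort_63_80()
        a = make_grouped_folds(exams, k=10, seed=5)
        b = make_grouped_folds(exams, k=10, seed=5)
        assert a == b
        c = make_grouped_folds(exams, k=10, seed=6)
        assert a != c  # different shuffle of the single-exam patients

    def test_too_many_multi_exam_patients(self):
        exams = [(f"P{i}", f"P{i}-E{j}") for i in range(4) for j in range(2)]
        with pytest.raises(ValueError, match="distinct folds"):
            make_grouped_folds(exams, k=3, seed=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_cohorts_exhaustively_validated(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        k = int(rng.integers(2, min(n, 6)))
        n_multi = int(rng.integers(0, k))
        exams = []
        for p in range(n):
            reps = 2 if p < n_multi else 1
            exams += [(f"P{p}", f"P{p}-E{j}") for j in range(reps)]
        plan = make_grouped_folds(exams, k=k, seed=seed)
        check_fold_plan(plan, exams)


class TestAggregateCV:
    @staticmethod
    def _ms(value: float) -> MetricSet:
        return MetricSet(**{n: value for n in METRIC_NAMES})

    def test_single_fold_single_exam(self):
        fold_means, mean, std = aggregate_cv({0: [self._ms(0.8)]})
        assert fold_means[0].dice == pytest.approx(0.8)
        assert mean.dice == pytest.approx(0.8)
        assert std.dice == 0.0

    def test_two_folds_mean(self):
        _, mean, std = aggregate_cv({0: [self._ms(0.8)], 1: [self._ms(1.0)]})
        assert mean.dice == pytest.approx(0.9)
        assert std.dice == pytest.approx(np.std([0.8, 1.0], ddof=1))

    def test_ten_fold_spreadsheet_oracle(self):
        rng = np.random.default_rng(0)
        per_fold = {}
        expected_fold_means = []
        for fold in range(10):
            values = rng.uniform(0.7, 1.0, size=int(rng.integers(2, 5)))
            per_fold[fold] = [self._ms(float(v)) for v in values]
            expected_fold_means.append(sum(values) / len(values))
        fold_means, mean, std = aggregate_cv(per_fold)
        for fold, expect in enumerate(expected_fold_means):
            assert fold_means[fold].dice == pytest.approx(expect, abs=1e-12)
        n = len(expected_fold_means)
        grand = sum(expected_fold_means) / n
        var = sum((v - grand) ** 2 for v in expected_fold_means) / (n - 1)
        assert mean.dice == pytest.approx(grand, abs=1e-12)
        assert std.dice == pytest.approx(var**0.5, abs=1e-12)

    def test_empty_fold_rejected(self):
        with pytest.raises(ValueError, match="no exams"):
            aggregate_cv({0: []})
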