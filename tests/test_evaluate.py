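import json

import numpy as np
import pytest

from emgrasp import (
    RunConfig,
    confusion,
    cross_validate,
    make_folds,
    report,
    weight_binary_task,
)
from emgrasp.dataio import GRASPS
from emgrasp.evaluate import CvResult, build_segments
from emgrasp.preprocess import Segment


def _segments(n, n_trials=None):
    n_trials = n_trials or n
    return [
        Segment(
            data=np.zeros((400, 6)), grasp="power", weight="light",
            subject="t", repetition=1, start=0, trial_id=i % n_trials,
        )
        for i in range(n)
    ]


@pytest.fixture(scope="module")
def fast_cfg():
    # small fold count and light CNN budget keep the CV unit tests quick;
    # full-scale defaults are exercised by the acceptance suite
    return RunConfig(k_folds=5, epochs=20)


@pytest.fixture(scope="module")
def svm_result(small_dataset, fast_cfg):
    return cross_validate(small_dataset, "tdar-svm", "grasp6", cfg=fast_cfg, seed=3)


class TestMakeFolds:
    def test_balanced_disjoint_partition(self):
        plan = make_folds(_segments(100), k=10, seed=0)
        sizes = np.bincount(plan.assignment, minlength=10)
        assert np.all(sizes == 10)
        assert plan.assignment.shape == (100,)

    def test_uneven_sizes_differ_by_at_most_one(self):
        plan = make_folds(_segments(101), k=10, seed=0)
        sizes = np.bincount(plan.assignment, minlength=10)
        assert sorted(sizes) == [10] * 9 + [11]

    def test_folds_rotate_in_order_and_cover_everything(self):
        plan = make_folds(_segments(30), k=3, seed=1)
        seen = []
        for f, (train, test) in enumerate(plan.folds()):
            assert np.all(plan.assignment[test] == f)
            assert set(train) | set(test) == set(range(30))
            assert not set(train) & set(test)
            seen.append(test)
        assert sorted(np.concatenate(seen)) == list(range(30))

    def test_grouped_mode_never_splits_a_trial(self):
        segs = _segments(60, n_trials=12)
        plan = make_folds(segs, k=4, mode="grouped_by_trial", seed=2)
        for tid in range(12):
            folds = {plan.assignment[i] for i, s in enumerate(segs) if s.trial_id == tid}
            assert len(folds) == 1

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            make_folds(_segments(5), k=10)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array(["a", "b", "c", "a"])
        counts, norm = confusion(y, y, ["a", "b", "c"])
        np.testing.assert_array_equal(counts, np.diag([2, 1, 1]))
        np.testing.assert_array_equal(norm.diagonal()[:3], [1, 1, 1])

    def test_collapsed_predictions_fill_one_column(self):
        true = np.array(["a", "b", "c"])
        pred = np.array(["a", "a", "a"])
        counts, _ = confusion(true, pred, ["a", "b", "c"])
        assert counts[:, 0].sum() == 3 and counts[:, 1:].sum() == 0

    def test_hand_counted_example(self):
        counts, _ = confusion(np.array([1, 1, 2]), np.array([1, 2, 2]), [1, 2])
        np.testing.assert_array_equal(counts, [[1, 1], [0, 1]])
        counts2, _ = confusion(
            np.array([1, 1, 2, 2]), np.array([1, 2, 2, 2]), [1, 2]
        )
        np.testing.assert_array_equal(counts2, [[1, 1], [0, 2]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([1, 2]), np.array([1]), [1, 2])


class TestWeightBinaryTask:
    def test_selects_one_grasp_with_both_weights(self, small_dataset):
        subset = weight_binary_task(small_dataset, "spherical")
        assert len(subset) == 4  # 2 reps x 2 weights in the small fixture
        assert {t.weight for t in subset} == {"light", "heavy"}
        assert {t.grasp for t in subset} == {"spherical"}

    def test_six_calls_partition_the_dataset(self, small_dataset):
        pieces = [weight_binary_task(small_dataset, g) for g in GRASPS]
        assert sum(len(p) for p in pieces) == len(small_dataset)
        ids = [id(t) for p in pieces for t in p]
        assert len(set(ids)) == len(small_dataset)

    def test_missing_weight_rejected(self, small_dataset):
        one_weight = [t for t in small_dataset if t.weight == "light"]
        with pytest.raises(ValueError, match="both weights"):
            weight_binary_task(one_weight, "power")

    def test_unknown_grasp_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            weight_binary_task(small_dataset, "pinch")


class TestCrossValidate:
    def test_confusion_total_equals_tested_segments(self, svm_result):
        assert svm_result.confusion_counts.sum() == svm_result.n_segments

    def test_mean_accuracy_consistent_with_confusion_trace(self, svm_result):
        trace_acc = svm_result.confusion_counts.trace() / svm_result.confusion_counts.sum()
        # fold sizes differ by <= 1, so the fold mean is within a whisker
        assert svm_result.mean_accuracy == pytest.approx(trace_acc, abs=0.01)

    def test_classes_follow_canonical_order(self, svm_result):
        assert svm_result.classes == list(GRASPS)

    def test_separable_dataset_classified_well(self, svm_result):
        assert svm_result.mean_accuracy >= 0.8

    def test_weight_task_runs_binary(self, small_dataset, fast_cfg):
        res = cross_validate(
            small_dataset, "tdar-svm", "weight2", cfg=fast_cfg, seed=3, grasp="power"
        )
        assert res.classes == ["light", "heavy"]
        assert res.confusion_counts.shape == (2, 2)

    def test_weight_task_requires_grasp(self, small_dataset, fast_cfg):
        with pytest.raises(ValueError, match="grasp"):
            cross_validate(small_dataset, "tdar-svm", "weight2", cfg=fast_cfg)

    def test_train_only_scope_runs_and_scores(self, small_dataset, fast_cfg):
        res = cross_validate(
            small_dataset, "tdar-svm", "grasp6",
            cfg=fast_cfg.replace(norm_scope="train_only"), seed=3,
        )
        assert res.confusion_counts.sum() == res.n_segments
        assert res.mean_accuracy >= 0.8

    def test_grouped_fold_mode(self, small_dataset, fast_cfg):
        res = cross_validate(
            small_dataset, "tdar-svm", "grasp6", cfg=fast_cfg, seed=3,
            fold_mode="grouped_by_trial",
        )
        assert res.confusion_counts.sum() == res.n_segments

    def test_unknown_method_rejected(self, small_dataset, fast_cfg):
        with pytest.raises(ValueError):
            cross_validate(small_dataset, "lda", "grasp6", cfg=fast_cfg)


class TestReport:
    def test_report_files_and_json_roundtrip(self, svm_result, tmp_path):
        paths = report([svm_result], tmp_path)
        payload = json.loads(paths["results_json"].read_text())
        restored = CvResult.from_dict(payload["results"][0])
        assert restored.mean_accuracy == svm_result.mean_accuracy
        np.testing.assert_array_equal(
            restored.confusion_counts, svm_result.confusion_counts
        )
        assert paths["accuracy_table"].exists()
        assert paths["heatmap_0"].exists()
        table = paths["accuracy_table"].read_text().splitlines()
        assert len(table) == 2  # header + one result row

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            report([], tmp_path)
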