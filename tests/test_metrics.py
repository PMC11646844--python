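import numpy as np
import pytest

from clonedelim.metrics import (
    ConfusionCounts,
    classify_missing_as_singletons,
    confusion_counts,
    median_size_mse,
    per_sequence_metrics,
    remove_singletons,
    repertoire_metrics,
)
from clonedelim.partition import Partition

TRUTH = Partition.from_clusters({"t1": ["a", "b", "c"], "t2": ["d", "e"]})
INFERRED = Partition.from_clusters({"i1": ["a", "b"], "i2": ["c"], "i3": ["d", "e"]})


def brute_force_counts(truth: Partition, inferred: Partition, focal: str) -> ConfusionCounts:
    """Independent oracle: classify every non-focal sequence by pair enumeration."""
    tp = tn = fp = fn = 0
    for sid in truth.ids():
        if sid == focal:
            continue
        same_true = truth.assignment[sid] == truth.assignment[focal]
        same_inf = inferred.assignment[sid] == inferred.assignment[focal]
        tp += same_true and same_inf
        fn += same_true and not same_inf
        fp += (not same_true) and same_inf
        tn += (not same_true) and not same_inf
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def random_partition(ids, n_labels, rng) -> Partition:
    return Partition({sid: f"c{rng.integers(0, n_labels)}" for sid in ids})


class TestConfusionCounts:
    def test_worked_example_focal_a(self):
        c = confusion_counts(TRUTH, INFERRED, "a")
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 0, 2)

    def test_worked_example_focal_c(self):
        c = confusion_counts(TRUTH, INFERRED, "c")
        assert (c.tp, c.fn, c.fp, c.tn) == (0, 2, 0, 2)

    def test_identity_partition_has_no_errors(self):
        for focal in TRUTH.ids():
            c = confusion_counts(TRUTH, TRUTH, focal)
            assert c.fp == 0 and c.fn == 0

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(20)]
        for _ in range(20):
            truth = random_partition(ids, 4, rng)
            inferred = random_partition(ids, 5, rng)
            for focal in ids[:5]:
                got = confusion_counts(truth, inferred, focal)
                assert got == brute_force_counts(truth, inferred, focal)

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(15)]
        truth = random_partition(ids, 3, rng)
        inferred = random_partition(ids, 4, rng)
        for focal in ids:
            c = confusion_counts(truth, inferred, focal)
            assert c.tp + c.fn + c.fp + c.tn == len(ids) - 1
            true_size = sum(
                1 for s in ids if truth.assignment[s] == truth.assignment[focal]
            )
            assert c.tp + c.fn == true_size - 1

    def test_mismatched_id_sets_rejected(self):
        other = Partition.from_clusters({"x": ["a", "b"]})
        with pytest.raises(ValueError):
            confusion_counts(TRUTH, other, "a")


class TestPerSequenceMetrics:
    def test_worked_example_values(self):
        p, r, s, f1 = per_sequence_metrics(ConfusionCounts(tp=1, tn=2, fp=0, fn=1))
        assert (p, r, s) == (1.0, 0.5, 1.0)
        assert f1 == pytest.approx(2 / 3)

    def test_perfect_counts(self):
        assert per_sequence_metrics(ConfusionCounts(tp=3, tn=4, fp=0, fn=0)) == (1, 1, 1, 1)

    def test_zero_tp_with_fn(self):
        p, r, s, f1 = per_sequence_metrics(ConfusionCounts(tp=0, tn=2, fp=0, fn=2))
        assert r == 0 and f1 == 0
        assert p == 1.0  # 0/0 convention: nothing wrongly merged

    def test_f1_is_harmonic_mean_of_precision_and_recall(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 10, size=4)
            p, r, _, f1 = per_sequence_metrics(
                ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
            )
            if p + r > 0 and tp + fp > 0 and tp + fn > 0:
                assert f1 == pytest.approx(2 * p * r / (p + r))


class TestSingletonHandling:
    def test_remove_singletons(self):
        p = Partition.from_clusters({"x": ["a", "b"], "y": ["c"]})
        out = remove_singletons(p)
        assert out.ids() == {"a", "b"}

    def test_all_singletons_removed(self):
        p = Partition.from_clusters({"x": ["a"], "y": ["b"]})
        assert len(remove_singletons(p)) == 0

    def test_no_singletons_unchanged(self):
        p = Partition.from_clusters({"x": ["a", "b"], "y": ["c", "d"]})
        assert remove_singletons(p).assignment == p.assignment

    def test_classify_missing_adds_singletons(self):
        inferred = Partition.from_clusters({"x": ["a", "b"]})
        full = classify_missing_as_singletons(inferred, {"a", "b", "c"})
        assert full.ids() == {"a", "b", "c"}
        assert sum(1 for m in full.clusters().values() if m == ["c"]) == 1

    def test_classify_missing_full_coverage_unchanged(self):
        inferred = Partition.from_clusters({"x": ["a", "b"]})
        assert classify_missing_as_singletons(inferred, {"a", "b"}).assignment == inferred.assignment

    def test_classify_missing_rejects_unknown_ids(self):
        inferred = Partition.from_clusters({"x": ["a", "z"]})
        with pytest.raises(ValueError):
            classify_missing_as_singletons(inferred, {"a", "b"})


class TestRepertoireMetrics:
    def test_identity_scores_one(self, repertoire_low_shm):
        truth = repertoire_low_shm.truth_partition()
        report = repertoire_metrics(truth, truth, drop_singletons=False)
        assert report.mean_f1 == 1.0
        assert report.mean_precision == 1.0
        assert report.mean_recall == 1.0
        assert report.mean_specificity == 1.0
        assert report.n_inferred_families == report.n_true_families

    def test_worked_example_mean_f1(self):
        report = repertoire_metrics(TRUTH, INFERRED, drop_singletons=False)
        assert report.mean_f1 == pytest.approx((2 / 3 + 2 / 3 + 0 + 1 + 1) / 5)

    def test_all_singletons_flagged_empty(self):
        truth = Partition.from_clusters({"t": ["a", "b"]})
        inferred = Partition.from_clusters({"x": ["a"], "y": ["b"]})
        report = repertoire_metrics(truth, inferred, drop_singletons=True)
        assert report.empty
        assert report.n_sequences_evaluated == 0
        assert np.isnan(report.mean_f1)

    def test_drop_singletons_restricts_both_partitions(self):
        truth = Partition.from_clusters({"t1": ["a", "b", "c"], "t2": ["d"]})
        inferred = Partition.from_clusters({"i1": ["a", "b"], "i2": ["c"], "i3": ["d"]})
        report = repertoire_metrics(truth, inferred, drop_singletons=True)
        assert report.n_sequences_evaluated == 2
        assert report.mean_f1 == 1.0  # a and b agree perfectly on the restricted set

    def test_refinement_gives_perfect_precision_and_specificity(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(30)]
        truth = random_partition(ids, 3, rng)
        # refine: split every true family in two
        inferred = Partition(
            {sid: f"{lab}_{rng.integers(0, 2)}" for sid, lab in truth.assignment.items()}
        )
        report = repertoire_metrics(truth, inferred, drop_singletons=False)
        assert report.mean_precision == 1.0
        assert report.mean_specificity == 1.0
        assert report.mean_recall < 1.0

    def test_vectorized_counts_match_per_focal_loop(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(25)]
        truth = random_partition(ids, 4, rng)
        inferred = random_partition(ids, 3, rng)
        report = repertoire_metrics(truth, inferred, drop_singletons=False)
        f1s = []
        for focal in sorted(ids):
            c = confusion_counts(truth, inferred, focal)
            f1s.append(per_sequence_metrics(c)[3])
        assert report.mean_f1 == pytest.approx(np.mean(f1s))


class TestMedianSizeMse:
    def _report(self, true_median, inferred_median):
        from clonedelim.metrics import MetricsReport

        return MetricsReport(1, 1, 1, 1, 1, 1, true_median, inferred_median, 1)

    def test_symmetric_errors(self):
        reports = [self._report(10, 8), self._report(10, 12)]
        assert median_size_mse(reports) == 4.0

    def test_perfect_is_zero(self):
        assert median_size_mse([self._report(7, 7)]) == 0.0

    def test_single_report(self):
        assert median_size_mse([self._report(5, 8)]) == 9.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            median_size_mse([])
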