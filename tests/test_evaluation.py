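"""Top-k metrics: ranking, attribution rule, oracle agreement, table checks."""

import numpy as np
import pytest

from danioscope.evaluation import (
    compute_report,
    confusion_topk,
    f1_score,
    is_correct_topk,
    macro_average,
    rank_probabilities,
)
from danioscope.phenotypes import PhenotypeClass

from _oracles import report_oracle


def ranked(probs, image_id=""):
    return rank_probabilities(np.asarray(probs, dtype=float), image_id=image_id)


def random_instances(n_instances=100, max_samples=50, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n = int(rng.integers(3, max_samples + 1))
        probs = rng.dirichlet(np.ones(5), size=n)
        truths = rng.integers(0, 5, size=n)
        yield [ranked(p) for p in probs], [PhenotypeClass(int(t)) for t in truths]


class TestRanking:
    def test_argmax_is_top1(self):
        pred = ranked([0.7, 0.1, 0.1, 0.05, 0.05])
        assert pred.ranked_classes[0] is PhenotypeClass.DEAD

    def test_probability_ties_break_by_class_index(self):
        pred = ranked([0.4, 0.4, 0.2, 0.0, 0.0])
        # brute-force enumeration of the documented sort: stable descending
        order = sorted(range(5), key=lambda i: (-[0.4, 0.4, 0.2, 0.0, 0.0][i], i))
        assert [int(c) for c in pred.ranked_classes] == order
        assert pred.ranked_classes[0] is PhenotypeClass.DEAD

    def test_exhaustive_k_always_contains_truth(self):
        pred = ranked([0.1, 0.2, 0.3, 0.15, 0.25])
        for cls in PhenotypeClass:
            assert is_correct_topk(pred, cls, k=5)

    def test_invalid_k_rejected(self):
        pred = ranked([0.2] * 5)
        with pytest.raises(ValueError):
            is_correct_topk(pred, PhenotypeClass.DEAD, k=0)
        with pytest.raises(ValueError):
            is_correct_topk(pred, PhenotypeClass.DEAD, k=6)


class TestTopKCorrectness:
    def test_second_ranked_truth_needs_k2(self):
        pred = ranked([0.5, 0.3, 0.1, 0.06, 0.04])
        truth = pred.ranked_classes[1]
        assert not is_correct_topk(pred, truth, k=1)
        assert is_correct_topk(pred, truth, k=2)

    def test_top_ranked_truth_correct_for_all_k(self):
        pred = ranked([0.5, 0.3, 0.1, 0.06, 0.04])
        assert all(is_correct_topk(pred, pred.ranked_classes[0], k) for k in range(1, 6))

    def test_correctness_monotone_in_k(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            pred = ranked(rng.dirichlet(np.ones(5)))
            truth = PhenotypeClass(int(rng.integers(0, 5)))
            flags = [is_correct_topk(pred, truth, k) for k in range(1, 6)]
            assert flags == sorted(flags)


class TestReport:
    def test_perfect_predictions_score_one_everywhere(self):
        preds, truths = [], []
        for cls in PhenotypeClass:
            p = np.full(5, 0.05)
            p[cls] = 0.8
            preds.append(ranked(p))
            truths.append(cls)
        report = compute_report(preds * 3, truths * 3, k=1)
        assert report.accuracy == 1.0
        assert report.precision == report.recall == report.f1 == (1.0,) * 5
        assert np.array_equal(report.confusion, np.eye(5, dtype=int) * 3)

    def test_hand_constructed_sample_matches_counting_oracle(self):
        rng = np.random.default_rng(11)
        probs = rng.dirichlet(np.ones(5), size=12)
        truths = [PhenotypeClass(int(t)) for t in rng.integers(0, 5, size=12)]
        preds = [ranked(p) for p in probs]
        for k in (1, 2, 3):
            report = compute_report(preds, truths, k)
            expected = report_oracle(
                [[int(c) for c in p.ranked_classes] for p in preds], [int(t) for t in truths], k
            )
            np.testing.assert_allclose(report.precision, expected["precision"])
            np.testing.assert_allclose(report.recall, expected["recall"])
            np.testing.assert_allclose(report.f1, expected["f1"])
            assert report.accuracy == pytest.approx(expected["accuracy"])

    def test_report_agrees_with_oracle_on_random_instances(self):
        for preds, truths in random_instances(100, seed=21):
            for k in (1, 3):
                report = compute_report(preds, truths, k)
                expected = report_oracle(
                    [[int(c) for c in p.ranked_classes] for p in preds],
                    [int(t) for t in truths],
                    k,
                )
                np.testing.assert_allclose(report.f1, expected["f1"])
                assert report.accuracy == pytest.approx(expected["accuracy"])
                np.testing.assert_array_equal(report.confusion, expected["confusion"])

    def test_never_predicted_never_true_class_scores_zero(self):
        # all samples are NORMAL and predicted NORMAL; the other classes get
        # 0/0 -> 0 for every metric
        p = np.array([0.02, 0.02, 0.02, 0.02, 0.92])
        preds = [ranked(p)] * 4
        truths = [PhenotypeClass.NORMAL] * 4
        report = compute_report(preds, truths, k=1)
        for cls in (PhenotypeClass.DEAD, PhenotypeClass.BLOOD_STASIS):
            assert report.precision[cls] == report.recall[cls] == report.f1[cls] == 0.0

    def test_k1_reduces_to_standard_confusion_matrix(self):
        from sklearn.metrics import confusion_matrix as sk_confusion

        for preds, truths in random_instances(10, seed=33):
            got = confusion_topk(preds, truths, k=1)
            top1 = [int(p.ranked_classes[0]) for p in preds]
            expected = sk_confusion([int(t) for t in truths], top1, labels=range(5))
            np.testing.assert_array_equal(got, expected)

    def test_confusion_conserves_samples_and_row_sums(self):
        for preds, truths in random_instances(20, seed=8):
            for k in (1, 2, 3):
                m = confusion_topk(preds, truths, k)
                assert m.sum() == len(preds)
                true_counts = np.bincount([int(t) for t in truths], minlength=5)
                np.testing.assert_array_equal(m.sum(axis=1), true_counts)

    def test_exhaustive_k_gives_diagonal_confusion(self):
        for preds, truths in random_instances(10, seed=2):
            m = confusion_topk(preds, truths, k=5)
            assert np.all(m == np.diag(np.diag(m)))

    def test_accuracy_and_recall_monotone_in_k(self):
        for preds, truths in random_instances(50, seed=13):
            reports = [compute_report(preds, truths, k) for k in (1, 2, 3, 4, 5)]
            accs = [r.accuracy for r in reports]
            assert accs == sorted(accs)
            for cls in range(5):
                recalls = [r.recall[cls] for r in reports]
                assert recalls == sorted(recalls)

    def test_macro_fields_match_per_class_columns(self):
        for preds, truths in random_instances(10, seed=5):
            r = compute_report(preds, truths, k=2)
            assert r.macro_precision == pytest.approx(macro_average(r.precision))
            assert r.macro_f1 == pytest.approx(macro_average(r.f1))

    def test_length_mismatch_rejected(self):
        preds = [ranked([0.2] * 5)]
        with pytest.raises(ValueError):
            compute_report(preds, [PhenotypeClass.DEAD, PhenotypeClass.EDEMA], k=1)


class TestPublishedTableArithmetic:
    """Worked examples taken from the study's published result tables."""

    def test_f1_from_printed_precision_recall(self):
        # Dead class, Top-1, strongest backbone: P=0.93, R=0.88 -> F1=0.90
        assert round(f1_score(0.93, 0.88), 2) == 0.90

    def test_macro_precision_of_printed_top1_column(self):
        # (0.93, 0.77, 0.00, 0.38, 0.33) -> 0.48
        assert round(macro_average([0.93, 0.77, 0.00, 0.38, 0.33]), 2) == 0.48

    def test_macro_average_basics(self):
        assert macro_average([0.7] * 5) == pytest.approx(0.7)
        assert macro_average([1, 0, 0, 0, 0]) == pytest.approx(0.20)

    def test_rounded_view_keeps_two_decimals(self):
        p = np.array([0.02, 0.02, 0.02, 0.02, 0.92])
        report = compute_report([ranked(p)] * 4, [PhenotypeClass.NORMAL] * 4, k=1)
        rounded = report.rounded()
        assert rounded["per_class"]["Normal"]["precision"] == 1.0
        assert rounded["accuracy"] == 1.0
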