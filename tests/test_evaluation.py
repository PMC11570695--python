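import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucopipe.evaluation import (
    BinaryCounts,
    binary_counts,
    class_metrics,
    compliance_report,
    confusion_matrix,
    iso15197_within,
    metrics_report,
    overall_accuracy,
)


def pairwise_oracle(true, pred, n_classes):
    """Exhaustive pair-enumeration oracle for per-class P/R/F1 and accuracy."""
    out = {}
    for k in range(n_classes):
        tp = sum(1 for t, p in zip(true, pred) if t == k and p == k)
        fp = sum(1 for t, p in zip(true, pred) if t != k and p == k)
        fn = sum(1 for t, p in zip(true, pred) if t == k and p != k)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[k] = (prec, rec, f1)
    acc = sum(1 for t, p in zip(true, pred) if t == p) / len(true)
    return out, acc


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = np.repeat(np.arange(16), 10)
        cm = confusion_matrix(labels, labels)
        assert (cm == np.diag(np.full(16, 10))).all()

    def test_empty_input_all_zero(self):
        assert confusion_matrix([], []).sum() == 0

    def test_matches_exhaustive_tally(self, rng):
        true = rng.integers(0, 16, 50)
        pred = rng.integers(0, 16, 50)
        cm = confusion_matrix(true, pred)
        for i in range(16):
            for j in range(16):
                assert cm[i, j] == sum(
                    1 for t, p in zip(true, pred) if t == i and p == j
                )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0])


class TestBinaryCounts:
    def test_two_class_hand_tally(self):
        cm = np.array([[8, 2], [1, 9]])
        c = binary_counts(cm, 0)
        assert (c.tp, c.fn, c.fp, c.tn) == (8, 2, 1, 9)

    def test_partition_identity(self, rng):
        cm = rng.integers(0, 20, (6, 6))
        for k in range(6):
            assert binary_counts(cm, k).total == cm.sum()

    def test_diagonal_matrix_has_no_errors(self):
        cm = np.diag([3, 4, 5])
        for k in range(3):
            c = binary_counts(cm, k)
            assert c.fp == c.fn == 0

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            binary_counts(np.eye(3, dtype=int), 3)


class TestClassMetrics:
    def test_harmonic_mean_hand_example(self):
        p, r, f1 = class_metrics(BinaryCounts(tp=8, fp=1, fn=2, tn=50))
        assert p == pytest.approx(8 / 9)
        assert r == pytest.approx(0.8)
        assert f1 == pytest.approx(2 * (8 / 9) * 0.8 / ((8 / 9) + 0.8))

    def test_zero_denominators_give_zero(self):
        assert class_metrics(BinaryCounts(tp=0, fp=0, fn=0, tn=10)) == (0.0, 0.0, 0.0)

    def test_reported_precision_recall_combination(self):
        # P = 1 and R = 0.92 (23 of 25 positives found) -> F1 prints as 0.96
        p, r, f1 = class_metrics(BinaryCounts(tp=23, fp=0, fn=2, tn=300))
        assert p == 1.0
        assert r == pytest.approx(0.92)
        assert round(f1, 2) == 0.96


class TestOverallAccuracy:
    def test_diagonal_is_perfect(self):
        assert overall_accuracy(np.diag([5, 5, 5])) == 1.0

    def test_hand_arithmetic(self):
        assert overall_accuracy(np.array([[8, 2], [1, 9]])) == pytest.approx(0.85)

    def test_invariant_under_class_permutation(self, rng):
        cm = rng.integers(0, 30, (8, 8))
        perm = rng.permutation(8)
        assert overall_accuracy(cm) == pytest.approx(
            overall_accuracy(cm[np.ix_(perm, perm)])
        )

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            overall_accuracy(np.zeros((4, 4), dtype=int))


class TestMetricOracleEquivalence:
    @settings(max_examples=120, deadline=None)
    @given(
        n_classes=st.integers(2, 8),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_agrees_with_pair_enumeration(self, n_classes, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(n_classes, 200))
        true = gen.integers(0, n_classes, n)
        pred = gen.integers(0, n_classes, n)
        cm = confusion_matrix(true, pred, n_classes=n_classes)
        expected, acc = pairwise_oracle(true, pred, n_classes)
        assert overall_accuracy(cm) == pytest.approx(acc, abs=1e-12)
        for k in range(n_classes):
            p, r, f1 = class_metrics(binary_counts(cm, k))
            ep, er, ef1 = expected[k]
            assert p == pytest.approx(ep, abs=1e-12)
            assert r == pytest.approx(er, abs=1e-12)
            assert f1 == pytest.approx(ef1, abs=1e-12)
            if (p, r) != (0.0, 0.0):
                assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        true = rng.integers(0, 5, 80)
        pred = rng.integers(0, 5, 80)
        cm = confusion_matrix(true, pred, n_classes=5)
        sk_p, sk_r, sk_f, _ = precision_recall_fscore_support(
            true, pred, labels=range(5), zero_division=0
        )
        for k in range(5):
            p, r, f1 = class_metrics(binary_counts(cm, k))
            assert p == pytest.approx(sk_p[k])
            assert r == pytest.approx(sk_r[k])
            assert f1 == pytest.approx(sk_f[k])


class TestISOBands:
    @pytest.mark.parametrize(
        "true,pred,expected",
        [(90, 104, True), (100, 115, True), (200, 235, False), (50, 66, False)],
    )
    def test_band_rules(self, true, pred, expected):
        assert iso15197_within(true, pred) is expected

    def test_continuity_at_threshold(self):
        # at 100 mg/dL the absolute and relative bands both equal 15
        assert iso15197_within(100, 115) and not iso15197_within(100, 115.1)
        assert iso15197_within(99.999, 114.9) and not iso15197_within(99.999, 115.1)

    def test_widening_absolute_band_never_decreases_compliance(self, rng):
        true = rng.integers(50, 100, 60).astype(float)
        pred = true + rng.normal(0, 20, 60)
        pred = np.clip(pred, 1, None)
        fracs = [
            np.mean([iso15197_within(t, p, absolute_band=b) for t, p in zip(true, pred)])
            for b in (5, 15, 30, 60, 1000)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            iso15197_within(0, 100)


class TestComplianceReport:
    def test_perfect_predictions(self):
        pairs = [(v, v) for v in (50, 80, 120, 180)]
        rep = compliance_report(pairs)
        assert rep.compliance_fraction == 1.0
        assert rep.passes_iso
        assert rep.r2_low == pytest.approx(1.0)
        assert rep.r2_high == pytest.approx(1.0)

    def test_predicting_stratum_mean_gives_zero_r2(self):
        pairs = [(50, 70.0), (70, 70.0), (90, 70.0)]
        rep = compliance_report(pairs)
        assert rep.r2_low == pytest.approx(0.0)

    def test_hand_evaluated_sums_of_squares(self):
        pairs = [(50, 50), (60, 70), (70, 70), (80, 80), (90, 80)]
        rep = compliance_report(pairs)
        assert rep.compliance_fraction == 1.0
        assert rep.r2_low == pytest.approx(1 - 200 / 1000)
        assert rep.r2_high is None  # no pairs at or above 100

    def test_single_true_value_stratum_reports_absent(self):
        rep = compliance_report([(120, 130), (120, 110)])
        assert rep.r2_high is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compliance_report([])


def test_metrics_report_macro_row(rng):
    true = rng.integers(0, 4, 100)
    pred = rng.integers(0, 4, 100)
    cm = confusion_matrix(true, pred, n_classes=4)
    report = metrics_report(cm, class_values=[50, 60, 70, 80])
    per_class = report.drop(index="macro")
    for col in ("precision", "recall", "f1"):
        assert report.loc["macro", col] == pytest.approx(per_class[col].mean())
    assert report["accuracy"].iloc[0] == pytest.approx(overall_accuracy(cm))
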