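import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from msbrainseg.evaluate import (
    ClassificationResult,
    build_confusion,
    build_report,
    classify_slice,
    macro_average,
    metric_histogram,
    render_overlay,
    slice_metrics,
    threshold_precision_curve,
    truncate3,
)
from msbrainseg.exceptions import ValidationError
from msbrainseg.phantom import SliceRecord, trace_boundary

label_maps = arrays(np.int64, (16, 16), elements=st.integers(0, 3))


def make_record(mask: np.ndarray, label: int = 1) -> SliceRecord:
    return SliceRecord(
        pid="T", label=label, image=mask.astype(float), mask=mask.astype(np.uint8),
        border=trace_boundary(mask),
    )


class TestClassifySlice:
    def test_all_healthy_is_non_classified(self):
        res = classify_slice(np.zeros((8, 8), dtype=int), tau_c=0.3)
        assert res.lp == -1
        assert res.ratios.sum() == 0

    def test_threshold_gates_the_call(self):
        labels = np.zeros((4, 4), dtype=int)
        labels.flat[:6] = 1
        labels.flat[6:8] = 2
        res = classify_slice(labels, tau_c=0.5)
        np.testing.assert_allclose(res.ratios, [0.75, 0.25, 0.0])
        assert res.lp == 1
        assert classify_slice(labels, tau_c=0.8).lp == -1

    def test_uniform_ratios_below_threshold(self):
        labels = np.array([[1, 2, 3]] * 3).T.reshape(3, 3)
        res = classify_slice(labels, tau_c=0.75)
        np.testing.assert_allclose(res.ratios, [1 / 3] * 3)
        assert res.lp == -1

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            classify_slice(np.zeros((2, 2), dtype=int), tau_c=1.5)

    @settings(max_examples=60, deadline=None)
    @given(labels=label_maps)
    def test_conservation_and_zero_threshold_limit(self, labels):
        res = classify_slice(labels, tau_c=0.0)
        n_tumor = (labels > 0).sum()
        per_class = [(labels == l).sum() for l in (1, 2, 3)]
        assert sum(per_class) == n_tumor
        if n_tumor:
            assert res.ratios.sum() == pytest.approx(1.0)
            assert res.lp == int(np.argmax(res.ratios)) + 1
        else:
            assert res.lp == -1


class TestSliceMetrics:
    def test_perfect_prediction(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[3:6, 3:6] = 1
        rec = make_record(mask, label=2)
        m = slice_metrics(mask * 2, rec)
        assert (m.dice, m.sensitivity, m.pttas) == (1.0, 1.0, 1.0)

    def test_printed_toy_counts(self):
        """tp=4, fp=2, fn=1 gives Dice 8/11, Sensitivity 4/5, pttas 1."""
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[0, :5] = 1  # T1: 5 pixels
        labels = np.zeros((5, 5), dtype=int)
        labels[0, :4] = 1  # 4 true positives, 1 false negative
        labels[1, :2] = 1  # 2 false positives
        m = slice_metrics(labels, make_record(mask, label=1))
        assert (m.tp, m.fp, m.fn) == (4, 2, 1)
        assert m.dice == pytest.approx(8 / 11)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.pttas == pytest.approx(1.0)

    def test_wrong_class_everywhere(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[2:4, 2:4] = 1
        labels = (mask * 3).astype(int)  # predicted pituitary, truth meningioma
        m = slice_metrics(labels, make_record(mask, label=1))
        assert m.dice == 0.0 and m.pttas == 0.0

    def test_shape_mismatch(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1, 1] = 1
        with pytest.raises(ValidationError):
            slice_metrics(np.zeros((5, 5), dtype=int), make_record(mask))

    @settings(max_examples=60, deadline=None)
    @given(labels=label_maps, data=st.data())
    def test_pttas_equals_unthresholded_true_class_ratio(self, labels, data):
        true_label = data.draw(st.integers(1, 3))
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        m = slice_metrics(labels, make_record(mask, label=true_label))
        res = classify_slice(labels, tau_c=0.0)
        if (labels > 0).sum():
            assert m.pttas == pytest.approx(res.ratios[true_label - 1])
        assert 0.0 <= m.dice <= 1.0
        assert 0.0 <= m.sensitivity <= 1.0
        assert 0.0 <= m.pttas <= 1.0


class TestMacroAverage:
    @pytest.mark.parametrize(
        "values,expected",
        [((0.894, 0.779, 0.813), 0.828), ((0.961, 0.907, 0.954), 0.940), ((0.938, 0.986, 0.979), 0.967)],
    )
    def test_truncated_printed_averages(self, values, expected):
        assert macro_average(values, truncate=True) == pytest.approx(expected)

    def test_identity_and_plain_mean(self):
        assert macro_average([0.5, 0.5, 0.5]) == 0.5
        assert macro_average([1.0, 0.0]) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            macro_average([])

    def test_truncate3_truncates_not_rounds(self):
        assert truncate3(0.97389) == 0.973
        assert truncate3(0.9999) == 0.999


class TestBuildConfusion:
    @staticmethod
    def calls(pairs):
        return [
            (t, ClassificationResult(ratios=np.zeros(3), tau_c=0.0, lp=lp)) for t, lp in pairs
        ]

    def test_all_correct(self):
        rep = build_confusion(self.calls([(1, 1), (2, 2), (3, 3)]))
        assert rep.accuracy == 1.0
        np.testing.assert_array_equal(rep.confusion, np.eye(3, dtype=int))

    def test_one_glioma_misread_as_meningioma(self):
        rep = build_confusion(self.calls([(1, 1), (1, 1), (2, 1), (2, 2)]))
        assert rep.accuracy == pytest.approx(0.75)

    def test_non_classified_counts_in_denominator(self):
        rep = build_confusion(self.calls([(1, 1), (1, -1), (2, 2), (3, 3)]))
        assert rep.accuracy == pytest.approx(0.75)
        np.testing.assert_array_equal(rep.non_classified, [1, 0, 0])

    def test_bad_labels_rejected(self):
        with pytest.raises(ValidationError):
            build_confusion(self.calls([(4, 1)]))
        with pytest.raises(ValidationError):
            build_confusion(self.calls([(1, 5)]))


class TestThresholdPrecisionCurve:
    def test_certain_correct_ratios(self):
        sets = [(l, np.eye(3)[l - 1]) for l in (1, 2, 3)]
        curve = threshold_precision_curve(sets, taus=[0.0, 0.5, 0.9])
        assert all(prec == 1.0 and n == 3 for _, prec, n in curve)

    def test_matches_brute_force_reclassification(self):
        rng = np.random.default_rng(5)
        raw = rng.dirichlet(np.ones(3), size=5)
        sets = [(int(rng.integers(1, 4)), r) for r in raw]
        taus = [0.0, 0.3, 0.5, 0.7, 0.9]
        curve = threshold_precision_curve(sets, taus)
        for (tau, prec, n), tau_in in zip(curve, taus):
            correct = n_cls = 0
            for true_label, ratios in sets:
                surviving = [r if r > tau_in else 0 for r in ratios]
                if max(surviving) > 0:
                    n_cls += 1
                    if int(np.argmax(surviving)) + 1 == true_label:
                        correct += 1
            assert (prec, n) == (correct / 5, n_cls)

    def test_classified_count_non_increasing(self):
        rng = np.random.default_rng(8)
        sets = [(1, r) for r in rng.dirichlet(np.ones(3), size=20)]
        curve = threshold_precision_curve(sets, taus=np.linspace(0, 1, 11))
        counts = [n for _, _, n in curve]
        assert counts == sorted(counts, reverse=True)


class TestRenderOverlay:
    @staticmethod
    def record():
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        return make_record(mask, label=1)

    def test_perfect_prediction_is_all_yellow(self):
        rec = self.record()
        rgb = render_overlay(rec.mask.astype(int), rec)
        yellow = (rgb == (255, 255, 0)).all(axis=-1)
        red = (rgb == (255, 0, 0)).all(axis=-1)
        green = (rgb == (0, 255, 0)).all(axis=-1)
        assert yellow.sum() == rec.mask.sum() and not red.any() and not green.any()

    def test_empty_prediction_shows_ground_truth_green(self):
        rec = self.record()
        rgb = render_overlay(np.zeros((10, 10), dtype=int), rec)
        green = (rgb == (0, 255, 0)).all(axis=-1)
        assert green.sum() == rec.mask.sum()
        assert not (rgb == (255, 0, 0)).all(axis=-1).any()

    def test_disjoint_prediction(self):
        rec = self.record()
        labels = np.zeros((10, 10), dtype=int)
        labels[7:9, 7:9] = 1
        rgb = render_overlay(labels, rec)
        assert (rgb == (255, 0, 0)).all(axis=-1).sum() == 4
        assert (rgb == (0, 255, 0)).all(axis=-1).sum() == rec.mask.sum()
        assert not (rgb == (255, 255, 0)).all(axis=-1).any()

    def test_class_tags_mode(self):
        rec = self.record()
        labels = np.zeros((10, 10), dtype=int)
        labels[0, 0], labels[0, 1], labels[0, 2] = 1, 2, 3
        rgb = render_overlay(labels, rec, mode="class-tags")
        assert tuple(rgb[0, 0]) == (255, 0, 0)
        assert tuple(rgb[0, 1]) == (0, 255, 0)
        assert tuple(rgb[0, 2]) == (0, 0, 255)

    def test_unknown_mode(self):
        with pytest.raises(ValidationError):
            render_overlay(np.zeros((10, 10), dtype=int), self.record(), mode="nope")


def test_metric_histogram_counts():
    df = metric_histogram([0.05, 0.05, 0.95], bins=10)
    assert df["count"].sum() == 3
    assert df.iloc[0]["count"] == 2


def test_build_report_assembles_confusion():
    mask = np.zeros((6, 6), dtype=np.uint8)
    mask[1:3, 1:3] = 1
    rec = make_record(mask, label=2)
    lm = (mask * 2).astype(int)
    entries = [(0, 2, slice_metrics(lm, rec), classify_slice(lm, 0.5))]
    rep = build_report(entries)
    assert rep.confusion.accuracy == 1.0
    assert rep.per_slice[0]["predicted_label"] == 2
    assert "per_slice" in rep.to_json()
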