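import numpy as np
import pytest

from plasmacount.annotations import PointAnnotation
from plasmacount.errors import UndefinedPercentageError, ValidationError
from plasmacount.evaluation import (
    ConfusionMatrix3,
    confusion,
    evaluate_detections,
    icc_absolute,
    macro_f1,
    match,
    pixels_to_microns,
    plasma_percentage,
    report_midpoint,
)


def pts(coords, labels=None):
    labels = labels or ["neg"] * len(coords)
    return [PointAnnotation(int(x), int(y), l) for (x, y), l in zip(coords, labels)]


class TestMatch:
    def test_identical_sets_all_matched(self):
        p = pts([(10, 10), (50, 50), (90, 10)])
        res = match(p, p)
        assert len(res.pairs) == 3
        assert all(d == 0.0 for _, _, d in res.pairs)
        assert res.unmatched_truth == [] and res.unmatched_detections == []

    def test_16px_apart_unmatched(self):
        res = match(pts([(10, 10)]), pts([(26, 10)]), threshold=15)
        assert res.pairs == []
        assert res.unmatched_truth == [0] and res.unmatched_detections == [0]

    def test_15px_exactly_matched(self):
        res = match(pts([(10, 10)]), pts([(25, 10)]), threshold=15)
        assert len(res.pairs) == 1
        assert res.pairs[0][2] == pytest.approx(15.0)

    def test_empty_inputs(self):
        res = match([], pts([(1, 1)]))
        assert res.pairs == [] and res.unmatched_detections == [0]
        res = match(pts([(1, 1)]), [])
        assert res.unmatched_truth == [0]

    def test_prefers_max_matches_over_distance(self):
        # one detection between two truths: greedy-by-distance would burn it;
        # optimal assignment pairs each truth when possible
        truth = pts([(0, 0), (20, 0)])
        dets = pts([(10, 0), (21, 0)])
        res = match(truth, dets, threshold=15)
        assert len(res.pairs) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 200, (5, 2))
        d = rng.uniform(0, 200, (6, 2))
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = rng.uniform(0, 50, 2)

        class P:
            def __init__(self, x, y):
                self.x, self.y = x, y

        def mk(a):
            return [P(x, y) for x, y in a]

        r1 = match(mk(t), mk(d))
        r2 = match(mk(t @ rot.T + shift), mk(d @ rot.T + shift))
        assert {(a, b) for a, b, _ in r1.pairs} == {(a, b) for a, b, _ in r2.pairs}


class TestConfusion:
    def test_perfect_detection_diagonal(self):
        truth = pts([(10, 10), (40, 10), (10, 40)], ["neg", "pos", "pos"])
        res, cm, f1 = evaluate_detections(truth, truth)
        assert np.array_equal(cm.counts, [[1, 0, 0], [0, 2, 0], [0, 0, 0]])
        assert f1 == 1.0

    def test_missed_positive(self):
        truth = pts([(10, 10)], ["pos"])
        res = match(truth, [])
        cm = confusion(res, ["pos"], [])
        assert cm.counts[1, 2] == 1 and cm.total() == 1

    def test_hand_enumerated_bookkeeping(self):
        # 10 truth (4 pos), one pos detected as neg, one spurious pos
        coords = [(20 * i, 0) for i in range(6)] + [(20 * i, 40) for i in range(4)]
        truth = pts(coords, ["neg"] * 6 + ["pos"] * 4)
        det_coords = list(coords) + [(200, 200)]
        det_labels = ["neg"] * 6 + ["neg"] + ["pos"] * 3 + ["pos"]
        dets = pts(det_coords, det_labels)
        _, cm, f1 = evaluate_detections(truth, dets)
        assert np.array_equal(cm.counts, [[6, 0, 0], [1, 3, 0], [0, 1, 0]])
        # F1_neg = 2*6/(12+1+0) = 12/13; F1_pos = 2*3/(6+1+1) = 3/4
        assert f1 == pytest.approx((12 / 13 + 3 / 4) / 2)

    def test_total_identity(self):
        rng = np.random.default_rng(0)
        truth = pts(rng.uniform(0, 100, (7, 2)), ["pos"] * 3 + ["neg"] * 4)
        dets = pts(rng.uniform(0, 100, (5, 2)), ["pos"] * 2 + ["neg"] * 3)
        res = match(truth, dets)
        cm = confusion(res, [p.label for p in truth], [d.label for d in dets])
        assert cm.total() == len(res.pairs) + len(res.unmatched_truth) + len(
            res.unmatched_detections
        )

    def test_bg_bg_cell_must_be_zero(self):
        with pytest.raises(ValidationError):
            ConfusionMatrix3(np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1]]))


class TestMacroF1:
    def test_empty_is_one_by_convention(self):
        assert macro_f1(ConfusionMatrix3()) == 1.0

    def test_hand_value(self):
        cm = ConfusionMatrix3(np.array([[6, 0, 0], [1, 3, 0], [0, 1, 0]]))
        assert macro_f1(cm) == pytest.approx(0.8365384615384616)

    def test_label_swap_invariance(self):
        c = np.array([[5, 2, 1], [1, 7, 2], [3, 1, 0]])
        swapped = c[[1, 0, 2]][:, [1, 0, 2]]
        assert macro_f1(ConfusionMatrix3(c)) == pytest.approx(
            macro_f1(ConfusionMatrix3(swapped))
        )


class TestPlasmaPercentage:
    @pytest.mark.parametrize("n_pos,n_neg,expected", [(2, 8, 20.0), (0, 50, 0.0), (50, 0, 100.0)])
    def test_values(self, n_pos, n_neg, expected):
        assert plasma_percentage(n_pos, n_neg) == expected

    def test_zero_total_raises(self):
        with pytest.raises(UndefinedPercentageError):
            plasma_percentage(0, 0)


class TestReportMidpoint:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("5–10%", 7.5),
            ("5-10%", 7.5),
            ("not increased", 2.5),
            ("normal", 2.5),
            ("less than 5%", 2.5),
            ("Not Increased", 2.5),
            ("12%", 12.0),
            ("7.5", 7.5),
        ],
    )
    def test_tokens(self, token, expected):
        assert report_midpoint(token) == expected

    def test_unparseable(self):
        with pytest.raises(ValidationError):
            report_midpoint("plenty of cells")


class TestICC:
    def test_identical_columns_one(self):
        y = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc_absolute(y) == pytest.approx(1.0)

    def test_constant_table_defined_one(self):
        assert icc_absolute(np.full((5, 3), 4.2)) == 1.0

    def test_offset_penalized_and_monotone(self):
        base = np.arange(10.0)
        vals = []
        for c in (0.5, 1.0, 2.0):
            vals.append(icc_absolute(np.column_stack([base, base + c])))
        assert all(v < 1.0 for v in vals)
        assert vals == sorted(vals, reverse=True)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10, 3, size=(12, 3))
        a, b = 2.7, -5.0
        assert icc_absolute(a * y + b) == pytest.approx(icc_absolute(y), abs=1e-12)

    def test_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        y = rng.normal(20, 5, size=(10, 2))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 2),
                "rater": np.tile(["a", "b"], 10),
                "score": y.ravel(),
            }
        )
        res = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        icc2 = res.loc[res["Type"] == "ICC(A,1)", "ICC"].item()
        assert icc_absolute(y) == pytest.approx(icc2, abs=1e-10)

    def test_validation(self):
        with pytest.raises(ValidationError):
            icc_absolute(np.zeros((1, 2)))
        with pytest.raises(ValidationError):
            icc_absolute(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestPixelsToMicrons:
    def test_matching_threshold(self):
        assert pixels_to_microns(15) == pytest.approx(3.75)

    def test_patch_side(self):
        assert pixels_to_microns(512) == pytest.approx(128.0)

    def test_zero(self):
        assert pixels_to_microns(0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            pixels_to_microns(-1)
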