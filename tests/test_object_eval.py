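"""Object-level confusion machinery, P/R/F1 arithmetic and pixel metrics."""

import numpy as np
import pytest
from scipy import ndimage

from viaphase.evaluate import (MISSED, NucleusRecord, ViabilityConfusion,
                               dominant_label, extract_objects, f1_from_pr,
                               normalize_confusion, object_confusion,
                               pixel_metrics, prf1, round_half_up)
from viaphase.ground_truth import BACKGROUND, DEAD, LIVE, SemanticMap


def disk_map(disks, shape=(96, 96)):
    """Render (cy, cx, r, cls) disks on background."""
    labels = np.full(shape, BACKGROUND, dtype=np.uint8)
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    for cy, cx, r, cls in disks:
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = cls
    return SemanticMap(labels)


def brute_force_confusion(gt: SemanticMap, pred: SemanticMap, min_area=50):
    """Independent per-object tally used as the oracle."""
    lab, n = ndimage.label(gt.labels != BACKGROUND, structure=np.ones((3, 3), int))
    counts = np.zeros((2, 2), dtype=int)
    missed = np.zeros(2, dtype=int)
    for i in range(1, n + 1):
        sel = lab == i
        if sel.sum() < min_area:
            continue
        gt_vals = gt.labels[sel]
        gt_cls = DEAD if (gt_vals == DEAD).sum() >= (gt_vals == LIVE).sum() else LIVE
        pv = pred.labels[sel]
        n_bg = (pv == BACKGROUND).sum()
        if n_bg > sel.sum() - n_bg:
            missed[gt_cls] += 1
        else:
            vote = DEAD if (pv == DEAD).sum() >= (pv == LIVE).sum() else LIVE
            counts[gt_cls, vote] += 1
    return counts, missed


class TestExtractObjects:
    def test_empty_map(self):
        assert extract_objects(disk_map([])) == []

    def test_two_live_disks(self):
        objs = extract_objects(disk_map([(25, 25, 8, LIVE), (70, 70, 9, LIVE)]))
        assert len(objs) == 2
        assert all(o.cls == LIVE for o in objs)

    def test_majority_class_dead(self):
        sem = disk_map([(48, 48, 10, LIVE)])
        # overwrite ~60% of the disk with dead pixels
        sel = np.nonzero(sem.labels == LIVE)
        k = int(0.6 * len(sel[0]))
        sem.labels[sel[0][:k], sel[1][:k]] = DEAD
        objs = extract_objects(SemanticMap(sem.labels))
        assert len(objs) == 1
        assert objs[0].cls == DEAD

    def test_min_area_filter(self):
        objs = extract_objects(disk_map([(48, 48, 3, LIVE)]), min_area_px=50)
        assert objs == []


class TestDominantLabel:
    def test_identical_prediction_returns_own_class(self):
        gt = disk_map([(48, 48, 10, DEAD)])
        obj = extract_objects(gt)[0]
        assert dominant_label(obj, gt) == DEAD

    def test_background_prediction_is_missed(self):
        gt = disk_map([(48, 48, 10, LIVE)])
        obj = extract_objects(gt)[0]
        assert dominant_label(obj, disk_map([])) == MISSED

    def test_majority_vote_with_tie_to_dead(self):
        pixels = np.array([[0, c] for c in range(10)])
        obj = NucleusRecord(1, pixels, (0.0, 4.5), 10, LIVE)
        pred = np.full((1, 10), LIVE, dtype=np.uint8)
        pred[0, :6] = DEAD  # 6 dead / 4 live
        assert dominant_label(obj, SemanticMap(pred)) == DEAD
        pred[0] = [DEAD] * 5 + [LIVE] * 5  # exact tie
        assert dominant_label(obj, SemanticMap(pred)) == DEAD


class TestObjectConfusion:
    def test_perfect_prediction_is_diagonal(self):
        gt = disk_map([(20, 20, 8, LIVE), (20, 70, 8, LIVE), (70, 20, 8, DEAD),
                       (70, 70, 8, DEAD), (48, 48, 8, DEAD)])
        cm = object_confusion(gt, gt)
        assert np.array_equal(cm.counts, [[2, 0], [0, 3]])
        assert cm.missed.sum() == 0

    def test_all_live_predicted_dead(self):
        gt = disk_map([(20, 20, 8, LIVE), (70, 70, 8, LIVE)])
        pred = SemanticMap(np.where(gt.labels == LIVE, DEAD, gt.labels))
        cm = object_confusion(gt, pred)
        assert cm.counts[LIVE, DEAD] == 2
        assert cm.n_live == 2 and cm.n_dead == 0

    def test_matches_bruteforce_on_random_scenes(self, rng):
        """Oracle equivalence on scenes with up to 10 objects."""
        for _ in range(30):
            n = int(rng.integers(0, 11))
            disks = []
            centers = []
            for _ in range(n):
                for _try in range(50):
                    cy, cx = rng.integers(12, 116, 2)
                    if all((cy - a) ** 2 + (cx - b) ** 2 > 24**2 for a, b in centers):
                        centers.append((cy, cx))
                        disks.append((cy, cx, int(rng.integers(5, 10)),
                                      int(rng.integers(0, 2))))
                        break
            gt = disk_map(disks, (128, 128))
            # perturbed prediction: random relabel/erase of some disks
            pred_disks = []
            for cy, cx, r, cls in disks:
                u = rng.random()
                if u < 0.2:
                    continue                      # erased -> missed
                if u < 0.45:
                    cls = 1 - cls                 # flipped class
                pred_disks.append((cy, cx, r, cls))
            pred = disk_map(pred_disks, (128, 128))
            cm = object_confusion(gt, pred)
            counts, missed = brute_force_confusion(gt, pred)
            assert np.array_equal(cm.counts, counts)
            assert np.array_equal(cm.missed, missed)


class TestNormalization:
    def test_published_style_entry(self):
        cm = ViabilityConfusion([[1949, 24], [6, 240]])
        norm = normalize_confusion(cm)
        assert round_half_up(norm[LIVE, LIVE]) == 98.8  # 1949 of 1973
        assert norm[:, LIVE].sum() == pytest.approx(100.0)
        assert norm[:, DEAD].sum() == pytest.approx(100.0)

    def test_perfect_matrix(self):
        norm = normalize_confusion(ViabilityConfusion([[7, 0], [0, 3]]))
        assert np.allclose(norm, [[100, 0], [0, 100]])

    def test_zero_class_flagged_as_nan(self):
        norm = normalize_confusion(ViabilityConfusion([[5, 1], [0, 0]]))
        assert np.isnan(norm[:, DEAD]).all()
        assert norm[:, LIVE].sum() == pytest.approx(100.0)

    def test_columns_sum_to_100_randomized(self, rng):
        for _ in range(20):
            cm = ViabilityConfusion(rng.integers(1, 500, (2, 2)))
            norm = normalize_confusion(cm)
            assert np.allclose(norm.sum(axis=0), 100.0)


class TestPRF1:
    def test_recall_equals_normalized_diagonal(self, rng):
        for _ in range(20):
            cm = ViabilityConfusion(rng.integers(1, 500, (2, 2)))
            rep = prf1(cm)
            norm = normalize_confusion(cm)
            assert rep.recall["live"] == pytest.approx(norm[LIVE, LIVE])
            assert rep.recall["dead"] == pytest.approx(norm[DEAD, DEAD])

    def test_macro_f1_invariant_to_class_swap(self, rng):
        cm = ViabilityConfusion(rng.integers(1, 500, (2, 2)))
        swapped = ViabilityConfusion(cm.counts[::-1, ::-1])
        assert prf1(cm).macro_f1 == pytest.approx(prf1(swapped).macro_f1)

    def test_zero_denominator_flagged(self):
        rep = prf1(ViabilityConfusion([[5, 0], [0, 0]]))
        assert rep.precision["dead"] == 0.0
        assert rep.flags


class TestF1FromPR:
    @pytest.mark.parametrize("p,r,expected", [
        (91.2, 97.6, 94.3),   # harmonic mean of published-style P/R pairs
        (94.6, 90.1, 92.3),
        (96.8, 98.3, 97.5),
        (100.0, 100.0, 100.0),
    ])
    def test_harmonic_mean_values(self, p, r, expected):
        assert round_half_up(f1_from_pr(p, r), 1) == expected

    def test_fixed_point(self):
        for v in (10.0, 55.5, 99.9):
            assert f1_from_pr(v, v) == pytest.approx(v)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            f1_from_pr(101.0, 50.0)
        with pytest.raises(ValueError):
            f1_from_pr(0.0, 0.0)


class TestPixelMetrics:
    def test_perfect_prediction(self):
        gt = disk_map([(30, 30, 8, LIVE), (70, 70, 8, DEAD)])
        m = pixel_metrics(gt, gt)
        for cls in ("live", "dead", "background"):
            assert m[cls]["f1"] == pytest.approx(100.0)
            assert m[cls]["iou"] == pytest.approx(100.0)

    def test_swapped_classes_have_zero_recall(self):
        gt = disk_map([(30, 30, 8, LIVE), (70, 70, 8, DEAD)])
        swapped = np.where(gt.labels == LIVE, DEAD,
                           np.where(gt.labels == DEAD, LIVE, gt.labels))
        m = pixel_metrics(gt, SemanticMap(swapped.astype(np.uint8)))
        assert m["live"]["recall"] == 0.0
        assert m["dead"]["recall"] == 0.0
        assert m["background"]["recall"] == pytest.approx(100.0)

    def test_hand_counted_fixture(self):
        gt = SemanticMap(np.array([[0, 0, 2, 2],
                                   [0, 1, 2, 2],
                                   [1, 1, 2, 2],
                                   [2, 2, 2, 2]], dtype=np.uint8))
        pred = SemanticMap(np.array([[0, 0, 2, 2],
                                     [0, 0, 2, 2],
                                     [1, 1, 1, 2],
                                     [2, 2, 2, 2]], dtype=np.uint8))
        m = pixel_metrics(gt, pred)
        # live: TP=3 FP=1 FN=0 -> P=75, R=100
        assert m["live"]["precision"] == pytest.approx(75.0)
        assert m["live"]["recall"] == pytest.approx(100.0)
        # dead: TP=2 FP=1 FN=1 -> P=2/3, R=2/3, IoU=2/4
        assert m["dead"]["precision"] == pytest.approx(200 / 3)
        assert m["dead"]["recall"] == pytest.approx(200 / 3)
        assert m["dead"]["iou"] == pytest.approx(50.0)
        # background: TP=9 FP=0 FN=1
        assert m["background"]["precision"] == pytest.approx(100.0)
        assert m["background"]["recall"] == pytest.approx(90.0)


class TestRounding:
    def test_round_half_up_matches_table_convention(self):
        assert round_half_up(94.25, 1) == 94.3
        assert round_half_up(94.24, 1) == 94.2
        assert round_half_up(96.75, 1) == 96.8
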