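"""Per-fiber metrics and the FT/DT evaluation protocol."""

import numpy as np
import pytest

from myoseg import binarize_and_label, ft_dt_summary, image_metrics


def flood_fill_components(fg):
    """Independent 8-connected labeling by breadth-first flood fill."""
    fg = np.asarray(fg, dtype=bool)
    h, w = fg.shape
    labels = np.zeros((h, w), dtype=int)
    nxt = 0
    for si in range(h):
        for sj in range(w):
            if fg[si, sj] and labels[si, sj] == 0:
                nxt += 1
                queue = [(si, sj)]
                labels[si, sj] = nxt
                while queue:
                    i, j = queue.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if 0 <= ni < h and 0 <= nj < w and fg[ni, nj] and labels[ni, nj] == 0:
                                labels[ni, nj] = nxt
                                queue.append((ni, nj))
    return labels


def brute_force_metrics(pred, gt):
    """Direct per-fiber P/R from the set definitions, averaged per image."""
    n_gt = int(gt.max())
    ps, rs = [], []
    for g in range(1, n_gt + 1):
        gpix = set(zip(*np.nonzero(gt == g)))
        best_s, best_inter = None, 0
        for s in range(1, int(pred.max()) + 1):
            spix = set(zip(*np.nonzero(pred == s)))
            inter = len(gpix & spix)
            if inter > best_inter:
                best_inter, best_s = inter, s
        if best_s is None:
            ps.append(0.0)
            rs.append(0.0)
        else:
            area_s = (pred == best_s).sum()
            ps.append(best_inter / area_s)
            rs.append(best_inter / len(gpix))
    p, r = np.mean(ps), np.mean(rs)
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


class TestBinarizeAndLabel:
    def test_zero_threshold_covers_everything(self, rng):
        labels = binarize_and_label(rng.random((20, 20)), 0.0, min_area=1)
        assert (labels > 0).all()
        assert labels.max() == 1

    def test_above_one_threshold_gives_no_components(self, rng):
        assert binarize_and_label(rng.random((20, 20)), 1.0 + 1e-9, min_area=1).max() == 0

    def test_matches_flood_fill_oracle(self, rng):
        prob = rng.random((24, 24))
        got = binarize_and_label(prob, 0.5, min_area=1)
        expected = flood_fill_components(prob >= 0.5)
        # same partition up to label naming
        assert got.max() == expected.max()
        for k in range(1, expected.max() + 1):
            sel = expected == k
            assert len(np.unique(got[sel])) == 1 and got[sel][0] > 0

    def test_min_area_filters_small_components(self):
        prob = np.zeros((12, 12))
        prob[1:3, 1:3] = 1.0  # 4 px
        prob[5:11, 5:11] = 1.0  # 36 px
        labels = binarize_and_label(prob, 0.5, min_area=30)
        assert labels.max() == 1
        assert (labels[5:11, 5:11] == 1).all()


class TestImageMetrics:
    def test_exact_match_scores_one(self):
        gt = np.zeros((16, 16), dtype=int)
        gt[2:7, 2:7] = 1
        gt[9:14, 9:14] = 2
        m = image_metrics(gt.copy(), gt)
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)
        assert m.n_fibers == 2

    def test_partial_overlap_hand_computation(self):
        """One 100-px ground-truth fiber, one 80-px prediction inside it:
        P = 1.0, R = 0.8, F1 = 2*1*0.8/1.8 = 8/9."""
        gt = np.zeros((14, 14), dtype=int)
        gt[2:12, 2:12] = 1  # 100 px
        pred = np.zeros((14, 14), dtype=int)
        pred[2:12, 2:10] = 1  # 80 px, fully inside
        m = image_metrics(pred, gt)
        assert m.precision == pytest.approx(1.0)
        assert m.recall == pytest.approx(0.8)
        assert m.f1 == pytest.approx(8 / 9)

    def test_no_overlap_scores_zero(self):
        gt = np.zeros((10, 10), dtype=int)
        gt[:3, :3] = 1
        pred = np.zeros((10, 10), dtype=int)
        pred[6:, 6:] = 1
        m = image_metrics(pred, gt)
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    def test_no_ground_truth_returns_sentinel(self):
        assert image_metrics(np.ones((5, 5), dtype=int), np.zeros((5, 5), dtype=int)) is None

    def test_matches_brute_force_on_random_labelings(self, rng):
        for _ in range(5):
            gt = binarize_and_label(rng.random((24, 24)), 0.55, min_area=1)
            pred = binarize_and_label(rng.random((24, 24)), 0.55, min_area=1)
            if gt.max() == 0:
                continue
            m = image_metrics(pred, gt)
            p, r, f1 = brute_force_metrics(pred, gt)
            assert m.precision == pytest.approx(p)
            assert m.recall == pytest.approx(r)
            assert m.f1 == pytest.approx(f1)

    def test_permutation_invariance_of_prediction_labels(self, rng):
        gt = np.zeros((16, 16), dtype=int)
        gt[1:7, 1:7] = 1
        gt[9:15, 9:15] = 2
        pred = np.zeros((16, 16), dtype=int)
        pred[1:6, 1:6] = 1
        pred[9:16, 9:16] = 2
        swapped = np.where(pred == 1, 2, np.where(pred == 2, 1, 0))
        a = image_metrics(pred, gt)
        b = image_metrics(swapped, gt)
        assert a.precision == pytest.approx(b.precision)
        assert a.recall == pytest.approx(b.recall)

    def test_recall_non_decreasing_for_nested_predictions(self):
        gt = np.zeros((12, 12), dtype=int)
        gt[1:11, 1:11] = 1
        small = np.zeros_like(gt)
        small[3:7, 3:7] = 1
        larger = np.zeros_like(gt)
        larger[2:9, 2:9] = 1
        assert image_metrics(larger, gt).recall >= image_metrics(small, gt).recall


class TestFtDtSummary:
    def toy_set(self):
        """3 toy images whose best thresholds differ."""
        gt1 = np.zeros((16, 16), dtype=int); gt1[2:8, 2:8] = 1
        p1 = np.zeros((16, 16)); p1[2:8, 2:8] = 0.9
        gt2 = np.zeros((16, 16), dtype=int); gt2[4:12, 4:12] = 1
        p2 = np.zeros((16, 16)); p2[4:12, 4:12] = 0.55; p2[0:3, 10:16] = 0.7  # distractor
        gt3 = np.zeros((16, 16), dtype=int); gt3[1:7, 1:7] = 1; gt3[9:15, 9:15] = 2
        p3 = np.zeros((16, 16)); p3[1:7, 1:7] = 0.8; p3[9:15, 9:15] = 0.35
        return [p1, p2, p3], [gt1, gt2, gt3]

    def test_single_image_ft_equals_dt(self):
        probs, gts = self.toy_set()
        s = ft_dt_summary(probs[:1], gts[:1], min_area=4)
        assert s.ft["f1"][0] == pytest.approx(s.dt["f1"][0])

    def test_dt_mean_f1_at_least_ft(self):
        probs, gts = self.toy_set()
        s = ft_dt_summary(probs, gts, min_area=4)
        assert s.dt["f1"][0] >= s.ft["f1"][0] - 1e-12

    def test_matches_exhaustive_grid_recomputation(self):
        """Oracle: recompute every (image, threshold) metric directly and
        take the FT/DT optima by exhaustive search."""
        probs, gts = self.toy_set()
        grid = np.arange(0.1, 1.0, 0.1)
        s = ft_dt_summary(probs, gts, threshold_grid=grid, min_area=4)
        all_f1 = np.empty((3, len(grid)))
        per = {}
        for i, (p, g) in enumerate(zip(probs, gts)):
            for j, t in enumerate(grid):
                m = image_metrics(binarize_and_label(p, float(t), 4), g)
                all_f1[i, j] = m.f1
                per[i, j] = m
        best_j = all_f1.mean(axis=0).argmax()
        assert s.ft_threshold == pytest.approx(grid[best_j])
        assert s.ft["f1"][0] == pytest.approx(all_f1[:, best_j].mean())
        dt_f1 = np.array([all_f1[i].max() for i in range(3)])
        assert s.dt["f1"][0] == pytest.approx(dt_f1.mean())
        assert s.dt["f1"][1] == pytest.approx(dt_f1.std())

    def test_image_without_fibers_excluded_with_warning(self):
        probs, gts = self.toy_set()
        probs.append(np.zeros((16, 16)))
        gts.append(np.zeros((16, 16), dtype=int))
        with pytest.warns(UserWarning, match="without ground-truth"):
            s = ft_dt_summary(probs, gts, min_area=4)
        assert len(s.per_image_ft) == 3

    def test_empty_test_set_raises(self):
        with pytest.raises(ValueError):
            ft_dt_summary([], [])
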