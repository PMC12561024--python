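"""Metric correctness against hand computations and brute-force oracles."""

import numpy as np
import pytest

from boneseg.metrics import (cl_dice, evaluate_set, mean_surface_distance,
                             score_pair, skeletonize)


def brute_cl_dice(pred, label):
    """Pixel-by-pixel loop re-implementation of the topology scores."""
    s_p = skeletonize(pred)
    s_l = skeletonize(label)
    n_sp = n_sl = inter_p = inter_s = 0
    h, w = pred.shape
    for r in range(h):
        for c in range(w):
            if s_p[r, c]:
                n_sp += 1
                if label[r, c]:
                    inter_p += 1
            if s_l[r, c]:
                n_sl += 1
                if pred[r, c]:
                    inter_s += 1
    if n_sp == 0 and n_sl == 0:
        return 1.0
    if n_sp == 0 or n_sl == 0:
        return 0.0
    tp = inter_p / n_sp
    ts = inter_s / n_sl
    return 0.0 if tp + ts == 0 else 2 * tp * ts / (tp + ts)


def brute_msd(pred, label, spacing):
    """Exhaustive pairwise-distance re-implementation of the directed MSD."""
    sr, sc = spacing
    # scale points to mm first so tied distances are bit-identical to the
    # pairwise-matrix computation and resolve to the same first minimum
    pts_p = [(r * sr, c * sc, r) for r, c in zip(*np.nonzero(skeletonize(pred)))]
    pts_l = [(r * sr, c * sc, r) for r, c in zip(*np.nonzero(skeletonize(label)))]
    if not pts_p or not pts_l:
        return None, None
    dists, offs = [], []
    for rl, cl, row_l in pts_l:
        best, best_row = None, None
        for rp, cp, row_p in pts_p:
            d = np.sqrt((rl - rp) ** 2 + (cl - cp) ** 2)
            if best is None or d < best:
                best, best_row = d, row_p
        dists.append(best)
        offs.append((row_l - best_row) * sr)
    return float(np.mean(dists)), float(np.mean(offs))


def random_mask(rng, shape=(12, 12), density=0.25):
    return (rng.random(shape) < density).astype(np.uint8)


class TestSkeletonize:
    def test_thin_line_is_fixed_point(self):
        m = np.zeros((20, 30), np.uint8)
        m[10, 5:25] = 1
        assert np.array_equal(skeletonize(m), m)

    def test_thick_bar_thins_to_line(self):
        m = np.zeros((20, 30), np.uint8)
        m[9:12, 5:25] = 1
        s = skeletonize(m)
        assert s.sum(axis=0).max() == 1
        assert 18 <= s.sum() <= 22

    def test_empty_in_empty_out(self):
        m = np.zeros((10, 10), np.uint8)
        assert skeletonize(m).sum() == 0

    def test_skeleton_inside_dilated_mask(self):
        from scipy.ndimage import binary_dilation
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = random_mask(rng, (16, 16), 0.4)
            s = skeletonize(m)
            assert not (s.astype(bool) & ~binary_dilation(m.astype(bool))).any()

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            skeletonize(np.full((4, 4), 2))


class TestClDice:
    def test_perfect_overlap_scores_one(self):
        m = np.zeros((20, 20), np.uint8)
        m[10, 2:18] = 1
        assert cl_dice(m, m).cl_dice == 1.0

    def test_two_segment_fixture_harmonic_mean(self):
        """Prediction skeleton fully inside label, label half covered:
        t_prec = 1, t_sens = 0.5 -> clDice = 2/3."""
        label = np.zeros((10, 20), np.uint8)
        label[5, 0:16] = 1          # 16 label pixels
        pred = np.zeros((10, 20), np.uint8)
        pred[5, 0:8] = 1            # covers exactly half of the label
        s = cl_dice(pred, label)
        assert s.t_prec == 1.0
        assert s.t_sens == 0.5
        assert s.cl_dice == pytest.approx(2 / 3)

    def test_empty_pred_nonempty_label_is_zero(self):
        label = np.zeros((8, 8), np.uint8)
        label[4, 1:7] = 1
        assert cl_dice(np.zeros_like(label), label).cl_dice == 0.0

    def test_both_empty_is_one(self):
        z = np.zeros((8, 8), np.uint8)
        assert cl_dice(z, z).cl_dice == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = random_mask(rng), random_mask(rng)
            assert cl_dice(a, b).cl_dice == pytest.approx(
                cl_dice(b, a).cl_dice, abs=1e-12)

    def test_oracle_equivalence_100_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = random_mask(rng), random_mask(rng)
            assert cl_dice(a, b).cl_dice == pytest.approx(
                brute_cl_dice(a, b), abs=1e-9)

    def test_padding_invariance(self):
        rng = np.random.default_rng(2)
        a, b = random_mask(rng), random_mask(rng)
        ap = np.pad(a, 5)
        bp = np.pad(b, 5)
        assert cl_dice(ap, bp).cl_dice == pytest.approx(
            cl_dice(a, b).cl_dice, abs=1e-12)


class TestMeanSurfaceDistance:
    def test_identical_masks_zero(self):
        m = np.zeros((20, 20), np.uint8)
        m[10, 2:18] = 1
        msd, off = mean_surface_distance(m, m, 0.2)
        assert msd == 0.0 and off == 0.0

    def test_two_label_points_one_pred_point(self):
        label = np.zeros((4, 4), np.uint8)
        label[0, 0] = label[0, 1] = 1
        pred = np.zeros((4, 4), np.uint8)
        pred[0, 0] = 1
        msd, off = mean_surface_distance(pred, label, 1.0)
        assert msd == pytest.approx(0.5)   # (0 + 1) / 2
        assert off == 0.0

    def test_rigid_shift_toward_probe(self):
        label = np.zeros((30, 30), np.uint8)
        label[20, 5:25] = 1
        pred = np.zeros((30, 30), np.uint8)
        pred[17, 5:25] = 1                  # 3 rows shallower
        msd, off = mean_surface_distance(pred, label, 0.2)
        assert msd == pytest.approx(0.6)
        assert off == pytest.approx(+0.6)   # toward the probe is positive

    def test_rigid_shift_linearity(self):
        label = np.zeros((40, 30), np.uint8)
        label[25, 5:25] = 1
        for k in (1, 2, 5):
            pred = np.zeros_like(label)
            pred[25 - k, 5:25] = 1
            _, off = mean_surface_distance(pred, label, (0.3, 0.3))
            assert off == pytest.approx(k * 0.3)

    def test_empty_skeleton_undefined(self):
        m = np.zeros((8, 8), np.uint8)
        m2 = m.copy()
        m2[3, 2:6] = 1
        assert mean_surface_distance(m, m2, 0.2) == (None, None)
        assert mean_surface_distance(m2, m, 0.2) == (None, None)

    def test_oracle_equivalence_100_random_masks(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            a = random_mask(rng, (10, 10), 0.3)
            b = random_mask(rng, (10, 10), 0.3)
            spacing = (float(rng.uniform(0.1, 0.5)), float(rng.uniform(0.1, 0.5)))
            got = mean_surface_distance(a, b, spacing)
            ref = brute_msd(a, b, spacing)
            if ref[0] is None:
                assert got == (None, None)
                continue
            assert got[0] == pytest.approx(ref[0], abs=1e-9)
            assert got[1] == pytest.approx(ref[1], abs=1e-9)
            checked += 1

    def test_anisotropic_spacing_applied_per_axis(self):
        label = np.zeros((10, 10), np.uint8)
        label[5, 5] = 1
        pred = np.zeros_like(label)
        pred[5, 7] = 1                       # 2 columns away
        msd, off = mean_surface_distance(pred, label, (0.1, 0.4))
        assert msd == pytest.approx(0.8)
        assert off == 0.0

    def test_rejects_bad_spacing(self):
        m = np.zeros((4, 4), np.uint8)
        with pytest.raises(ValueError):
            mean_surface_distance(m, m, 0.0)


class TestEvaluateSet:
    @staticmethod
    def _line(row, shape=(16, 16)):
        m = np.zeros(shape, np.uint8)
        m[row, 2:14] = 1
        return m

    def test_mean_and_sample_sd(self):
        label = self._line(8)
        pred_perfect = self._line(8)
        pred_partial = np.zeros_like(label)
        pred_partial[8, 2:8] = 1             # t_prec 1, t_sens 0.5 -> 2/3
        meta = {"pixel_spacing_mm": 0.2}
        rep = evaluate_set([(pred_perfect, label, meta),
                            (pred_partial, label, meta)])
        vals = [1.0, 2 / 3]
        assert rep.overall["cl_dice_mean"] == pytest.approx(np.mean(vals))
        assert rep.overall["cl_dice_sd"] == pytest.approx(np.std(vals, ddof=1))

    def test_all_perfect(self):
        label = self._line(8)
        meta = {"pixel_spacing_mm": 0.2}
        rep = evaluate_set([(label, label, meta)] * 3)
        assert rep.overall["cl_dice_mean"] == 1.0
        assert rep.overall["msd_mean"] == 0.0

    def test_undefined_msd_excluded_and_counted(self):
        label = self._line(8)
        empty = np.zeros_like(label)
        meta = {"pixel_spacing_mm": 0.2}
        rep = evaluate_set([(label, label, meta), (empty, label, meta)])
        assert rep.n_msd_excluded == 1
        assert rep.overall["n_msd"] == 1
        assert rep.overall["msd_mean"] == 0.0
        assert rep.overall["cl_dice_mean"] == pytest.approx(0.5)

    def test_stratified_report_layout(self):
        label = self._line(8)
        rep = evaluate_set(
            [(label, label, {"pixel_spacing_mm": 0.2, "age_group": "<10"}),
             (label, label, {"pixel_spacing_mm": 0.2, "age_group": ">=10"})],
            strata_key="age_group")
        assert set(rep.by_stratum) == {"<10", ">=10"}
        table = rep.format_table()
        assert "all" in table and "<10" in table and ">=10" in table

    def test_score_pair_combines_all_fields(self):
        label = self._line(8)
        s = score_pair(label, label, 0.2)
        assert s.cl_dice == 1.0 and s.mean_surface_distance_mm == 0.0
        assert s.n_label_points == s.n_pred_points == 12
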