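"""Shape and size extraction from binary silhouettes."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from antmimic import morphometry as M
from antmimic import synthetic_data as S

from conftest import best_shift_iou, rasterize_rotated_rectangle

SCALE = 0.05  # mm/px used throughout


def disk_mask(r=100, pad=10):
    n = 2 * (r + pad)
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - n / 2) ** 2 + (yy - n / 2) ** 2 <= r**2


class TestCircularity:
    def test_disk_is_maximal(self):
        c = M.compute_circularity(M.SilhouetteMask(disk_mask(), SCALE))
        assert c == pytest.approx(1.0, abs=0.03)

    def test_square_closed_form(self):
        sq = np.zeros((220, 220), bool)
        sq[10:210, 10:210] = True
        c = M.compute_circularity(M.SilhouetteMask(sq, SCALE))
        assert c == pytest.approx(math.pi / 4, abs=0.03)

    def test_ellipse_ramanujan_oracle(self):
        a, b = 100, 25
        yy, xx = np.mgrid[0:230, 0:230]
        ell = ((xx - 115) / a) ** 2 + ((yy - 115) / b) ** 2 <= 1
        # independent oracle: Ramanujan's perimeter approximation
        h = ((a - b) / (a + b)) ** 2
        P = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        expected = 4 * math.pi * (math.pi * a * b) / P**2
        c = M.compute_circularity(M.SilhouetteMask(ell, SCALE))
        assert c == pytest.approx(expected, abs=0.03)

    def test_invariances(self):
        base = np.zeros((200, 260), bool)
        yy, xx = np.mgrid[0:200, 0:260]
        base |= ((xx - 120) / 80.0) ** 2 + ((yy - 100) / 40.0) ** 2 <= 1
        c0 = M.compute_circularity(M.SilhouetteMask(base, SCALE))
        shifted = np.roll(base, (7, -11), axis=(0, 1))
        assert M.compute_circularity(M.SilhouetteMask(shifted, SCALE)) == pytest.approx(c0, abs=1e-12)
        assert M.compute_circularity(M.SilhouetteMask(np.rot90(base), SCALE)) == pytest.approx(
            c0, abs=1e-9
        )
        from scipy.ndimage import rotate

        rot = rotate(base.astype(float), 25, reshape=True, order=1) > 0.5
        assert M.compute_circularity(M.SilhouetteMask(rot, SCALE)) == pytest.approx(c0, abs=0.03)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            M.compute_circularity(M.SilhouetteMask(np.zeros((10, 10), bool), SCALE))

    def test_multiple_components_rejected(self):
        img = np.zeros((30, 30), bool)
        img[2:8, 2:8] = True
        img[20:26, 20:26] = True
        with pytest.raises(ValueError, match="components"):
            M.compute_circularity(M.SilhouetteMask(img, SCALE))


class TestStraighten:
    def test_axis_aligned_rectangle_is_fixed_point(self):
        rect = np.zeros((120, 340), bool)
        rect[40:80, 40:300] = True
        st, axis = M.straighten_mask(M.SilhouetteMask(rect, SCALE))
        assert best_shift_iou(st, rect) > 0.99
        # axis is the horizontal centerline
        assert np.allclose(axis.points[:, 1], 59.5, atol=1.5)

    @pytest.mark.parametrize("angle", [15.0, 30.0, 60.0])
    def test_rotated_rectangle_recovered(self, angle):
        rect = np.zeros((120, 340), bool)
        rect[40:80, 40:300] = True
        rot = rasterize_rotated_rectangle(angle_deg=angle)
        st, _ = M.straighten_mask(M.SilhouetteMask(rot, SCALE))
        assert best_shift_iou(st, rect) >= 0.98

    def test_generator_spine_recovered(self):
        for seed in range(4):
            mask, truth = S.gen_silhouette("mimic", seed=seed)
            st, axis = M.straighten_mask(mask)
            d, _ = cKDTree(truth["spine"]).query(axis.points)
            assert np.sqrt((d**2).mean()) < 2.0
            # arc length preserved within 1% of the generating spine length
            assert axis.arc_length_px == pytest.approx(truth["length_px"], rel=0.02)

    def test_area_preserved(self):
        for seed in (0, 3):
            mask, _ = S.gen_silhouette("ant", seed=seed)
            st, _ = M.straighten_mask(mask)
            assert st.sum() == pytest.approx(mask.body.sum(), rel=0.03)

    def test_multi_component_rejected(self):
        img = np.zeros((40, 80), bool)
        img[5:15, 5:35] = True
        img[25:35, 45:75] = True
        with pytest.raises(ValueError, match="components"):
            M.straighten_mask(M.SilhouetteMask(img, SCALE))


class TestOutlineProfile:
    def _rect_straightened(self):
        rect = np.zeros((120, 340), bool)
        rect[40:80, 40:300] = True
        return M.straighten_mask(M.SilhouetteMask(rect, SCALE))[0]

    def test_rectangle_constant_profile(self):
        prof = M.compute_outline_profile(self._rect_straightened(), SCALE)
        assert prof.distances.std() / prof.distances.mean() < 0.02
        std = prof.standardize()
        assert std.standardized and std.distances.max() == 1.0
        assert np.allclose(std.distances, 1.0, atol=0.05)

    def test_mirror_flip_invariance(self):
        mask, _ = S.gen_silhouette("control", seed=5)
        st, _ = M.straighten_mask(mask)
        p1 = M.compute_outline_profile(st, SCALE)
        flipped = M.SilhouetteMask(
            mask.pixels[::-1].copy(), mask.scale, [], mask.body_only_pixels[::-1].copy()
        )
        st2, _ = M.straighten_mask(flipped)
        p2 = M.compute_outline_profile(st2, SCALE)
        assert np.allclose(p1.distances, p2.distances, atol=0.6 * SCALE)

    def test_dumbbell_constriction_position(self):
        # two blunt lobes joined by a neck at 50% length
        L = 200.0
        s = np.linspace(0, L, 400)
        u = s / L
        w = np.where(np.abs(u - 0.5) < 0.12, 20 * (1 - 0.6 * np.exp(-(((u - 0.5) / 0.08) ** 2))), 20.0)
        cols = np.arange(260.0)
        inside = (cols >= 30) & (cols <= 230)
        cw = np.where(inside, np.interp(cols, 30 + s, w), -1)
        img = np.abs(np.arange(120.0)[:, None] - 60.0) <= cw[None, :]
        st, _ = M.straighten_mask(M.SilhouetteMask(img, SCALE))
        prof = M.compute_outline_profile(st, SCALE)
        assert abs(int(np.argmin(prof.distances)) - 19.5) <= 1.5  # stations 19/20 bracket 50%

    def test_scaling_invariance_after_standardization(self):
        mask, _ = S.gen_silhouette("ant", seed=2)
        st, _ = M.straighten_mask(mask)
        p1 = M.compute_outline_profile(st, SCALE).standardize()
        p2 = M.compute_outline_profile(st, SCALE * 3).standardize()
        assert np.allclose(p1.distances, p2.distances)

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="40"):
            M.OutlineProfile(np.ones(30))
        with pytest.raises(ValueError, match=">= 0"):
            M.OutlineProfile(np.concatenate([np.ones(39), [-1.0]]))


class TestBodyLength:
    def test_straight_axis(self):
        axis = M.BodyAxis(np.column_stack([np.arange(201.0), np.zeros(201)]), SCALE)
        assert M.measure_body_length(axis) == pytest.approx(10.0)

    def test_semicircular_axis(self):
        r = 120
        t = np.linspace(0, np.pi, 400)
        axis = M.BodyAxis(np.column_stack([r * np.cos(t), r * np.sin(t)]), SCALE)
        assert M.measure_body_length(axis) == pytest.approx(np.pi * r * SCALE, rel=0.01)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            M.BodyAxis(np.zeros((1, 2)), SCALE)


class TestAppendageThickness:
    def test_six_px_bar(self):
        img = np.zeros((40, 60), bool)
        img[17:23, 5:55] = True
        lms = [
            M.Landmark(a, seg, 30.0, 20.0, 1.0, 0.0)
            for a in range(1, 5)
            for seg in ("femur", "tibia", "tarsus")
        ]
        sz = M.measure_appendage_thickness(M.SilhouetteMask(img, SCALE, lms))
        assert np.allclose(sz.appendage_thicknesses, 0.30, atol=0.02)
        assert sz.mean_thickness == pytest.approx(sz.appendage_thicknesses.mean())

    def test_generator_widths_recovered_within_one_px(self):
        for seed in range(4):
            mask, truth = S.gen_silhouette("ant", seed=seed)
            sz = M.measure_appendage_thickness(mask)
            err = np.abs(sz.appendage_thicknesses / SCALE - truth["segment_widths_px"])
            assert err.max() < 1.0

    def test_landmark_outside_rejected(self):
        img = np.zeros((40, 60), bool)
        img[17:23, 5:55] = True
        lms = [
            M.Landmark(a, seg, 30.0, 35.0, 1.0, 0.0)  # off the bar
            for a in range(1, 5)
            for seg in ("femur", "tibia", "tarsus")
        ]
        with pytest.raises(ValueError, match="appendage 1 femur"):
            M.measure_appendage_thickness(M.SilhouetteMask(img, SCALE, lms))

    def test_mean_is_sum_over_twelve(self, rng):
        vals = rng.uniform(0.1, 0.6, 12)
        st = M.SizeTraits(5.0, vals, float(vals.mean()))
        assert st.mean_thickness == pytest.approx(vals.sum() / 12)


class TestSpeciesMeanOutline:
    def test_single_profile_standardized(self):
        p = M.OutlineProfile(np.linspace(0.5, 2.0, 40))
        m = M.species_mean_outline([p])
        assert m.standardized and m.distances.max() == 1.0
        assert np.allclose(m.distances, p.distances / p.distances.max())

    def test_matches_loop_oracle(self, rng):
        profiles = [M.OutlineProfile(rng.uniform(0.2, 3.0, 40)) for _ in range(7)]
        m = M.species_mean_outline(profiles)
        # brute-force pointwise mean
        acc = np.zeros(40)
        for p in profiles:
            for i in range(40):
                acc[i] += p.distances[i]
        acc /= len(profiles)
        assert np.allclose(m.distances, acc / acc.max())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            M.species_mean_outline([])
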