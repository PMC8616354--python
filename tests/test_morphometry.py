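import numpy as np
import pytest

from platemorph import morphometry as mm
from platemorph.phantom import PhantomSpec, make_platelet_mask
from platemorph.types import BinaryMask, Outline, ParameterError


def brute_force_boundary(pix: np.ndarray) -> set[tuple[int, int]]:
    """All foreground pixels 4-adjacent to background or the border."""
    h, w = pix.shape
    out = set()
    for y in range(h):
        for x in range(w):
            if not pix[y, x]:
                continue
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w) or not pix[ny, nx]:
                    out.add((x, y))
                    break
    return out


class TestLabelPlatelets:
    def test_two_disjoint_disks(self):
        pix = np.zeros((60, 120), dtype=bool)
        yy, xx = np.mgrid[0:60, 0:120]
        pix |= (xx - 30) ** 2 + (yy - 30) ** 2 <= 100
        pix |= (xx - 90) ** 2 + (yy - 30) ** 2 <= 100
        comps = mm.label_platelets(BinaryMask(pix))
        assert len(comps) == 2

    def test_border_touching_excluded(self):
        pix = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[0:40, 0:40]
        pix |= (xx - 0) ** 2 + (yy - 20) ** 2 <= 64  # touches left border
        pix |= (xx - 28) ** 2 + (yy - 20) ** 2 <= 25
        comps = mm.label_platelets(BinaryMask(pix))
        assert len(comps) == 1
        assert not comps[0].pixels[:, 0].any()

    def test_empty_mask(self):
        assert mm.label_platelets(BinaryMask(np.zeros((16, 16), bool))) == []

    def test_min_area_filter(self):
        pix = np.zeros((40, 40), dtype=bool)
        pix[10:12, 10:12] = True  # 4 px
        pix[20:30, 20:30] = True  # 100 px
        comps = mm.label_platelets(BinaryMask(pix), min_area=50.0)
        assert len(comps) == 1
        assert comps[0].area_px == 100

    def test_row_major_ordering(self):
        pix = np.zeros((60, 60), dtype=bool)
        pix[40:48, 5:13] = True
        pix[10:18, 30:38] = True
        comps = mm.label_platelets(BinaryMask(pix))
        cents = [np.argwhere(c.pixels).mean(axis=0) for c in comps]
        assert cents[0][0] < cents[1][0]


class TestTraceContour:
    def test_3x3_square_eight_points_in_order(self):
        pix = np.pad(np.ones((3, 3), dtype=bool), 2)
        outline = mm.trace_contour(BinaryMask(pix))
        assert len(outline) == 8
        pts = {tuple(p) for p in outline.points.astype(int)}
        assert pts == brute_force_boundary(pix)
        # successive points are 8-adjacent
        diffs = np.abs(np.diff(np.vstack([outline.points,
                                          outline.points[:1]]), axis=0))
        assert (diffs.max(axis=1) == 1).all()

    def test_every_boundary_pixel_represented(self):
        mask, _ = make_platelet_mask(
            PhantomSpec(body_semi_axes=(12.0, 8.0), n_filopodia=3,
                        filopodium_length=7.0, filopodium_width=3.0, seed=2))
        outline = mm.trace_contour(mask)
        traced = {tuple(p) for p in outline.points.astype(int)}
        assert traced == brute_force_boundary(mask.pixels)

    def test_contour_length_converges_to_circumference(self, disk50):
        mask, _ = disk50
        perim = mm.subpixel_perimeter(mask)
        assert perim / (2 * np.pi * 50) == pytest.approx(1.0, abs=0.05)

    def test_rerasterizing_contour_covers_component_boundary(self):
        mask, _ = make_platelet_mask(PhantomSpec(body_semi_axes=(10.0, 7.0)))
        outline = mm.trace_contour(mask)
        from scipy import ndimage
        filled = np.zeros(mask.shape, dtype=bool)
        pts = outline.points.astype(int)
        filled[pts[:, 1], pts[:, 0]] = True
        filled = ndimage.binary_fill_holes(filled)
        assert (filled == mask.pixels).all()

    def test_multi_component_rejected(self):
        pix = np.zeros((30, 30), dtype=bool)
        pix[5:10, 5:10] = True
        pix[20:25, 20:25] = True
        with pytest.raises(ParameterError):
            mm.trace_contour(BinaryMask(pix))


class TestShapeParameters:
    def test_disk_circularity_near_one(self, disk50):
        mask, _ = disk50
        rec = mm.measure_mask(mask)[0]
        assert rec.circularity == pytest.approx(1.0, abs=0.02)

    def test_square_circularity(self, square60):
        rec = mm.measure_mask(square60)[0]
        assert rec.circularity == pytest.approx(np.pi / 4, abs=0.02)

    def test_designed_ellipse_aspect_ratio(self, ellipse_30_15):
        mask, _ = ellipse_30_15
        rec = mm.measure_mask(mask)[0]
        assert rec.aspect_ratio == pytest.approx(2.0, abs=0.05)

    def test_area_is_pixel_count_scaled(self):
        mask, _ = make_platelet_mask(PhantomSpec(body_semi_axes=(15.0, 10.0)),
                                     pixel_size=0.2)
        rec = mm.measure_mask(mask)[0]
        assert rec.area == pytest.approx(mask.area_px * 0.04)

    def test_degenerate_component_rejected(self):
        pix = np.zeros((20, 20), dtype=bool)
        pix[5:15, 10] = True  # 1-px-wide line
        comp = BinaryMask(pix)
        outline_pts = np.argwhere(pix)[:, ::-1].astype(float)
        outline = Outline(outline_pts)
        with pytest.raises(mm.DegenerateShapeError):
            mm.shape_parameters(outline, comp)


class TestCurvature:
    def test_disk_mean_curvature(self, disk50):
        mask, _ = disk50
        outline = mm.trace_contour(mask)
        kappa = mm.curvature_profile(outline)
        assert kappa.mean() == pytest.approx(1 / 50, rel=0.10)

    def test_straight_edges_of_rounded_rectangle(self):
        from scipy import ndimage
        pix = np.zeros((40, 80), dtype=bool)
        pix[10:30, 10:70] = True
        pix = ndimage.binary_opening(pix, structure=np.ones((5, 5)))
        outline = mm.trace_contour(BinaryMask(pix))
        kappa = mm.curvature_profile(outline)
        x = mm.smooth_outline(outline).x
        straight = (x > 25) & (x < 55)
        assert np.abs(kappa[straight]).max() < 0.05

    def test_sign_flips_at_spike_neck(self):
        mask, _ = make_platelet_mask(
            PhantomSpec(body_semi_axes=(15.0, 15.0), n_filopodia=1,
                        filopodium_length=10.0, filopodium_width=4.0, seed=0))
        outline = mm.trace_contour(mask)
        kappa = mm.curvature_profile(outline)
        assert kappa.max() > 0.3   # convex tip
        assert kappa.min() < -0.05  # concave neck

    def test_curvature_scales_with_pixel_size(self, disk50):
        mask, _ = disk50
        outline = mm.trace_contour(mask)
        halved = Outline(outline.points, pixel_size=0.5)
        k1 = mm.curvature_profile(outline)
        k2 = mm.curvature_profile(halved)
        assert np.allclose(k2, 2 * k1)


class TestCountFilopodia:
    PS = 0.1  # µm/px

    def _count(self, spec):
        mask, _ = make_platelet_mask(spec, pixel_size=self.PS)
        return mm.measure_mask(mask)[0].n_filopodia

    def test_plain_disk_zero(self):
        assert self._count(PhantomSpec(body_semi_axes=(20.0, 20.0))) == 0

    def test_five_designed(self):
        spec = PhantomSpec(body_semi_axes=(20.0, 20.0), n_filopodia=5,
                           filopodium_length=15.0, filopodium_width=4.0, seed=1)
        assert self._count(spec) == 5

    def test_min_length_above_design_gives_zero(self):
        spec = PhantomSpec(body_semi_axes=(20.0, 20.0), n_filopodia=5,
                           filopodium_length=15.0, filopodium_width=4.0, seed=1)
        mask, _ = make_platelet_mask(spec, pixel_size=self.PS)
        rec = mm.measure_mask(mask, filo_min_length=5.0)[0]
        assert rec.n_filopodia == 0

    @pytest.mark.parametrize("designed", range(9))
    def test_recovery_rate_at_least_95_percent(self, designed):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = PhantomSpec(body_semi_axes=(20.0, 20.0),
                               n_filopodia=designed, filopodium_length=15.0,
                               filopodium_width=4.0, seed=seed)
            hits += self._count(spec) == designed
        assert hits >= 0.95 * n_seeds

    def test_monotone_in_added_filopodia(self):
        counts, circs = [], []
        for n in (0, 2, 4, 6, 8):
            spec = PhantomSpec(body_semi_axes=(20.0, 20.0), n_filopodia=n,
                               filopodium_length=15.0, filopodium_width=4.0,
                               seed=3)
            mask, _ = make_platelet_mask(spec, pixel_size=self.PS)
            rec = mm.measure_mask(mask)[0]
            counts.append(rec.n_filopodia)
            circs.append(rec.circularity)
        assert counts == sorted(counts)
        assert circs == sorted(circs, reverse=True)
        assert all(c2 < c1 for c1, c2 in zip(circs, circs[1:]))


class TestInvariants:
    def test_rotation_invariance(self):
        vals = {"area": [], "circ": [], "ar": [], "nf": []}
        for ang in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            spec = PhantomSpec(body_semi_axes=(25.0, 12.0), orientation=float(ang),
                               n_filopodia=4, filopodium_length=12.0,
                               filopodium_width=4.0, seed=2)
            mask, _ = make_platelet_mask(spec, pixel_size=0.1)
            rec = mm.measure_mask(mask)[0]
            vals["area"].append(rec.area)
            vals["circ"].append(rec.circularity)
            vals["ar"].append(rec.aspect_ratio)
            vals["nf"].append(rec.n_filopodia)
        for key in ("area", "circ", "ar"):
            arr = np.array(vals[key])
            assert (arr.max() - arr.min()) / arr.mean() < 0.03, key
        assert len(set(vals["nf"])) == 1

    def test_circularity_bounded(self):
        shapes = [PhantomSpec(body_semi_axes=(r, r)) for r in (5, 10, 25, 50)]
        shapes += [PhantomSpec(body_semi_axes=(30.0, 10.0)),
                   PhantomSpec(body_semi_axes=(20.0, 20.0), n_filopodia=6,
                               filopodium_length=10.0, filopodium_width=3.0)]
        for spec in shapes:
            mask, _ = make_platelet_mask(spec)
            rec = mm.measure_mask(mask)[0]
            assert rec.circularity <= 1.01

    def test_star_circularity_decreases_with_arms(self):
        circs = []
        for n in (0, 2, 4, 6, 8):
            spec = PhantomSpec(body_semi_axes=(20.0, 20.0), n_filopodia=n,
                               filopodium_length=15.0, filopodium_width=4.0,
                               seed=1)
            mask, _ = make_platelet_mask(spec)
            circs.append(mm.measure_mask(mask)[0].circularity)
        assert all(b < a for a, b in zip(circs, circs[1:]))
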