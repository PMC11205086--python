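"""Unit and property tests for the pixel-exact halving geometry."""

from __future__ import annotations

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st

from woundhalve.errors import (
    CannotHalveError,
    DegenerateMaskError,
    EmptyMaskError,
    InvalidOutlineError,
)
from woundhalve.geometry import (
    BinaryMask,
    HalvingLine,
    StripProfile,
    WoundOutline,
    halve,
    halving_line,
    min_area_box,
    rasterize_outline,
    rasterize_outlines,
    select_halving,
    split_by_line,
    strip_profile,
)

from conftest import (
    brute_force_min_box_extents,
    point_in_polygon_oracle,
    random_blob_mask,
)


def _rect_mask(h=8, w=12, r0=2, r1=6, c0=1, c1=11) -> BinaryMask:
    g = np.zeros((h, w), dtype=bool)
    g[r0:r1, c0:c1] = True
    return BinaryMask(g)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


class TestRasterize:
    def test_axis_aligned_square_covers_16_pixels(self):
        outline = WoundOutline([(0, 0), (4, 0), (4, 4), (0, 4)], (8, 8))
        mask = rasterize_outline(outline)
        assert mask.pixel_count == 16
        assert mask.grid[:4, :4].all() and mask.grid.sum() == 16

    def test_subpixel_triangle_encloses_no_center(self):
        outline = WoundOutline([(0.1, 0.1), (0.4, 0.1), (0.2, 0.4)], (8, 8))
        with pytest.raises(InvalidOutlineError):
            rasterize_outline(outline)

    @pytest.mark.parametrize(
        "vertices",
        [
            [(0, 0), (6, 0), (0, 6)],
            [(1.2, 0.7), (6.9, 2.1), (4.4, 7.3), (0.3, 5.2)],
        ],
    )
    def test_matches_point_in_polygon_oracle(self, vertices):
        outline = WoundOutline(vertices, (8, 8))
        mask = rasterize_outline(outline)
        for i in range(8):
            for j in range(8):
                expected = point_in_polygon_oracle(j + 0.5, i + 0.5, vertices)
                if expected is None:  # center on the border: convention is open
                    continue
                assert mask.grid[i, j] == expected, (i, j)

    def test_outline_invariants_rejected(self):
        with pytest.raises(InvalidOutlineError):
            WoundOutline([(0, 0), (4, 0)], (8, 8))  # too few vertices
        with pytest.raises(InvalidOutlineError):
            WoundOutline([(0, 0), (4, 0), (8, 0)], (16, 16))  # zero area
        with pytest.raises(InvalidOutlineError):
            WoundOutline([(0, 0), (9, 0), (0, 4)], (8, 8))  # out of bounds

    def test_even_odd_union_with_hole(self):
        outer = WoundOutline([(0, 0), (10, 0), (10, 10), (0, 10)], (16, 16))
        hole = WoundOutline([(3, 3), (7, 3), (7, 7), (3, 7)], (16, 16))
        mask = rasterize_outlines([outer, hole])
        assert mask.pixel_count == 100 - 16
        assert not mask.grid[4, 4] and mask.grid[1, 1]


# ---------------------------------------------------------------------------
# minimum-area oriented bounding box
# ---------------------------------------------------------------------------


class TestMinAreaBox:
    def test_axis_aligned_rectangle_extents(self):
        box = min_area_box(_rect_mask())
        assert box.length_L == pytest.approx(9.0)
        assert box.width_W == pytest.approx(3.0)
        assert np.allclose(box.long_axis, [1.0, 0.0])
        assert np.allclose(box.center, [6.0, 4.0])

    def test_rotated_rectangle_recovers_minimal_area(self):
        # rasterize a 40x14 rectangle rotated by 30 degrees
        ang = np.deg2rad(30.0)
        c, s = np.cos(ang), np.sin(ang)
        corners = np.array([[-20, -7], [20, -7], [20, 7], [-20, 7]], float)
        rot = corners @ np.array([[c, s], [-s, c]]) + 32
        outline = WoundOutline(rot, (64, 64))
        mask = rasterize_outline(outline)
        box = min_area_box(mask)
        brute = brute_force_min_box_extents(mask.foreground_centers(), 0.1)
        assert box.length_L * box.width_W <= brute * 1.05

    def test_degenerate_masks_rejected(self):
        g = np.zeros((8, 8), dtype=bool)
        with pytest.raises(EmptyMaskError):
            min_area_box(BinaryMask(g))
        g[3, 3] = True
        with pytest.raises(DegenerateMaskError):
            min_area_box(BinaryMask(g))  # single pixel
        g[3, 4], g[3, 5] = True, True
        with pytest.raises(DegenerateMaskError):
            min_area_box(BinaryMask(g))  # collinear row

    def test_every_center_inside_box(self, rng):
        for _ in range(20):
            mask = random_blob_mask(rng)
            box = min_area_box(mask)
            off = box.long_offsets(mask.foreground_centers())
            assert off.min() >= -1e-6
            assert off.max() <= box.length_L + 1e-6

    def test_agrees_with_shapely_oriented_envelope(self, rng):
        for _ in range(20):
            mask = random_blob_mask(rng)
            box = min_area_box(mask)
            env = shapely.oriented_envelope(
                shapely.MultiPoint(mask.foreground_centers())
            )
            assert box.length_L * box.width_W <= env.area * (1 + 1e-9)


# ---------------------------------------------------------------------------
# strip sweep and selection
# ---------------------------------------------------------------------------


class TestStripProfile:
    def test_uniform_rectangle_profile(self):
        mask = _rect_mask()
        prof = strip_profile(mask, min_area_box(mask))
        assert prof.cumulative.tolist() == [4, 8, 12, 16, 20, 24, 28, 32, 36, 40]

    def test_partition_property(self, rng):
        for _ in range(20):
            mask = random_blob_mask(rng)
            prof = strip_profile(mask, min_area_box(mask))
            assert prof.cumulative[-1] == mask.pixel_count
            assert (np.diff(prof.cumulative) >= 0).all()

    def test_two_blob_gap_gives_plateau(self):
        g = np.zeros((10, 30), dtype=bool)
        g[3:7, 2:6] = True
        g[3:7, 20:24] = True
        mask = BinaryMask(g)
        prof = strip_profile(mask, min_area_box(mask))
        masses = prof.strip_masses()
        assert (masses[5:17] == 0).all()  # flat plateau over the gap
        assert prof.cumulative[-1] == 32


class TestSelectHalving:
    @pytest.mark.parametrize(
        "cumulative, n_expected, f1_expected",
        [
            ([4, 8, 12, 16, 20, 24, 28, 32, 36, 40], 5, 50.0),
            ([1, 3, 10, 12, 14], 3, 100 * 10 / 14),
            ([2, 6, 8], 1, 25.0),  # tie |2-4| == |6-4| -> smallest n
        ],
    )
    def test_examples(self, cumulative, n_expected, f1_expected):
        prof = StripProfile(np.asarray(cumulative), int(cumulative[-1]))
        split = select_halving(prof)
        assert split.n_selected == n_expected
        assert split.fraction_side1 == pytest.approx(f1_expected)
        assert split.fraction_side1 + split.fraction_side2 == pytest.approx(100.0)

    def test_single_pixel_cannot_halve(self):
        with pytest.raises(CannotHalveError):
            select_halving(StripProfile(np.array([1]), 1))

    @given(
        masses=st.lists(st.integers(min_value=0, max_value=9), min_size=1,
                        max_size=30).filter(lambda m: sum(m) >= 2)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exhaustive_minimization(self, masses):
        c = np.cumsum(masses)
        prof = StripProfile(c, int(c[-1]))
        split = select_halving(prof)
        target = c[-1] / 2.0
        best = min(range(len(c)), key=lambda i: (abs(c[i] - target), i))
        assert split.n_selected == best + 1

    @given(
        masses=st.lists(st.integers(min_value=0, max_value=9), min_size=1,
                        max_size=30).filter(lambda m: sum(m) >= 2)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_sweep_direction_invariance(self, masses):
        c = np.cumsum(masses)
        prof = StripProfile(c, int(c[-1]))
        rev = np.cumsum(masses[::-1])
        prof_rev = StripProfile(rev, int(rev[-1]))
        assert select_halving(prof).abs_deviation == pytest.approx(
            select_halving(prof_rev).abs_deviation
        )

    def test_deviation_bounded_by_half_max_strip(self, rng):
        for _ in range(30):
            mask = random_blob_mask(rng)
            prof = strip_profile(mask, min_area_box(mask))
            split = select_halving(prof)
            bound = 100.0 * prof.strip_masses().max() / (2.0 * prof.total_A)
            assert split.abs_deviation <= bound + 1e-9


class TestHalvingLine:
    def test_axis_aligned_line_position(self):
        mask = _rect_mask()  # columns 1..10, centers x in [1.5, 10.5]
        box = min_area_box(mask)
        split = select_halving(strip_profile(mask, box))
        line = halving_line(box, split)
        assert split.n_selected == 5
        assert np.allclose(line.endpoints[:, 0], 1.5 + 5)  # x_min + n
        assert sorted(line.endpoints[:, 1].tolist()) == [2.5, 5.5]

    def test_endpoints_on_box_boundary(self, rng):
        for _ in range(10):
            mask = random_blob_mask(rng)
            box = min_area_box(mask)
            line = halving_line(box, select_halving(strip_profile(mask, box)))
            for p in line.endpoints:
                off_long = box.long_offsets(p[None, :])[0]
                off_short = abs((p - box.center) @ box.short_axis)
                assert -1e-9 <= off_long <= box.length_L + 1e-9
                assert off_short == pytest.approx(box.width_W / 2.0)

    def test_right_angle_rotation_equivariance(self, rng):
        mask = random_blob_mask(rng)
        out = halve(mask)
        rot = BinaryMask(np.rot90(mask.grid))
        out_rot = halve(rot)
        assert out_rot.split.abs_deviation == pytest.approx(
            out.split.abs_deviation
        )
        fr = sorted([out.split.fraction_side1, out.split.fraction_side2])
        fr_rot = sorted([out_rot.split.fraction_side1, out_rot.split.fraction_side2])
        assert fr == pytest.approx(fr_rot)


# ---------------------------------------------------------------------------
# splitting by arbitrary lines
# ---------------------------------------------------------------------------


class TestSplitByLine:
    def test_center_line_halves_even_rectangle(self):
        mask = _rect_mask()  # 10 columns wide
        line = HalvingLine([(6.0, -5.0), (6.0, 20.0)], "manual")
        split = split_by_line(mask, line)
        assert split.fraction_side1 == pytest.approx(50.0)
        assert not split.non_separating

    def test_line_outside_wound_is_non_separating(self):
        mask = _rect_mask()
        split = split_by_line(mask, HalvingLine([(11.8, 0.0), (11.8, 8.0)], "manual"))
        assert split.non_separating
        assert split.fraction_side1 in (0.0, 100.0)
        assert split.abs_deviation == pytest.approx(50.0)

    def test_short_segment_is_extended_to_border(self):
        # a 2-px stub in the middle still splits the whole 10-px-wide wound
        mask = _rect_mask()
        split = split_by_line(mask, HalvingLine([(6.0, 3.5), (6.0, 4.5)], "manual"))
        assert split.fraction_side1 == pytest.approx(50.0)

    def test_diagonal_line_matches_per_pixel_oracle(self, rng):
        yy, xx = np.mgrid[0:40, 0:40]
        mask = BinaryMask((xx + 0.5 - 20) ** 2 + (yy + 0.5 - 20) ** 2 < 14**2)
        a, b = np.array([3.0, 1.0]), np.array([38.0, 36.0])
        split = split_by_line(mask, HalvingLine([a, b], "manual"))
        d = b - a
        centers = mask.foreground_centers()
        cross = d[0] * (centers[:, 1] - a[1]) - d[1] * (centers[:, 0] - a[0])
        expected = 100.0 * (cross >= 0).sum() / len(centers)
        assert split.fraction_side1 == pytest.approx(expected)

    def test_partition_is_exact(self, rng):
        for _ in range(10):
            mask = random_blob_mask(rng)
            p = rng.uniform(0, 48, size=(2, 2))
            if np.allclose(p[0], p[1]):
                continue
            split = split_by_line(mask, HalvingLine(p, "manual"))
            n1 = round(split.fraction_side1 * mask.pixel_count / 100.0)
            n2 = round(split.fraction_side2 * mask.pixel_count / 100.0)
            assert n1 + n2 == mask.pixel_count
            assert split.fraction_side1 + split.fraction_side2 == 100.0


class TestRigidMotions:
    def test_translation_leaves_fractions_unchanged(self, rng):
        mask = random_blob_mask(rng)
        out = halve(mask)
        g = np.zeros((70, 75), dtype=bool)
        g[11 : 11 + 48, 17 : 17 + 48] = mask.grid
        out_t = halve(BinaryMask(g))
        assert out_t.split.fraction_side1 == pytest.approx(
            out.split.fraction_side1
        )
        assert out_t.split.n_selected == out.split.n_selected


class TestResolutionConsistency:
    def test_doubling_resolution_barely_moves_the_fraction(self, rng):
        """Median |delta fraction| across wounds stays within 0.5 points at 2x."""
        from woundhalve.simulate import generate_wound

        from woundhalve.simulate import sample_wound_params

        deltas = []
        for i in range(50):
            r = np.random.default_rng(900 + i)
            params = sample_wound_params(
                r, image_size=(320, 320), long_axis_range=(100, 180)
            )
            outline = generate_wound(params)
            f1 = halve(rasterize_outline(outline)).split.fraction_side1
            doubled = WoundOutline(outline.vertices * 2.0, (640, 640))
            f2 = halve(rasterize_outline(doubled)).split.fraction_side1
            deltas.append(abs(f1 - f2))
        assert np.median(deltas) <= 0.5
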