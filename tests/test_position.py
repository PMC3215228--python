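"""Position metrics: margins, extrusion, coverage, uncovered TA, overlap."""

import math
import warnings

import numpy as np
import pytest

from menmorph.morphometry import ContourStack
from menmorph.position import (SliceMargins, compute_margins, coverage,
                               extrusion_stats, footprint_intervals,
                               overlap_distance_stats, slice_diagnostics,
                               uncovered_ta)
from menmorph.segio import ValidationError


def rect(x0, x1, z0=0.0, z1=2.0):
    return np.array([[x0, z0], [x1, z0], [x1, z1], [x0, z1], [x0, z0]], float)


def stack(intervals_by_slice, dy=1.0, z=(0.0, 2.0)):
    return ContourStack(
        {iy: [rect(lo, hi, *z) for lo, hi in ivals]
         for iy, ivals in intervals_by_slice.items()}, "s", dy)


def margins_from(e_by_slice, d_by_slice=None, sign=1, dy=1.0):
    d_by_slice = d_by_slice or {k: -5.0 for k in e_by_slice}
    return SliceMargins({iy: (0.0, e, d_by_slice[iy])
                         for iy, e in e_by_slice.items()}, sign, dy)


class TestMarginsAndExtrusion:
    def test_margins_by_construction(self):
        # lateral side: u = +x.  TA spans u in [-10, 1.5], plateau edge at 0,
        # femoral surface shares the internal junction vertex at u = -10.
        cart = stack({0: [(-20.0, 0.0)]})
        ta = ContourStack({0: [np.array([[-10.0, 0.0], [1.5, 0.0]])]}, "ta", 1.0)
        fa = ContourStack({0: [np.array([[-10.0, 0.0], [1.5, 2.0]])]}, "fa", 1.0)
        m = compute_margins(cart, ta, fa, "lateral", [0])
        u_ac, u_ta_ext, u_ta_int = m.margins[0]
        assert u_ac == pytest.approx(0.0)
        assert u_ta_ext == pytest.approx(1.5)
        assert u_ta_int == pytest.approx(-10.0)

    def test_medial_outward_is_negative_x(self):
        cart = stack({0: [(0.0, 20.0)]})     # medial: external = smaller x
        ta = ContourStack({0: [np.array([[-1.5, 0.0], [10.0, 0.0]])]}, "ta", 1.0)
        fa = ContourStack({0: [np.array([[10.0, 2.0], [-1.5, 0.0]])]}, "fa", 1.0)
        m = compute_margins(cart, ta, fa, "medial", [0])
        e, _ = extrusion_stats(m)
        assert e == pytest.approx(1.5)       # meniscus extends 1.5 mm medially

    def test_extrusion_mean_and_max(self):
        m = margins_from({0: 1.0, 1: 2.0, 2: 3.0})
        assert extrusion_stats(m) == (pytest.approx(2.0), pytest.approx(3.0))

    def test_all_negative_extrusions(self):
        m = margins_from({0: -3.0, 1: -1.0, 2: -2.0})
        e_me, e_max = extrusion_stats(m)
        assert e_max == pytest.approx(-1.0)
        assert e_max >= e_me

    def test_overlap_signed_mean(self):
        m = margins_from({i: 1.0 for i in range(4)}, {i: -12.0 for i in range(4)})
        d_me, d_max = overlap_distance_stats(m)
        assert d_me == pytest.approx(-12.0)
        assert d_max >= d_me

    def test_published_signed_convention_consistency(self):
        # medial means -12.0 (mean) vs -4.66 (max): under the signed-max
        # convention the max is the less-internal value, so max >= mean and
        # |mean| > |max| for all-negative distances.
        assert -4.66 >= -12.0
        m = margins_from({0: 1.0, 1: 1.0}, {0: -12.0, 1: -4.66})
        d_me, d_max = overlap_distance_stats(m)
        assert d_max == pytest.approx(-4.66)
        assert abs(d_me) > abs(d_max)

    def test_slices_without_junction_are_skipped(self):
        m = SliceMargins({0: (0.0, 1.0, math.nan), 1: (0.0, 1.0, -7.0)}, 1, 1.0)
        d_me, d_max = overlap_distance_stats(m)
        assert d_me == pytest.approx(-7.0)

    def test_empty_slice_set_rejected(self):
        cart = stack({0: [(0.0, 1.0)]})
        with pytest.raises(ValidationError):
            compute_margins(cart, cart, cart, "medial", [])


class TestCoverage:
    def test_half_covered(self):
        cart_fp = footprint_intervals(stack({i: [(0.0, 10.0)] for i in range(4)}),
                                      range(4))
        ta_fp = footprint_intervals(stack({i: [(5.0, 10.0)] for i in range(4)}),
                                    range(4))
        cov, covp = coverage(cart_fp, ta_fp, range(4), dy=1.0)
        assert covp == pytest.approx(50.0)
        assert cov == pytest.approx(20.0)

    def test_disc_annulus_closed_form(self):
        """Concentric full annulus [10, 20] on a disc of radius 19."""
        a, r_in, r_out, dy = 19.0, 10.0, 20.0, 0.05
        ys = np.arange(-a + dy / 2, a, dy)
        cart, ta = {}, {}
        for i, y in enumerate(ys):
            half = math.sqrt(a * a - y * y)
            cart[i] = [(-half, half)]
            ho = math.sqrt(max(r_out ** 2 - y * y, 0.0))
            hi = math.sqrt(max(r_in ** 2 - y * y, 0.0))
            ta[i] = [(-ho, -hi), (hi, ho)] if hi > 0 else [(-ho, ho)]
        cov, covp = coverage(cart, ta, range(len(ys)), dy)
        expected = 100.0 * (a ** 2 - r_in ** 2) / a ** 2        # = 72.299...
        assert covp == pytest.approx(expected, abs=0.1)
        # 2D raster oracle for the same configuration
        n = 1500
        xs = np.linspace(-r_out, r_out, n)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        r = np.hypot(X, Y)
        disc = r <= a
        ann = (r >= r_in) & (r <= r_out)
        raster = 100.0 * (disc & ann).sum() / disc.sum()
        assert covp == pytest.approx(raster, abs=1.0)

    def test_zero_plateau_rejected(self):
        with pytest.raises(ValidationError):
            coverage({}, {}, [0], 1.0)

    def test_covered_plus_uncovered_plateau_is_total(self):
        cart_fp = {0: [(0.0, 10.0)]}
        ta_fp = {0: [(6.0, 12.0)]}
        cov, covp = coverage(cart_fp, ta_fp, [0], 1.0)
        uncovered_plateau = 10.0 - cov
        assert cov + uncovered_plateau == pytest.approx(10.0)
        assert covp == pytest.approx(40.0)


class TestUncoveredTA:
    def test_fully_inside(self):
        cart_fp = {0: [(0.0, 15.0)]}
        ta_fp = {0: [(2.0, 10.0)]}
        assert uncovered_ta(cart_fp, ta_fp, [0], 1.0) == (pytest.approx(0.0),
                                                          pytest.approx(0.0))

    def test_overhang_fraction(self):
        cart_fp = {i: [(0.0, 15.0)] for i in range(3)}
        ta_fp = {i: [(10.0, 16.5)] for i in range(3)}      # 1.5 of 6.5 outside
        unc, uncp = uncovered_ta(cart_fp, ta_fp, range(3), 1.0)
        assert uncp == pytest.approx(100 * 1.5 / 6.5)
        assert unc == pytest.approx(3 * 1.5)

    def test_monotone_in_radial_offset(self):
        """More extruded phantom -> strictly larger uncovered TA fraction."""
        import dataclasses

        from menmorph.morphometry import compute_morphometry
        from menmorph.phantom import preset_params, voxelize_phantom

        p1 = preset_params("F", "medial")                    # delta = 1.83
        p0 = dataclasses.replace(p1, outer_radius=p1.plateau_semi_axis_x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = compute_morphometry(voxelize_phantom(p1), "medial")
            r0 = compute_morphometry(voxelize_phantom(p0), "medial")
        assert r1.TA_Uncovp > r0.TA_Uncovp


class TestRigidShifts:
    def mk_margins(self, shift_meniscus=0.0, shift_all=0.0):
        cart = stack({i: [(0.0 + shift_all, 20.0 + shift_all)] for i in range(3)})
        ta = ContourStack(
            {i: [np.array([[6.0 + shift_meniscus + shift_all, 0.0],
                           [21.0 + shift_meniscus + shift_all, 0.0]])]
             for i in range(3)}, "ta", 1.0)
        fa = ContourStack(
            {i: [np.array([[6.0 + shift_meniscus + shift_all, 0.0],
                           [21.0 + shift_meniscus + shift_all, 2.0]])]
             for i in range(3)}, "fa", 1.0)
        return compute_margins(cart, ta, fa, "lateral", range(3))

    def test_translation_invariance(self):
        base, moved = self.mk_margins(), self.mk_margins(shift_all=7.3)
        assert extrusion_stats(base) == pytest.approx(extrusion_stats(moved))
        assert overlap_distance_stats(base) == pytest.approx(
            overlap_distance_stats(moved))

    def test_outward_shift_equivariance(self):
        t = 2.5
        base, moved = self.mk_margins(), self.mk_margins(shift_meniscus=t)
        assert extrusion_stats(moved)[0] == pytest.approx(extrusion_stats(base)[0] + t)
        assert overlap_distance_stats(moved)[0] == pytest.approx(
            overlap_distance_stats(base)[0] + t)


def test_slice_diagnostics_table(tmp_path):
    m = margins_from({0: 1.0, 1: 2.0}, {0: -8.0, 1: -9.0})
    cart_fp = {0: [(0.0, 10.0)], 1: [(0.0, 10.0)]}
    ta_fp = {0: [(5.0, 11.0)], 1: [(4.0, 11.0)]}
    df = slice_diagnostics(m, cart_fp, ta_fp, tmp_path / "d.csv")
    assert list(df.columns)[:3] == ["slice", "extrusion_mm", "overlap_distance_mm"]
    assert (tmp_path / "d.csv").exists()
    assert df.loc[0, "covered_length_mm"] == pytest.approx(5.0)
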