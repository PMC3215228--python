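"""Surface partition (TA/FA/EA) and serial-section ribbon triangulation."""

import math
import warnings

import numpy as np
import pytest

from conftest import make_seg
from menmorph.morphometry import (ContourStack, TriangulatedSurface,
                                  classify_contour_segments,
                                  meniscus_surface_areas,
                                  partition_meniscus_surface, surface_area,
                                  total_surface_area,
                                  triangulate_between_slices)
from menmorph.segio import ValidationError

RECT = np.array([[0.0, 0.0], [8.0, 0.0], [8.0, 4.0], [0.0, 4.0], [0.0, 0.0]])


class TestEdgeClassification:
    def test_rectangle_fixed_outward_sign(self):
        # compartment centre to the left => external side is +x
        runs = classify_contour_segments(RECT, outward_sign=+1)
        by_tag = {}
        for tag, verts in runs:
            by_tag.setdefault(tag, 0.0)
            by_tag[tag] += np.hypot(*np.diff(verts, axis=0).T).sum()
        # external vertical edge whole; internal vertical edge split to
        # bottom/top at its mid height, so bottom/top each gain 2 mm
        assert by_tag["bottom"] == pytest.approx(10.0)
        assert by_tag["top"] == pytest.approx(10.0)
        assert by_tag["external"] == pytest.approx(4.0)

    def test_internal_edge_split_point_at_mid_height(self):
        runs = classify_contour_segments(RECT, outward_sign=+1)
        bottom_z = np.concatenate([v[:, 1] for t, v in runs if t == "bottom"])
        top_z = np.concatenate([v[:, 1] for t, v in runs if t == "top"])
        # the internal edge (x = 0) is split exactly at z = 2: the bottom run
        # climbs to z = 2 and the top run descends to z = 2
        assert bottom_z.max() == pytest.approx(2.0)
        assert top_z.min() == pytest.approx(2.0)

    def test_radial_mode_tags_both_outer_walls_external(self):
        # two rectangles on either side of the centre, as one ring-like contour
        ring = np.array([[-10, 0], [10, 0], [10, 4], [-10, 4], [-10, 0]], float)
        runs = classify_contour_segments(ring, center_x=0.0)
        ext = sum(np.hypot(*np.diff(v, axis=0).T).sum()
                  for t, v in runs if t == "external")
        assert ext == pytest.approx(8.0)      # both vertical walls

    def test_exactly_45_degree_edges_prefer_bottom_top(self):
        tri = np.array([[0, 0], [4, 0], [0, 4], [0, 0]], float)
        runs = classify_contour_segments(tri, outward_sign=-1)
        tags = {t for t, _ in runs}
        assert "top" in tags          # the 45-degree hypotenuse
        ext = [v for t, v in runs if t == "external"]
        assert not ext or all(np.allclose(v[:, 0], 0.0) for v in ext)


class TestRibbon:
    def test_two_parallel_squares(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], float)
        st = ContourStack({0: [sq], 1: [sq]}, "s", 1.5)
        assert surface_area(triangulate_between_slices(st)) == pytest.approx(60.0)

    def test_cylinder_wall(self):
        th = np.linspace(0, 2 * math.pi, 257)
        circ = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
        st = ContourStack({0: [circ], 1: [circ]}, "c", 1.5)
        area = surface_area(triangulate_between_slices(st))
        assert area == pytest.approx(2 * math.pi * 10 * 1.5, rel=0.005)

    def test_single_slice_insufficient(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        with pytest.raises(ValidationError, match="nsufficient"):
            triangulate_between_slices(ContourStack({0: [sq]}, "s", 1.0))

    def test_component_mismatch_matched_with_warning(self):
        sq = np.array([[0, 0], [4, 0], [4, 4], [0, 4], [0, 0]], float)
        far = sq + [20, 0]
        st = ContourStack({0: [sq], 1: [sq, far]}, "s", 1.0)
        with pytest.warns(UserWarning, match="mismatch"):
            surf = triangulate_between_slices(st)
        assert surface_area(surf) > 0

    def test_outward_winding_for_ccw_contours(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], float)
        surf = triangulate_between_slices(ContourStack({0: [sq], 1: [sq]}, "s", 1.0))
        v = surf.vertices[surf.faces]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        cen = v.mean(axis=1)
        outward = cen - [5.0, 0.5, 5.0]
        dots = np.einsum("ij,ij->i", n, outward)
        assert (dots > 0).all()


class TestSurfaceArea:
    def test_unit_square_two_triangles(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 1], [0, 0, 1]], float)
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        assert surface_area(TriangulatedSurface(verts, faces)) == pytest.approx(1.0)

    def test_scaling_law(self):
        verts = np.random.default_rng(0).normal(size=(30, 3))
        faces = np.arange(30).reshape(-1, 3)
        s1 = surface_area(TriangulatedSurface(verts, faces))
        s2 = surface_area(TriangulatedSurface(verts * 2, faces))
        assert s2 == pytest.approx(4 * s1, rel=1e-12)

    def test_total_surface_area_is_exact_sum(self):
        # published men/women medial and lateral component sums
        assert total_surface_area(620, 714, 440) == 1774
        assert total_surface_area(651, 746, 451) == 1848
        assert total_surface_area(0, 0, 0) == 0


class TestPartition:
    def test_channel_solid_partition_lengths(self):
        # constant-height channel over its cartilage: bottom/top spans match
        # the footprint width; both vertical walls face away from the
        # compartment centre, so the external surface carries both
        nx, nz = 9, 4
        lab = np.zeros((nx + 2, 4, nz + 2), dtype=np.int16)
        lab[1:nx + 1, 1:3, 1:nz + 1] = 3                      # MM
        lab[1:nx + 1, 1:3, 0:1] = 1                           # cartilage below
        seg = make_seg(lab, (1.0, 1.0, 1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ta, fa, ea = partition_meniscus_surface(seg, "medial", [1, 2])
        for iy in (1, 2):
            lt = sum(np.hypot(*np.diff(v, axis=0).T).sum()
                     for v in ta.slice_polylines(iy))
            lf = sum(np.hypot(*np.diff(v, axis=0).T).sum()
                     for v in fa.slice_polylines(iy))
            le = sum(np.hypot(*np.diff(v, axis=0).T).sum()
                     for v in ea.slice_polylines(iy))
            # 45-degree corner chamfers go to bottom/top by the tie rule, so
            # each wall loses half a voxel of length at each end
            assert lt == pytest.approx(nx, abs=1.0)
            assert lf == pytest.approx(nx, abs=1.0)
            assert le == pytest.approx(2 * (nz - 1), abs=1.0)

    def test_wedge_section_classification(self, fmed_params, fmed_seg_acq):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ta, fa, ea = partition_meniscus_surface(fmed_seg_acq, "medial")
        iys = ta.nonempty_slices()
        iy = iys[len(iys) // 2]
        assert ta.slice_polylines(iy) and fa.slice_polylines(iy)
        # tibial surface lies at the plateau plane, femoral strictly above
        zs_ta = np.concatenate([v[:, 1] for v in ta.slice_polylines(iy)])
        zs_fa = np.concatenate([v[:, 1] for v in fa.slice_polylines(iy)])
        assert zs_ta.max() <= zs_fa.max()
        assert zs_ta.min() == pytest.approx(0.0, abs=0.2)

    def test_prepartitioned_agrees_with_derived(self, fmed_params):
        from menmorph.phantom import voxelize_phantom

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            solid = voxelize_phantom(fmed_params, spacing=(0.15, 0.45, 0.15))
            pre = voxelize_phantom(fmed_params, spacing=(0.15, 0.45, 0.15),
                                   prepartition=True)
            a1 = meniscus_surface_areas(solid, "medial", None)
            a2 = meniscus_surface_areas(pre, "medial", None)
        for tag in ("TA", "FA", "EA"):
            assert a2[tag] == pytest.approx(a1[tag], rel=0.02), tag
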