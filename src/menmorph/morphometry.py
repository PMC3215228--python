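"""Size measures from a segmentation: contours, surfaces, areas, volume,
thickness and width.

The measurement chain mirrors a coronal slice-wise workflow: per-slice
sub-pixel boundary contours (marching squares at the 0.5 level of the binary
mask), restriction to slices on which both tibial cartilage and meniscus are
present, partition of the meniscus boundary into tibial (TA, inferior),
femoral (FA, superior) and external (EA, outer-rim) surfaces by outward
normal dominance, serial-section ribbon triangulation between adjacent slice
contours, and triangle-sum surface areas.  Volume is voxel-counted;
thickness is the z-extent of voxel columns; width is the in-slice x-extent
of the meniscus footprint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure as _skmeasure

from . import position as _position
from .segio import (CARTILAGE_LABEL, MENISCUS_LABEL, MeniscusRecord,
                    StructureMissingError, ValidationError, VoxelSegmentation)

__all__ = [
    "ContourStack", "TriangulatedSurface", "extract_slice_contours",
    "restrict_slice_range", "partition_meniscus_surface",
    "cartilage_surface_stack", "triangulate_between_slices", "surface_area",
    "partition_mesh_areas", "meniscus_surface_areas", "compartment_center",
    "total_surface_area", "meniscus_volume", "thickness_stats", "width_stats",
    "compute_morphometry", "classify_contour_segments", "polygon_area",
]


@dataclass
class ContourStack:
    """Ordered per-coronal-slice 2D polylines (x, z in mm) for one structure."""

    contours: dict[int, list[np.ndarray]]
    structure: str
    dy: float
    y_origin: float = 0.0

    def nonempty_slices(self) -> list[int]:
        return sorted(iy for iy, polys in self.contours.items() if polys)

    def slice_polylines(self, iy: int) -> list[np.ndarray]:
        return self.contours.get(iy, [])

    def y_mm(self, iy: int) -> float:
        return self.y_origin + iy * self.dy

    def restricted(self, slice_set) -> "ContourStack":
        keep = set(slice_set)
        return ContourStack({iy: p for iy, p in self.contours.items() if iy in keep},
                            self.structure, self.dy, self.y_origin)


@dataclass
class TriangulatedSurface:
    """Triangle mesh between adjacent slice contours, tagged by region."""

    vertices: np.ndarray            # (N, 3) mm
    faces: np.ndarray               # (M, 3) int
    region: str = ""

    def area(self) -> float:
        return surface_area(self)

    def export(self, path, file_type: str | None = None):
        """Write the mesh (PLY/OBJ) for visual inspection via trimesh."""
        import trimesh

        mesh = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        return mesh.export(path, file_type=file_type)


def polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a closed 2D polyline (last point may repeat)."""
    p = np.asarray(poly, dtype=float)
    if len(p) >= 2 and np.allclose(p[0], p[-1]):
        p = p[:-1]
    x, z = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(z, -1) - np.roll(x, -1) * z))


def extract_slice_contours(seg: VoxelSegmentation, structure) -> ContourStack:
    """Marching-squares boundaries of a structure's mask, per coronal slice.

    Contours are traced at the 0.5 level of the zero-padded binary mask with
    linear interpolation, i.e. the boundary passes midway between an inside
    and an outside voxel centre (a single voxel encloses 0.5 * dx * dz).
    Multiple components per slice are kept.  An empty structure yields an
    empty stack.
    """
    mask = seg.mask(structure)
    dx, dy, dz = seg.spacing
    x0, y0, z0 = seg.origin
    contours: dict[int, list[np.ndarray]] = {}
    name = structure if isinstance(structure, str) else "+".join(structure)
    for iy in range(seg.shape[1]):
        sl = mask[:, iy, :]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        polys = []
        for c in _skmeasure.find_contours(padded, 0.5):
            xy = np.column_stack(((c[:, 0] - 1.0) * dx + x0, (c[:, 1] - 1.0) * dz + z0))
            polys.append(xy)
        contours[iy] = polys
    return ContourStack(contours, name, dy, y0)


def restrict_slice_range(cartilage: ContourStack, meniscus: ContourStack) -> list[int]:
    """Slices on which BOTH the cartilage and the meniscus have contours.

    All downstream measures are evaluated on this restricted slice set only.
    Disjoint extents yield an empty set with a structured warning.
    """
    both = sorted(set(cartilage.nonempty_slices()) & set(meniscus.nonempty_slices()))
    if not both and cartilage.nonempty_slices() and meniscus.nonempty_slices():
        warnings.warn("cartilage and meniscus slice extents are disjoint; "
                      "restricted slice set is empty", stacklevel=2)
    return both


# ---------------------------------------------------------------------------
# boundary classification


def _ensure_ccw(poly: np.ndarray) -> np.ndarray:
    p = poly
    if len(p) >= 2 and np.allclose(p[0], p[-1]):
        p = p[:-1]
    if polygon_area(np.vstack([p, p[:1]])) < 0:
        p = p[::-1]
    return p


def classify_contour_segments(poly: np.ndarray, outward_sign: int | None = None,
                              center_x: float | None = None):
    """Split a closed (x, z) contour into runs tagged bottom/top/external/internal.

    Edge normals are taken outward (contour oriented counter-clockwise).
    Dominance rule: ``|nz| >= |nx|`` classifies an edge as bottom (nz < 0) or
    top (nz >= 0) — the tie at exactly 45 degrees thus prefers bottom/top
    over external.  x-dominant edges are external when the normal points away
    from the compartment centre — either away from ``center_x`` (the usual
    mode; a coronal section may show meniscus on both sides of the
    compartment centre, and both outer rims face away from it) or along a
    fixed ``outward_sign`` — and internal otherwise.  Internal runs attach to
    the nearer of bottom/top (by normal z-sign; purely horizontal internal
    normals split at the contour's mid height), so the meniscal inner rim is
    the bottom/top junction.

    Returns a list of ``(tag, vertices)`` with tag in
    {"bottom", "top", "external"}.
    """
    if (outward_sign is None) == (center_x is None):
        raise ValidationError("give exactly one of outward_sign / center_x")
    p = _ensure_ccw(np.asarray(poly, dtype=float))
    n = len(p)
    if n < 3:
        return []
    nxt = np.roll(p, -1, axis=0)
    t = nxt - p
    lengths = np.hypot(t[:, 0], t[:, 1])
    keep = lengths > 1e-12
    normals = np.column_stack((t[:, 1], -t[:, 0]))       # outward for CCW

    xmid_all = 0.5 * (p[:, 0] + nxt[:, 0])
    z_split = 0.5 * (p[:, 1].min() + p[:, 1].max())

    # tagged edge list (p_start, p_end, tag); purely vertical internal edges
    # crossing the mid height are split there so the lower part joins the
    # bottom surface and the upper part the top
    edges: list[tuple[np.ndarray, np.ndarray, str]] = []
    for i in range(n):
        if not keep[i]:
            continue
        nx_, nz_ = normals[i]
        a, b = p[i], nxt[i]
        # tolerance so exact 45-degree edges (ubiquitous on marching-squares
        # contours) classify as bottom/top despite floating-point noise
        if abs(nz_) >= abs(nx_) * (1.0 - 1e-9) - 1e-12:
            edges.append((a, b, "bottom" if nz_ < 0 else "top"))
            continue
        if center_x is not None:
            out_facing = nx_ * (xmid_all[i] - center_x) > 0
        else:
            out_facing = nx_ * outward_sign > 0
        if out_facing:
            edges.append((a, b, "external"))
        elif abs(nz_) > 1e-12:
            # internal face: attach to the nearer of bottom/top
            edges.append((a, b, "bottom" if nz_ < 0 else "top"))
        else:
            lo, hi = (a, b) if a[1] <= b[1] else (b, a)
            if lo[1] < z_split < hi[1]:
                mid = np.array([a[0], z_split])
                first, second = (("bottom", "top") if a[1] < b[1]
                                 else ("top", "bottom"))
                edges.append((a, mid, first))
                edges.append((mid, b, second))
            else:
                zm = 0.5 * (a[1] + b[1])
                edges.append((a, b, "bottom" if zm <= z_split else "top"))

    if not edges:
        return []
    # rotate so we start at a tag change, then group consecutive runs
    m = len(edges)
    start = next((k for k in range(m) if edges[k][2] != edges[k - 1][2]), 0)
    ordered = edges[start:] + edges[:start]
    out = []
    cur_tag = ordered[0][2]
    verts = [ordered[0][0], ordered[0][1]]
    for a, b, tag in ordered[1:]:
        if tag == cur_tag:
            verts.append(b)
        else:
            out.append((cur_tag, np.asarray(verts)))
            cur_tag, verts = tag, [a, b]
    out.append((cur_tag, np.asarray(verts)))
    return out


def partition_meniscus_surface(seg: VoxelSegmentation, compartment: str,
                               slice_set=None):
    """Split the meniscus boundary into TA / FA / EA contour stacks.

    With solid labels, classification is by outward-normal dominance (see
    :func:`classify_contour_segments`).  With pre-partitioned surface labels
    the stored labels are authoritative: each boundary edge is assigned to
    the surface of the nearest labelled shell voxel (pass-through mode).
    A slice whose boundary has no inferior-facing portion yields an empty TA
    for that slice with a warning.
    """
    men_name = MENISCUS_LABEL[compartment]
    if not seg.solid_mask(compartment).any():
        raise StructureMissingError(f"no {men_name} voxels in segmentation")
    stack = extract_slice_contours(seg, list(_solid_names(seg, compartment)))
    if slice_set is not None:
        stack = stack.restricted(slice_set)
    cx = compartment_center_x(seg, compartment)

    if seg.is_prepartitioned(compartment):
        return _partition_prepartitioned(seg, stack, men_name)

    ta: dict[int, list] = {}
    fa: dict[int, list] = {}
    ea: dict[int, list] = {}
    for iy in stack.nonempty_slices():
        ta.setdefault(iy, []), fa.setdefault(iy, []), ea.setdefault(iy, [])
        for poly in stack.slice_polylines(iy):
            for tag, verts in classify_contour_segments(poly, center_x=cx):
                {"bottom": ta, "top": fa, "external": ea}[tag][iy].append(verts)
        if not ta[iy]:
            warnings.warn(f"slice {iy}: meniscus boundary has no inferior-facing "
                          "portion; TA empty on this slice", stacklevel=2)
    mk = lambda d, s: ContourStack(d, s, stack.dy, stack.y_origin)
    return mk(ta, f"{men_name}_TA"), mk(fa, f"{men_name}_FA"), mk(ea, f"{men_name}_EA")


def _solid_names(seg: VoxelSegmentation, compartment: str):
    from .segio import SOLID_GROUPS
    return SOLID_GROUPS[MENISCUS_LABEL[compartment]]


def compartment_center(seg: VoxelSegmentation, compartment: str) -> tuple[float, float]:
    """World (x, y) of the compartment centre: the centroid of its tibial
    cartilage (falling back to the meniscus solid when absent)."""
    mask = seg.mask(CARTILAGE_LABEL[compartment])
    if not mask.any():
        mask = seg.solid_mask(compartment)
    ix, iy, _ = np.nonzero(mask)
    return (seg.origin[0] + float(ix.mean()) * seg.spacing[0],
            seg.origin[1] + float(iy.mean()) * seg.spacing[1])


def compartment_center_x(seg: VoxelSegmentation, compartment: str) -> float:
    return compartment_center(seg, compartment)[0]


def _partition_prepartitioned(seg: VoxelSegmentation, stack: ContourStack, men_name: str):
    from scipy.spatial import cKDTree

    dx, dz = seg.spacing[0], seg.spacing[2]
    x0, z0 = seg.origin[0], seg.origin[2]
    out = {"TA": {}, "FA": {}, "EA": {}}
    for iy in stack.nonempty_slices():
        trees = {}
        for surf in ("TA", "FA", "EA"):
            m = seg.mask(f"{men_name}_{surf}")[:, iy, :]
            pts = np.column_stack(np.nonzero(m)).astype(float)
            if len(pts):
                pts = np.column_stack((pts[:, 0] * dx + x0, pts[:, 1] * dz + z0))
                trees[surf] = cKDTree(pts)
        for k in out:
            out[k].setdefault(iy, [])
        if not trees:
            continue
        surfs = list(trees)
        for poly in stack.slice_polylines(iy):
            p = _ensure_ccw(poly)
            mids = 0.5 * (p + np.roll(p, -1, axis=0))
            dists = np.stack([trees[s].query(mids)[0] for s in surfs])
            tags = [surfs[k] for k in np.argmin(dists, axis=0)]
            # group consecutive edges sharing a tag, wrapping
            n = len(p)
            start = next((i for i in range(n) if tags[i] != tags[i - 1]), 0)
            order = list(range(start, n)) + list(range(start))
            cur, edges = tags[order[0]], [order[0]]
            runs = []
            for i in order[1:]:
                if tags[i] == cur:
                    edges.append(i)
                else:
                    runs.append((cur, edges))
                    cur, edges = tags[i], [i]
            runs.append((cur, edges))
            nxt = np.roll(p, -1, axis=0)
            for tag, es in runs:
                verts = [p[es[0]]] + [nxt[e] for e in es]
                out[tag][iy].append(np.asarray(verts))
    mk = lambda d, s: ContourStack(d, s, stack.dy, stack.y_origin)
    return (mk(out["TA"], f"{men_name}_TA"), mk(out["FA"], f"{men_name}_FA"),
            mk(out["EA"], f"{men_name}_EA"))


def cartilage_surface_stack(seg: VoxelSegmentation, compartment: str,
                            slice_set=None) -> ContourStack:
    """Superior (articular) surface of the tibial cartilage slab as contours."""
    name = CARTILAGE_LABEL[compartment]
    if not seg.has_structure(name):
        raise StructureMissingError(f"no {name} voxels in segmentation")
    stack = extract_slice_contours(seg, name)
    if slice_set is not None:
        stack = stack.restricted(slice_set)
    cx = compartment_center_x(seg, compartment)
    top: dict[int, list] = {}
    for iy in stack.nonempty_slices():
        top[iy] = []
        for poly in stack.slice_polylines(iy):
            for tag, verts in classify_contour_segments(poly, center_x=cx):
                if tag == "top":
                    top[iy].append(verts)
    return ContourStack(top, f"{name}_surface", stack.dy, stack.y_origin)


# ---------------------------------------------------------------------------
# serial-section triangulation


def _is_closed(poly: np.ndarray) -> bool:
    return len(poly) >= 4 and np.allclose(poly[0], poly[-1])


#: Half-window (mm) of the staircase filter applied to contours entering the
#: surface-area triangulation.  Marching squares on a binary mask yields
#: axis/diagonal micro-edges whose path length overestimates slanted
#: boundaries by several percent; averaging each vertex with its neighbours
#: within a fixed sub-millimetre arc length removes that bias while moving no
#: vertex by more than a fraction of a voxel.  At voxel pitches at or above
#: the window the filter degenerates to the identity.
STAIRCASE_HALF_WINDOW_MM = 0.25


def smooth_contour(poly: np.ndarray,
                   half_window: float = STAIRCASE_HALF_WINDOW_MM) -> np.ndarray:
    """Average polyline vertices within ``half_window`` mm of arc length.

    Closed polylines wrap; open polylines keep their endpoints fixed (they
    are split points shared with adjacent surface regions).
    """
    closed = _is_closed(poly)
    p = poly[:-1] if closed else poly
    n = len(p)
    if n < 5 or half_window <= 0:
        return poly
    out = np.empty_like(p)
    for i in range(n):
        acc_pts = [p[i]]
        for d in (1, -1):
            acc = 0.0
            j = i
            while True:
                nj = (j + d) % n if closed else j + d
                if not closed and not 0 <= nj < n:
                    break
                acc += float(np.hypot(*(p[nj] - p[j])))
                if acc > half_window or (closed and nj == i):
                    break
                acc_pts.append(p[nj])
                j = nj
        out[i] = np.mean(acc_pts, axis=0)
    if not closed:
        out[0], out[-1] = p[0], p[-1]
        return out
    return np.vstack([out, out[:1]])


def _ribbon(a: np.ndarray, b: np.ndarray, ya: float, yb: float,
            allow_reverse: bool = True):
    """Greedy shortest-diagonal triangle ribbon between two polylines.

    ``a`` and ``b`` are (N, 2) arrays of (x, z) with ``ya < yb``; the result
    is a list of 3D triangles.  Closed polylines (first == last vertex) are
    re-oriented counter-clockwise and stitched around the full loop; open
    polylines are aligned end-to-end (reversing ``b`` when that shortens the
    end-point matching, unless ``allow_reverse`` is off to preserve an
    inherited orientation).  Triangle vertices are ordered so that, for
    counter-clockwise input, every face normal points out of the solid —
    downstream surface classification relies on this.
    """
    closed = _is_closed(a) and _is_closed(b)
    pa = a[:-1] if _is_closed(a) else a
    pb = b[:-1] if _is_closed(b) else b
    pa, pb = np.asarray(pa, float), np.asarray(pb, float)
    if closed:
        if polygon_area(np.vstack([pa, pa[:1]])) < 0:
            pa = pa[::-1]
        if polygon_area(np.vstack([pb, pb[:1]])) < 0:
            pb = pb[::-1]
        # rotate b so its start is nearest a's start
        j0 = int(np.argmin(np.sum((pb - pa[0]) ** 2, axis=1)))
        pb = np.roll(pb, -j0, axis=0)
        ia = list(range(len(pa))) + [0]
        ib = list(range(len(pb))) + [0]
    else:
        if allow_reverse:
            same = np.linalg.norm(pa[0] - pb[0]) + np.linalg.norm(pa[-1] - pb[-1])
            flip = np.linalg.norm(pa[0] - pb[-1]) + np.linalg.norm(pa[-1] - pb[0])
            if flip < same:
                pb = pb[::-1]
        ia = list(range(len(pa)))
        ib = list(range(len(pb)))

    A = np.column_stack((pa[:, 0], np.full(len(pa), ya), pa[:, 1]))
    B = np.column_stack((pb[:, 0], np.full(len(pb), yb), pb[:, 1]))

    def _params(P, idx):
        d = np.linalg.norm(np.diff(P[idx], axis=0), axis=1)
        s = np.r_[0.0, np.cumsum(d)]
        return s / s[-1] if s[-1] > 0 else s

    ua, ub = _params(A, ia), _params(B, ib)
    tris = []
    i = j = 0
    ni, nj = len(ia) - 1, len(ib) - 1
    while i < ni or j < nj:
        adv_a = i < ni
        adv_b = j < nj
        if adv_a and adv_b:
            # advance the side lagging in normalized arc length, breaking
            # ties by the shorter new diagonal
            if abs(ua[i + 1] - ub[j + 1]) > 1e-12:
                adv_a = ua[i + 1] < ub[j + 1]
            else:
                da = np.linalg.norm(A[ia[i + 1]] - B[ib[j]])
                db = np.linalg.norm(B[ib[j + 1]] - A[ia[i]])
                adv_a = da <= db
        if adv_a:
            tris.append((A[ia[i]], B[ib[j]], A[ia[i + 1]]))
            i += 1
        else:
            tris.append((A[ia[i]], B[ib[j]], B[ib[j + 1]]))
            j += 1
    return tris


def _longest_run(poly: np.ndarray, inside: np.ndarray) -> np.ndarray:
    best = (0, 0)
    start = None
    for k, flag in enumerate(list(inside) + [False]):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            if k - start > best[1] - best[0]:
                best = (start, k)
            start = None
    return poly[best[0]:best[1]]


def _clip_to_xrange(poly: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Contiguous portion of a polyline with x in [lo, hi].

    Closed polylines are rotated so the clipped run is contiguous (and
    returned unchanged, still closed, when nothing is clipped); open
    polylines keep their longest in-range run.  Vertex order — hence
    inherited orientation — is preserved.
    """
    if _is_closed(poly):
        p = poly[:-1]
        inside = (p[:, 0] >= lo) & (p[:, 0] <= hi)
        if inside.all():
            return poly
        k0 = int(np.argmin(inside))        # first outside vertex
        p = np.roll(p, -k0, axis=0)
        inside = np.roll(inside, -k0)
        return _longest_run(p, inside)
    inside = (poly[:, 0] >= lo) & (poly[:, 0] <= hi)
    return _longest_run(poly, inside)


def _cut_closed_near(closed_poly: np.ndarray, open_piece: np.ndarray) -> np.ndarray:
    """Open a closed polyline at the vertex nearest the open piece's start,
    so that two counter-clockwise pieces march in step."""
    p = closed_poly[:-1]
    k = int(np.argmin(np.sum((p - open_piece[0]) ** 2, axis=1)))
    return np.roll(p, -k, axis=0)


def _overlap_pairs(polys_a, polys_b):
    """Pair components of adjacent slices by x-footprint overlap.

    Components that overlap in x correspond; a component matching several
    partners (a body splitting in two where the inner-rim hole opens) is
    tiled at the x-midpoints between its partners so no part of a contour
    is ribboned twice.  Components with no overlap at all attach to the
    nearest-centroid partner.  Returns the pair index list and the
    (possibly clipped/opened) polyline pairs to ribbon.
    """
    ra = [(p[:, 0].min(), p[:, 0].max()) for p in polys_a]
    rb = [(p[:, 0].min(), p[:, 0].max()) for p in polys_b]
    pairs = [(i, j) for i in range(len(polys_a)) for j in range(len(polys_b))
             if min(ra[i][1], rb[j][1]) - max(ra[i][0], rb[j][0]) > 0]
    cen_a = [p.mean(axis=0) for p in polys_a]
    cen_b = [p.mean(axis=0) for p in polys_b]
    for i in set(range(len(polys_a))) - {i for i, _ in pairs}:
        j = int(np.argmin([np.sum((c - cen_a[i]) ** 2) for c in cen_b]))
        pairs.append((i, j))
    for j in set(range(len(polys_b))) - {j for _, j in pairs}:
        i = int(np.argmin([np.sum((c - cen_b[j]) ** 2) for c in cen_a]))
        pairs.append((i, j))
    # a component claimed by several partners is tiled by cutting at the x
    # midpoints between adjacent partners' footprints (no gap, no overlap)
    def _cut_bounds(partner_ranges, j):
        order = sorted(range(len(partner_ranges)), key=lambda k: partner_ranges[k][0])
        pos = order.index(j)
        lo = -np.inf if pos == 0 else 0.5 * (partner_ranges[order[pos - 1]][1]
                                             + partner_ranges[order[pos]][0])
        hi = np.inf if pos == len(order) - 1 else 0.5 * (
            partner_ranges[order[pos]][1] + partner_ranges[order[pos + 1]][0])
        return lo, hi

    partners_of_a = {i: [j for i2, j in pairs if i2 == i] for i, _ in pairs}
    partners_of_b = {j: [i for i, j2 in pairs if j2 == j] for _, j in pairs}
    clipped = []
    for i, j in sorted(pairs):
        a, b = polys_a[i], polys_b[j]
        was_cut = False
        if len(partners_of_a[i]) > 1:
            prs = [rb[k] for k in partners_of_a[i]]
            lo, hi = _cut_bounds(prs, partners_of_a[i].index(j))
            a = _clip_to_xrange(_ccw(a), lo, hi)
            was_cut = True
        if len(partners_of_b[j]) > 1:
            prs = [ra[k] for k in partners_of_b[j]]
            lo, hi = _cut_bounds(prs, partners_of_b[j].index(i))
            b = _clip_to_xrange(_ccw(b), lo, hi)
            was_cut = True
        if len(a) < 2 or len(b) < 2:
            continue
        if _is_closed(a) and not _is_closed(b):
            a = _cut_closed_near(_ccw(a), b)
            was_cut = True
        elif _is_closed(b) and not _is_closed(a):
            b = _cut_closed_near(_ccw(b), a)
            was_cut = True
        # pieces cut from counter-clockwise parents keep that orientation;
        # reversing one side would flip the outward winding of the ribbon
        clipped.append((a, b, not was_cut))
    return sorted(pairs), clipped


def _ccw(poly: np.ndarray) -> np.ndarray:
    if not _is_closed(poly):
        return poly
    if polygon_area(poly) < 0:
        return poly[::-1]
    return poly


def triangulate_between_slices(stack: ContourStack, region: str = "") -> TriangulatedSurface:
    """Connect adjacent slice contours into a triangle ribbon surface.

    Components on adjacent slices correspond by nearest centroid (unmatched
    components attach to their nearest neighbour with a warning); within a
    matched pair, triangles advance greedily along the shorter diagonal.
    The anterior-most and posterior-most contours are left uncapped, since a
    coronal slice stack truncates the meniscal horns anyway.
    """
    slices = stack.nonempty_slices()
    if len(slices) < 2:
        raise ValidationError("insufficient slices for triangulation (need >= 2)")
    all_tris = []
    n_mismatched = 0
    for s0, s1 in zip(slices[:-1], slices[1:]):
        polys_a = stack.slice_polylines(s0)
        polys_b = stack.slice_polylines(s1)
        ya, yb = stack.y_mm(s0), stack.y_mm(s1)
        pairs, clipped = _overlap_pairs(polys_a, polys_b)
        if len(polys_a) != len(polys_b):
            n_mismatched += 1
        for a, b, may_reverse in clipped:
            if len(a) >= 2 and len(b) >= 2:
                all_tris.extend(_ribbon(a, b, ya, yb, allow_reverse=may_reverse))
    if n_mismatched:
        warnings.warn(f"{region or stack.structure}: component count mismatch on "
                      f"{n_mismatched} adjacent slice pair(s); matched by footprint "
                      "overlap / nearest centroid", stacklevel=2)
    verts = np.asarray(all_tris, dtype=float).reshape(-1, 3)
    faces = np.arange(len(verts)).reshape(-1, 3)
    return TriangulatedSurface(verts, faces, region=region)


def surface_area(surface: TriangulatedSurface) -> float:
    """Sum of triangle areas by the cross-product formula (mm^2)."""
    v = surface.vertices[surface.faces]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def partition_mesh_areas(surface: TriangulatedSurface,
                         center_xy: tuple[float, float]) -> dict[str, float]:
    """TA/FA/EA areas of a whole-meniscus mesh by 3D normal dominance.

    Per triangle: with outward unit normal ``n`` and the outward radial
    direction ``rhat`` from the compartment centre axis at the triangle
    centroid, z-dominant triangles (``|n_z| >= |n . rhat|``, ties included)
    are tibial (``n_z < 0``) or femoral surface; radially-dominant outward
    triangles are external surface; radially-dominant inward (inner-rim)
    triangles attach to the nearer of TA/FA by z-sign.  Classifying in 3D —
    rather than from in-slice edge normals — keeps surface nearly tangent to
    the slice planes (the antero-posterior ends of the outer rim) correctly
    assigned to the external surface.

    The ribbon builder emits consistently outward-wound triangles for
    counter-clockwise slice contours, so face normals are trusted as
    outward directly.
    """
    v = surface.vertices[surface.faces]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    ok = areas > 1e-12
    n = np.zeros_like(cross)
    n[ok] = cross[ok] / (2.0 * areas[ok, None])

    cen = v.mean(axis=1)
    rad = cen[:, :2] - np.asarray(center_xy)
    rnorm = np.maximum(np.linalg.norm(rad, axis=1), 1e-12)
    rhat = rad / rnorm[:, None]
    z_mid = 0.5 * (surface.vertices[:, 2].min() + surface.vertices[:, 2].max())

    n_r = n[:, 0] * rhat[:, 0] + n[:, 1] * rhat[:, 1]
    n_z = n[:, 2]
    zdom = np.abs(n_z) >= np.abs(n_r) * (1.0 - 1e-9) - 1e-12
    below = cen[:, 2] <= z_mid
    tag_ta = ok & (zdom & (n_z < 0) |
                   ~zdom & (n_r <= 0) & ((n_z < -1e-12) | ((np.abs(n_z) <= 1e-12) & below)))
    tag_ea = ok & ~zdom & (n_r > 0)
    tag_fa = ok & ~tag_ta & ~tag_ea
    return {"TA": float(areas[tag_ta].sum()),
            "FA": float(areas[tag_fa].sum()),
            "EA": float(areas[tag_ea].sum())}


def meniscus_surface_areas(seg: VoxelSegmentation, compartment: str,
                           slice_set) -> dict[str, float]:
    """TA/FA/EA areas from the whole-meniscus serial-section mesh.

    The meniscus solid contours are ribbon-triangulated as one closed
    surface (uncapped at the anterior/posterior ends) and the triangles
    partitioned by 3D normal dominance; with pre-partitioned surface labels
    the triangles are instead assigned to the nearest labelled shell voxel.
    """
    stack = extract_slice_contours(seg, list(_solid_names(seg, compartment)))
    if slice_set is not None:
        stack = stack.restricted(slice_set)
    stack = ContourStack(
        {iy: [smooth_contour(p) for p in stack.slice_polylines(iy)]
         for iy in stack.nonempty_slices()},
        stack.structure, stack.dy, stack.y_origin)
    surf = triangulate_between_slices(stack, region="meniscus")
    if seg.is_prepartitioned(compartment):
        return _mesh_areas_from_labels(seg, surf, MENISCUS_LABEL[compartment])
    return partition_mesh_areas(surf, compartment_center(seg, compartment))


def _mesh_areas_from_labels(seg: VoxelSegmentation, surf: TriangulatedSurface,
                            men_name: str) -> dict[str, float]:
    from scipy.spatial import cKDTree

    v = surf.vertices[surf.faces]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    cen = v.mean(axis=1)
    spacing = np.asarray(seg.spacing)
    origin = np.asarray(seg.origin)
    dists, out = [], {}
    surfs = []
    for tag in ("TA", "FA", "EA"):
        m = seg.mask(f"{men_name}_{tag}")
        pts = np.column_stack(np.nonzero(m)).astype(float) * spacing + origin
        if len(pts):
            surfs.append(tag)
            dists.append(cKDTree(pts).query(cen)[0])
    if not surfs:
        raise StructureMissingError(f"no {men_name} surface sub-labels present")
    choice = np.argmin(np.stack(dists), axis=0)
    return {tag: float(areas[choice == k].sum()) if tag in surfs else 0.0
            for tag in ("TA", "FA", "EA")
            for k in [surfs.index(tag) if tag in surfs else -1]}


def total_surface_area(ta: float, fa: float, ea: float) -> float:
    """TOT A, the sum of the three meniscal surfaces."""
    return ta + fa + ea


# ---------------------------------------------------------------------------
# voxel-based size measures


def meniscus_volume(seg: VoxelSegmentation, compartment: str, slice_set) -> float:
    """Voxel-counted meniscus volume (mm^3) within the restricted slices."""
    if not slice_set:
        return 0.0
    mask = seg.solid_mask(compartment)[:, sorted(slice_set), :]
    return float(mask.sum()) * seg.voxel_volume


def thickness_stats(seg: VoxelSegmentation, compartment: str, slice_set):
    """(Th_Me, Th_Max): per-column z-extent of the meniscus, mean and max.

    Columns run along z (thickness = meniscal height); the mean is over
    columns that intersect the meniscus at all.
    """
    if not slice_set:
        return math.nan, math.nan
    mask = seg.solid_mask(compartment)[:, sorted(slice_set), :]
    counts = mask.sum(axis=2).astype(float)
    occupied = counts > 0
    if not occupied.any():
        return math.nan, math.nan
    th = counts[occupied] * seg.spacing[2]
    return float(th.mean()), float(th.max())


def width_stats(meniscus_contours: ContourStack, slice_set, side: str | None = None):
    """(Wid_Me, Wid_Max): per-slice total x-extent of the meniscus footprint.

    The extent runs from the external-most to the internal-most boundary
    point across all components of the slice; ``side`` is accepted for
    signature symmetry but the extent is side-independent.
    """
    widths = []
    keep = set(slice_set)
    for iy in meniscus_contours.nonempty_slices():
        if iy not in keep:
            continue
        xs = np.concatenate([p[:, 0] for p in meniscus_contours.slice_polylines(iy)])
        widths.append(float(xs.max() - xs.min()))
    if not widths:
        return math.nan, math.nan
    return float(np.mean(widths)), float(np.max(widths))


# ---------------------------------------------------------------------------
# orchestration


def compute_morphometry(seg: VoxelSegmentation, compartment: str,
                        subject_meta: dict | None = None) -> MeniscusRecord:
    """Run the full measurement chain for one compartment.

    Steps: contour extraction, slice restriction, surface partition,
    triangulation and areas, voxel volume, thickness, width, then the
    position metrics (extrusion, coverage, uncovered TA, overlap distance).
    Returns a validated :class:`MeniscusRecord`.
    """
    meta = subject_meta or {}
    cart_name = CARTILAGE_LABEL[compartment]
    if not seg.has_structure(cart_name):
        raise StructureMissingError(f"no {cart_name} voxels in segmentation")
    if not seg.solid_mask(compartment).any():
        raise StructureMissingError(
            f"no {MENISCUS_LABEL[compartment]} voxels in segmentation")

    cart_stack = extract_slice_contours(seg, cart_name)
    men_stack = extract_slice_contours(seg, list(_solid_names(seg, compartment)))
    slice_set = restrict_slice_range(cart_stack, men_stack)
    if len(slice_set) < 2:
        raise ValidationError("fewer than 2 slices contain both cartilage and meniscus")

    ta_stack, fa_stack, ea_stack = partition_meniscus_surface(seg, compartment, slice_set)
    ac_stack = cartilage_surface_stack(seg, compartment, slice_set)

    areas = meniscus_surface_areas(seg, compartment, slice_set)
    ta, fa, ea = areas["TA"], areas["FA"], areas["EA"]
    acdab = surface_area(triangulate_between_slices(ac_stack, "ACdAB"))
    tot = total_surface_area(ta, fa, ea)

    vol = meniscus_volume(seg, compartment, slice_set)
    th_me, th_max = thickness_stats(seg, compartment, slice_set)
    wid_me, wid_max = width_stats(men_stack, slice_set)

    side = compartment
    margins = _position.compute_margins(cart_stack, ta_stack, fa_stack, side, slice_set)
    ex_me, ex_max = _position.extrusion_stats(margins)
    ovd_me, ovd_max = _position.overlap_distance_stats(margins)
    cart_fp = _position.footprint_intervals(cart_stack, slice_set)
    ta_fp = _position.footprint_intervals(ta_stack, slice_set)
    cov, covp = _position.coverage(cart_fp, ta_fp, slice_set, seg.spacing[1])
    unc, uncp = _position.uncovered_ta(cart_fp, ta_fp, slice_set, seg.spacing[1])

    record = MeniscusRecord(
        subject_id=str(meta.get("subject_id", "phantom")),
        compartment=compartment,
        sex=meta.get("sex"), age=meta.get("age"),
        height=meta.get("height"), weight=meta.get("weight"),
        ACdAB=acdab, TA=ta, FA=fa, EA=ea, TOT_A=tot,
        TOTA_over_ACdAB=tot / acdab if acdab > 0 else math.nan,
        V=vol, Th_Me=th_me, Th_Max=th_max, Wid_Me=wid_me, Wid_Max=wid_max,
        TA_Uncov=unc, TA_Uncovp=uncp, ACdAB_Cov=cov, ACdAB_Covp=covp,
        Ex_Me=ex_me, Ex_Max=ex_max, OvD_Me=ovd_me, OvD_Max=ovd_max,
    )
    record.validate()
    return record
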