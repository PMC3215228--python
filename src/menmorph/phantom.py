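"""Parametric tibia + meniscus phantoms with closed-form ground truth.

The phantom is a validation instrument, not an anatomical model.  Per
compartment it consists of

* a flat elliptical tibial plateau (the ACdAB region) at ``z = 0`` — realised
  as a thin slab just below ``z = 0`` so that it has voxels, its superior
  surface being the plateau;
* a meniscus shaped as an annular wedge: in polar coordinates around the
  plateau centre the solid occupies ``phi in [phi0, phi0 + theta]``,
  ``r in [R - w, R]``, with a flat bottom at ``z = 0``, a vertical outer wall
  at ``r = R`` and a top surface whose height rises linearly from 0 at the
  inner rim to ``h`` at the outer rim: ``z(r) = h * (r - (R - w)) / w``.

Every measure of the measurement pipeline then has a closed form or a cheap
one-dimensional-integral oracle:

========  =====================================================
ACdAB     ``pi * a * b``
TA        ``theta * w * (R - w/2)``          (flat bottom)
EA        ``theta * R * h``                  (outer cylindrical wall)
FA        ``sqrt(1 + (h/w)**2) * TA``        (slanted top)
V         ``theta * h * w * (w/3 + (R - w)/2)``
Th.Me     ``V / TA``;  Th.Max = ``h``
extrusion ``delta = R - a`` at the central slice (circular plateau)
========  =====================================================

Signed radial offset ``delta``: positive means the meniscus outer rim lies
beyond the plateau rim (extruded), negative means it lies inside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import ACQUISITION_SPACING, REFERENCE
from .segio import DEFAULT_LABEL_MAP, ValidationError, VoxelSegmentation

__all__ = [
    "PhantomParams", "GroundTruthMorphometry", "analytic_morphometry",
    "restricted_ground_truth", "restricted_plateau_area", "restricted_y_range",
    "meniscus_y_extent", "analytic_coverage_percent", "voxelize_phantom",
    "voxelize_knee", "preset_params", "write_ground_truth_csv", "PRESETS",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry of one compartment phantom (all lengths in mm, angles rad)."""

    plateau_semi_axis_x: float = 17.5
    plateau_semi_axis_y: float = 17.5
    outer_radius: float = 19.0          # R, meniscus outer rim
    radial_width: float = 9.0           # w, outer minus inner rim radius
    peak_height: float = 7.0            # h, wedge height at the outer rim
    arc_start: float = math.pi / 4      # phi0
    arc_span: float = 1.5 * math.pi     # theta
    compartment: str = "medial"
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("plateau_semi_axis_x", "plateau_semi_axis_y",
                     "outer_radius", "radial_width", "peak_height"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 < self.arc_span <= 2 * math.pi + 1e-12:
            raise ValidationError("arc_span must lie in (0, 2*pi]")
        if self.radial_width >= self.outer_radius:
            raise ValidationError("radial_width must be smaller than outer_radius")
        if self.compartment not in ("medial", "lateral"):
            raise ValidationError("compartment must be 'medial' or 'lateral'")

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.radial_width

    def plateau_radius(self, phi: float | np.ndarray) -> np.ndarray:
        """Plateau rim radius along direction ``phi`` (ellipse polar form)."""
        a, b = self.plateau_semi_axis_x, self.plateau_semi_axis_y
        return a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)

    @property
    def mid_angle(self) -> float:
        return self.arc_start + self.arc_span / 2.0

    @property
    def radial_offset(self) -> float:
        """Signed offset of the meniscus outer rim beyond the plateau rim.

        Evaluated along the mid-arc direction; for a circular plateau this is
        simply ``R - a`` everywhere along the arc.
        """
        return self.outer_radius - float(self.plateau_radius(self.mid_angle))

    @property
    def outward_sign(self) -> int:
        """+1 if the external direction of this compartment is +x, else -1."""
        return -1 if self.compartment == "medial" else +1

    def scaled(self, s: float) -> "PhantomParams":
        """Uniformly scale every length by ``s`` (angles unchanged)."""
        return PhantomParams(
            plateau_semi_axis_x=self.plateau_semi_axis_x * s,
            plateau_semi_axis_y=self.plateau_semi_axis_y * s,
            outer_radius=self.outer_radius * s,
            radial_width=self.radial_width * s,
            peak_height=self.peak_height * s,
            arc_start=self.arc_start,
            arc_span=self.arc_span,
            compartment=self.compartment,
            center=(self.center[0] * s, self.center[1] * s),
        )


@dataclass
class GroundTruthMorphometry:
    """Ground-truth counterparts of the pipeline's size measures."""

    ACdAB: float
    TA: float
    FA: float
    EA: float
    TOT_A: float
    V: float
    Th_Me: float
    Th_Max: float
    radial_extrusion: float
    #: which fields are exact closed forms vs numeric 1D-integral oracles
    analytic_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert abs(self.TOT_A - (self.TA + self.FA + self.EA)) <= 1e-9 * max(1.0, self.TOT_A)
        assert self.Th_Max >= self.Th_Me - 1e-12


def analytic_morphometry(params: PhantomParams) -> GroundTruthMorphometry:
    """Closed-form morphometry of the full (unrestricted) phantom."""
    a, b = params.plateau_semi_axis_x, params.plateau_semi_axis_y
    R, w, h, th = params.outer_radius, params.radial_width, params.peak_height, params.arc_span
    ta = th * w * (R - w / 2.0)
    ea = th * R * h
    fa = math.sqrt(1.0 + (h / w) ** 2) * ta
    v = th * h * w * (w / 3.0 + (R - w) / 2.0)
    return GroundTruthMorphometry(
        ACdAB=math.pi * a * b,
        TA=ta, FA=fa, EA=ea, TOT_A=ta + fa + ea,
        V=v, Th_Me=v / ta, Th_Max=h,
        radial_extrusion=params.radial_offset,
        analytic_flags={k: "closed-form" for k in
                        ("ACdAB", "TA", "FA", "EA", "TOT_A", "V", "Th_Me", "Th_Max",
                         "radial_extrusion")},
    )


def _phi_radial_interval(params: PhantomParams, phi: np.ndarray,
                         y_lo: float, y_hi: float):
    """Per-angle admissible radial interval of the meniscus footprint
    restricted to slices ``y in [y_lo, y_hi]`` (y relative to the centre)."""
    R, r_in = params.outer_radius, params.inner_radius
    s = np.sin(phi)
    lo = np.full_like(phi, r_in)
    hi = np.full_like(phi, float(R))
    pos = s > 1e-12
    neg = s < -1e-12
    zero = ~pos & ~neg
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = np.where(pos, np.maximum(lo, y_lo / np.where(pos, s, 1.0)), lo)
        hi = np.where(pos, np.minimum(hi, y_hi / np.where(pos, s, 1.0)), hi)
        lo = np.where(neg, np.maximum(lo, y_hi / np.where(neg, s, 1.0)), lo)
        hi = np.where(neg, np.minimum(hi, y_lo / np.where(neg, s, 1.0)), hi)
    empty_zero = zero & ~((y_lo <= 0.0) & (0.0 <= y_hi))
    hi = np.where(empty_zero, lo, hi)
    ok = hi > lo
    return np.where(ok, lo, r_in), np.where(ok, hi, r_in), ok


def restricted_plateau_area(params: PhantomParams, y_lo: float, y_hi: float,
                            n: int = 20001) -> float:
    """Elliptical plateau area within slices ``y in [y_lo, y_hi]`` (centre-relative)."""
    a, b = params.plateau_semi_axis_x, params.plateau_semi_axis_y
    y = np.linspace(max(y_lo, -b), min(y_hi, b), n)
    if y[-1] <= y[0]:
        return 0.0
    chord = 2.0 * a * np.sqrt(np.clip(1.0 - (y / b) ** 2, 0.0, None))
    return float(np.trapezoid(chord, y))


def restricted_ground_truth(params: PhantomParams, y_lo: float, y_hi: float,
                            n_phi: int = 40001) -> GroundTruthMorphometry:
    """Ground truth restricted to coronal slices ``y in [y_lo, y_hi]``
    (both bounds relative to the phantom centre).

    The measurement pipeline only uses slices on which both the tibial
    cartilage and the meniscus are present; this oracle integrates the closed
    per-angle forms of every measure over that restricted footprint
    (trapezoid rule over ``n_phi`` angles), exact up to quadrature error.
    The plateau area is likewise restricted.
    """
    R, w, h = params.outer_radius, params.radial_width, params.peak_height
    r_in = params.inner_radius
    phi = np.linspace(params.arc_start, params.arc_start + params.arc_span, n_phi)
    lo, up, ok = _phi_radial_interval(params, phi, y_lo, y_hi)

    ta = np.trapezoid(np.where(ok, (up ** 2 - lo ** 2) / 2.0, 0.0), phi)

    def vol_prim(r):
        return (h / w) * (r ** 3 / 3.0 - r_in * r ** 2 / 2.0)

    v = np.trapezoid(np.where(ok, vol_prim(up) - vol_prim(lo), 0.0), phi)
    y_wall = R * np.sin(phi)
    ea = R * h * np.trapezoid(((y_wall >= y_lo) & (y_wall <= y_hi)).astype(float), phi)
    fa = math.sqrt(1.0 + (h / w) ** 2) * ta
    acdab = restricted_plateau_area(params, y_lo, y_hi)
    flags = {k: "numeric-oracle" for k in
             ("ACdAB", "TA", "FA", "EA", "TOT_A", "V", "Th_Me")}
    flags.update({"Th_Max": "closed-form", "radial_extrusion": "closed-form"})
    return GroundTruthMorphometry(
        ACdAB=acdab, TA=float(ta), FA=float(fa), EA=float(ea),
        TOT_A=float(ta + fa + ea), V=float(v),
        Th_Me=float(v / ta) if ta > 0 else 0.0, Th_Max=h,
        radial_extrusion=params.radial_offset, analytic_flags=flags,
    )


def meniscus_y_extent(params: PhantomParams) -> tuple[float, float]:
    """Centre-relative antero-posterior extent of the meniscus footprint."""
    phi = np.linspace(params.arc_start, params.arc_start + params.arc_span, 40001)
    y = np.concatenate([params.outer_radius * np.sin(phi),
                        params.inner_radius * np.sin(phi)])
    return float(y.min()), float(y.max())


def restricted_y_range(params: PhantomParams) -> tuple[float, float]:
    """Centre-relative y-range of slices carrying both plateau and meniscus."""
    b = params.plateau_semi_axis_y
    m_lo, m_hi = meniscus_y_extent(params)
    return max(-b, m_lo), min(b, m_hi)


def analytic_coverage_percent(params: PhantomParams, n_phi: int = 40001) -> float:
    """Tibial coverage (%) of a circular plateau by the meniscus TA footprint,
    evaluated on the restricted slice range the pipeline uses.

    Numerator: overlap area of the annular-sector footprint with the plateau
    disc; denominator: plateau area within the restricted slices (the
    projected footprint, not the 3D mesh area).
    """
    a = params.plateau_semi_axis_x
    if abs(params.plateau_semi_axis_y - a) > 1e-9:
        raise ValidationError("closed-form coverage requires a circular plateau")
    y_lo, y_hi = restricted_y_range(params)
    phi = np.linspace(params.arc_start, params.arc_start + params.arc_span, n_phi)
    lo, up, ok = _phi_radial_interval(params, phi, y_lo, y_hi)
    lo_c, up_c = np.minimum(lo, a), np.minimum(up, a)
    covered = np.trapezoid(np.where(ok, (up_c ** 2 - lo_c ** 2) / 2.0, 0.0), phi)
    denom = restricted_plateau_area(params, y_lo, y_hi)
    if denom <= 0:
        raise ValidationError("empty restricted plateau footprint")
    return 100.0 * float(covered) / denom


# ---------------------------------------------------------------------------
# voxelization


def _grid_axis(lo: float, hi: float, step: float, align_boundary_at_zero: bool):
    """Voxel-centre coordinates covering [lo, hi].

    With ``align_boundary_at_zero`` the centres sit at ``(k + 1/2) * step`` so
    that ``z = 0`` (the plateau surface) is exactly a voxel boundary.
    """
    if align_boundary_at_zero:
        k_lo = math.floor(lo / step - 0.5)
        k_hi = math.ceil(hi / step - 0.5)
        return (np.arange(k_lo, k_hi + 1) + 0.5) * step
    n = int(math.ceil((hi - lo) / step)) + 1
    return lo + np.arange(n) * step


def _rasterize_compartment(params, xs, ys, zs, labels, label_map, rng, noise_sd,
                           plateau_thickness, prepartition):
    """Paint one compartment's plateau and meniscus into ``labels`` in place."""
    cx, cy = params.center
    R, w, h = params.outer_radius, params.radial_width, params.peak_height
    r_in = params.inner_radius
    phi0, th = params.arc_start, params.arc_span
    cart_name = "MT_ACdAB" if params.compartment == "medial" else "LT_ACdAB"
    men_name = "MM" if params.compartment == "medial" else "LM"

    X = xs[:, None] - cx                      # (nx, 1)
    Z = zs[None, :]                           # (1, nz)
    plateau_z = (Z >= -plateau_thickness) & (Z < 0)
    men_count_per_slice = np.zeros(len(ys), dtype=int)

    # per-slice boundary jitter: outer rim, inner rim, plateau rim
    jit = rng.normal(0.0, noise_sd, size=(len(ys), 3)) if noise_sd > 0 else np.zeros((len(ys), 3))

    men_mask3 = np.zeros((len(xs), len(ys), len(zs)), dtype=bool) if prepartition else None

    for iy, y in enumerate(ys):
        Y = y - cy
        r = np.hypot(X[:, 0], Y)                         # (nx,)
        phi = np.mod(np.arctan2(Y, X[:, 0]) - phi0, 2 * math.pi)
        in_arc = phi <= th
        r_pl = np.asarray(params.plateau_radius(np.arctan2(Y, X[:, 0]))) + jit[iy, 2]
        plate_xy = r <= r_pl
        plate = plate_xy[:, None] & plateau_z
        labels[:, iy, :][plate] = label_map[cart_name]

        lo = r_in + jit[iy, 1]
        hi = R + jit[iy, 0]
        radial = (r >= lo) & (r <= hi) & in_arc
        height = h * np.clip((r - r_in) / w, 0.0, 1.0)
        men = radial[:, None] & (Z >= 0) & (Z < height[:, None])
        labels[:, iy, :][men] = label_map[men_name]
        men_count_per_slice[iy] = int(men.sum())
        if prepartition:
            men_mask3[:, iy, :] = men

    n_slices = int((men_count_per_slice > 0).sum())
    if n_slices < 3:
        raise ValidationError(
            f"spacing too coarse: meniscus intersects only {n_slices} coronal slices (need >= 3)")

    if prepartition:
        _paint_surface_shell(params, men_mask3, xs, ys, zs, labels, label_map, men_name)


def _paint_surface_shell(params, men_mask, xs, ys, zs, labels, label_map, men_name):
    """Relabel the meniscus boundary shell with analytic TA/FA/EA sub-labels.

    A shell voxel is a meniscus voxel with a 6-neighbourhood face exposed to
    background; it is assigned to the nearest of the three analytic surfaces
    (flat bottom, slanted top, outer wall).
    """
    from scipy.ndimage import binary_erosion

    core = binary_erosion(men_mask, structure=np.array(
        [[[0, 0, 0], [0, 1, 0], [0, 0, 0]],
         [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
         [[0, 0, 0], [0, 1, 0], [0, 0, 0]]], dtype=bool))
    shell = men_mask & ~core
    ix, iy, iz = np.nonzero(shell)
    x = xs[ix] - params.center[0]
    y = ys[iy] - params.center[1]
    z = zs[iz]
    r = np.hypot(x, y)
    h, w = params.peak_height, params.radial_width
    slope_norm = math.sqrt(1.0 + (h / w) ** 2)
    d_bottom = np.abs(z)
    d_top = np.abs(h * np.clip((r - params.inner_radius) / w, 0, 1) - z) / slope_norm
    d_wall = np.abs(params.outer_radius - r)
    choice = np.argmin(np.stack([d_bottom, d_top, d_wall]), axis=0)
    for k, surf in enumerate(("TA", "FA", "EA")):
        sel = choice == k
        labels[ix[sel], iy[sel], iz[sel]] = label_map[f"{men_name}_{surf}"]


def voxelize_phantom(params: PhantomParams,
                     spacing: tuple[float, float, float] = ACQUISITION_SPACING,
                     noise_sd: float = 0.0, seed: int = 0,
                     prepartition: bool = False,
                     plateau_thickness: float = 1.5,
                     margin: float = 1.5) -> VoxelSegmentation:
    """Voxelize a single-compartment phantom at MRI-like spacing.

    Voxel ownership is by centre-point inclusion.  ``noise_sd`` (mm) applies
    seeded Gaussian radial jitter to the meniscus and plateau rims per coronal
    slice, emulating manual-segmentation variability without changing
    topology.  Deterministic for a given seed.
    """
    return voxelize_knee([params], spacing, noise_sd=noise_sd, seed=seed,
                         prepartition=prepartition,
                         plateau_thickness=plateau_thickness, margin=margin)


def voxelize_knee(compartments: list[PhantomParams],
                  spacing: tuple[float, float, float] = ACQUISITION_SPACING,
                  noise_sd: float = 0.0, seed: int = 0,
                  prepartition: bool = False,
                  plateau_thickness: float = 1.5,
                  margin: float = 1.5) -> VoxelSegmentation:
    """Voxelize one or two compartment phantoms into a shared label grid."""
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be 3 positive values, got {tuple(spacing)}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if not compartments:
        raise ValidationError("need at least one compartment")
    dx, dy, dz = (float(s) for s in spacing)

    pad = margin + 5.0 * noise_sd
    ext = [p.outer_radius + pad for p in compartments]
    ext_pl = [max(p.plateau_semi_axis_x, p.plateau_semi_axis_y) + pad for p in compartments]
    reach = [max(e, ep) for e, ep in zip(ext, ext_pl)]
    x_lo = min(p.center[0] - r for p, r in zip(compartments, reach))
    x_hi = max(p.center[0] + r for p, r in zip(compartments, reach))
    y_lo = min(p.center[1] - r for p, r in zip(compartments, reach))
    y_hi = max(p.center[1] + r for p, r in zip(compartments, reach))
    z_lo = -plateau_thickness - dz
    z_hi = max(p.peak_height for p in compartments) + dz

    xs = _grid_axis(x_lo, x_hi, dx, align_boundary_at_zero=True)
    ys = _grid_axis(y_lo, y_hi, dy, align_boundary_at_zero=True)
    zs = _grid_axis(z_lo, z_hi, dz, align_boundary_at_zero=True)

    labels = np.zeros((len(xs), len(ys), len(zs)), dtype=np.int16)
    rng = np.random.default_rng(seed)
    for params in compartments:
        _rasterize_compartment(params, xs, ys, zs, labels, DEFAULT_LABEL_MAP, rng,
                               noise_sd, plateau_thickness, prepartition)
    return VoxelSegmentation(
        labels=labels, spacing=(dx, dy, dz),
        origin=(float(xs[0]), float(ys[0]), float(zs[0])),
        label_map=dict(DEFAULT_LABEL_MAP), laterality="right",
    )


# ---------------------------------------------------------------------------
# presets calibrated to the published reference means


def preset_params(sex: str, compartment: str) -> PhantomParams:
    """Compartment phantom calibrated to the published reference morphometry.

    The arc is the posterior half-annulus ``phi in [pi, 2 pi]``: its two end
    faces then lie exactly in the central coronal plane, i.e. they are the
    uncapped anterior/posterior open ends of the slice stack rather than
    surfaces visible within slices — matching the no-end-cap convention of
    coronal serial-section reconstruction.

    Calibration, from the reference means of the given sex and compartment:
    plateau area (ACdAB) fixes the circular plateau radius ``a``; mean
    extrusion fixes the radial offset ``delta`` (hence ``R = a + delta``);
    maximal thickness fixes the wedge peak height; and the tibial coverage
    percentage — evaluated on the restricted slice range, as the pipeline
    measures it — fixes the inner rim radius:

    * extruded rim (``R > a``): covered = (pi/2)(a^2 - r_in^2), denominator
      the half plateau, so ``r_in = a * sqrt(1 - covp)``;
    * rim inside the plateau (``R <= a``): covered = (pi/2)(R^2 - r_in^2),
      denominator the plateau area within the meniscus' slice range.
    """
    ref = REFERENCE[compartment][sex]
    a = math.sqrt(ref["ACdAB"][0] / math.pi)
    delta = ref["Ex_Me"][0]
    R = a + delta
    covp = ref["ACdAB_Covp"][0] / 100.0
    if R > a:
        r_in_sq = a ** 2 * (1.0 - covp)
    else:
        denom = R * math.sqrt(a ** 2 - R ** 2) + a ** 2 * math.asin(R / a)
        r_in_sq = R ** 2 - 2.0 * covp * denom / math.pi
    if r_in_sq <= 0 or r_in_sq >= R ** 2:
        raise ValidationError("coverage target unattainable for this geometry")
    w = R - math.sqrt(r_in_sq)
    # cap the wedge slope at 1: boundary staircases then stay
    # horizontal/diagonal (unambiguous tibial/femoral classification) and the
    # sub-voxel-thin portion of the inner rim is as narrow as possible
    h = min(ref["Th_Max"][0], w)
    return PhantomParams(
        plateau_semi_axis_x=a, plateau_semi_axis_y=a,
        outer_radius=R, radial_width=w, peak_height=h,
        arc_start=math.pi, arc_span=math.pi,
        compartment=compartment, center=(0.0, 0.0),
    )


PRESETS = {
    "female-medial": ("F", "medial"),
    "male-medial": ("M", "medial"),
    "female-lateral": ("F", "lateral"),
    "male-lateral": ("M", "lateral"),
}


def write_ground_truth_csv(truths: dict[str, GroundTruthMorphometry],
                           path: str | Path) -> Path:
    """One row per named phantom; measure columns as in the record schema."""
    rows = []
    for name, gt in truths.items():
        row = {"phantom": name}
        d = asdict(gt)
        flags = d.pop("analytic_flags")
        row.update(d)
        row["numeric_oracle_fields"] = ";".join(
            sorted(k for k, v in flags.items() if v != "closed-form"))
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
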