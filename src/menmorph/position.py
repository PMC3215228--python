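"""Meniscus position relative to the tibial plateau.

All measures are evaluated per coronal slice on the restricted slice set and
use a side-aware outward coordinate ``u``: larger ``u`` means more external
(more medial for a medial compartment of a right knee, more lateral for a
lateral one).  Per slice:

* extrusion ``e = u(TA external margin) - u(ACdAB external margin)`` —
  positive when the meniscus reaches beyond the plateau rim;
* overlap distance ``d = u(TA internal margin) - u(ACdAB external margin)``
  — negative when the meniscal inner rim (the TA/FA junction) lies internal
  to the plateau rim, which is the physiological situation, hence the
  negative reported means;
* coverage: length of the intersection of the plateau's x-interval footprint
  with the TA's, times the slice thickness, summed over slices.  The
  denominator is the projected plateau footprint area (not the 3D mesh
  area).

Means are over the restricted slices; maxima are signed maxima (the least
internal slice), so ``Ex_Max >= Ex_Me`` and ``OvD_Max >= OvD_Me`` always.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .segio import ValidationError

__all__ = [
    "SliceMargins", "compute_margins", "extrusion_stats",
    "overlap_distance_stats", "footprint_intervals", "coverage",
    "uncovered_ta", "slice_diagnostics",
]

_OUTWARD_SIGN = {"medial": -1, "lateral": +1}


@dataclass
class SliceMargins:
    """Per-slice external/internal margins in the outward coordinate ``u``.

    ``margins[iy] = (u_acdab_external, u_ta_external, u_ta_internal)``; the
    external ACdAB margin is each slice's reference point (extrusion and
    overlap are differences against it).
    """

    margins: dict[int, tuple[float, float, float]]
    outward_sign: int
    dy: float

    def slices(self) -> list[int]:
        return sorted(self.margins)

    def extrusions(self) -> np.ndarray:
        return np.array([self.margins[iy][1] - self.margins[iy][0] for iy in self.slices()])

    def overlap_distances(self) -> np.ndarray:
        """Per-slice overlap distances; slices without a TA/FA junction
        (horn regions where bottom and top never meet) are omitted."""
        d = np.array([self.margins[iy][2] - self.margins[iy][0] for iy in self.slices()])
        return d[np.isfinite(d)]


def _u_values(polys, sign: int) -> np.ndarray:
    return np.concatenate([p[:, 0] * sign for p in polys])


def _junction_u(ta_polys, fa_polys, sign: int, tol: float = 1e-6) -> float:
    """Outward coordinate of the TA/FA junction (the meniscal inner rim).

    Junctions are vertices shared between a TA and an FA boundary segment
    (the surfaces are split at exact contour vertices, so shared endpoints
    match to within floating-point noise).  With several junctions on a
    slice — e.g. one per meniscus body — the most external one belongs to
    the compartment's own body and is returned.  NaN when bottom and top
    never meet on the slice (no inner rim visible).
    """
    ta_ends = np.array([p[i] for p in ta_polys for i in (0, -1)])
    fa_ends = np.array([p[i] for p in fa_polys for i in (0, -1)])
    if not len(ta_ends) or not len(fa_ends):
        return math.nan
    d = np.abs(ta_ends[:, None, :] - fa_ends[None, :, :]).max(axis=2)
    shared = ta_ends[(d < tol).any(axis=1)]
    if not len(shared):
        return math.nan
    return float((shared[:, 0] * sign).max())


def compute_margins(cart_contours, ta_contours, fa_contours, side: str,
                    slice_set) -> SliceMargins:
    """Per-slice margins of ACdAB and TA in outward coordinates.

    External margins are the most external contour vertices after sub-pixel
    tracing (ties break toward larger ``u``); the TA internal margin is the
    TA/FA junction, i.e. the meniscal inner rim where the tibial and femoral
    surfaces meet.  Slices in the restricted set lacking a TA boundary are
    excluded with a warning.
    """
    sign = _OUTWARD_SIGN[side]
    if not slice_set:
        raise ValidationError("restricted slice set is empty")
    margins = {}
    for iy in sorted(slice_set):
        cart = cart_contours.slice_polylines(iy)
        ta = ta_contours.slice_polylines(iy)
        fa = fa_contours.slice_polylines(iy)
        if not cart:
            continue
        if not ta:
            warnings.warn(f"slice {iy} has cartilage but no TA boundary; excluded",
                          stacklevel=2)
            continue
        u_cart = _u_values(cart, sign)
        u_ta = _u_values(ta, sign)
        margins[iy] = (float(u_cart.max()), float(u_ta.max()),
                       _junction_u(ta, fa, sign))
    if not margins:
        raise ValidationError("no slice carries both an ACdAB and a TA margin")
    return SliceMargins(margins, sign, ta_contours.dy)


def extrusion_stats(margins: SliceMargins) -> tuple[float, float]:
    """(Ex_Me, Ex_Max): signed mean and signed maximum per-slice extrusion."""
    e = margins.extrusions()
    return float(e.mean()), float(e.max())


def overlap_distance_stats(margins: SliceMargins) -> tuple[float, float]:
    """(OvD_Me, OvD_Max): signed mean and signed maximum overlap distance.

    Evaluated over the slices where the meniscal inner rim (TA/FA junction)
    is visible; NaN when it never is.
    """
    d = margins.overlap_distances()
    if not len(d):
        return math.nan, math.nan
    return float(d.mean()), float(d.max())


# ---------------------------------------------------------------------------
# footprint coverage


def footprint_intervals(stack, slice_set) -> dict[int, list[tuple[float, float]]]:
    """Per-slice x-interval footprint: one (min, max) interval per component,
    merged where components overlap in x."""
    out: dict[int, list[tuple[float, float]]] = {}
    keep = set(slice_set)
    for iy in stack.nonempty_slices():
        if iy not in keep:
            continue
        ivals = sorted((float(p[:, 0].min()), float(p[:, 0].max()))
                       for p in stack.slice_polylines(iy))
        merged = [ivals[0]]
        for lo, hi in ivals[1:]:
            if lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        out[iy] = merged
    return out


def _interval_length(ivals) -> float:
    return sum(hi - lo for lo, hi in ivals)


def _intersect(a, b):
    out = []
    for lo1, hi1 in a:
        for lo2, hi2 in b:
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if hi > lo:
                out.append((lo, hi))
    return out


def coverage(cart_footprint, ta_footprint, slice_set, dy: float) -> tuple[float, float]:
    """(ACdAB_Cov mm^2, ACdAB_Covp %): plateau area covered by the meniscus TA."""
    total = covered = 0.0
    for iy in sorted(slice_set):
        cart = cart_footprint.get(iy, [])
        ta = ta_footprint.get(iy, [])
        total += _interval_length(cart) * dy
        covered += _interval_length(_intersect(cart, ta)) * dy
    if total <= 0:
        raise ValidationError("plateau footprint is empty on the restricted slices")
    return covered, 100.0 * covered / total


def uncovered_ta(cart_footprint, ta_footprint, slice_set, dy: float) -> tuple[float, float]:
    """(TA_Uncov mm^2, TA_Uncovp %): TA footprint area beyond the plateau.

    The percentage is relative to the total TA footprint area.
    """
    ta_total = outside = 0.0
    for iy in sorted(slice_set):
        cart = cart_footprint.get(iy, [])
        ta = ta_footprint.get(iy, [])
        lt = _interval_length(ta)
        ta_total += lt * dy
        outside += (lt - _interval_length(_intersect(ta, cart))) * dy
    if ta_total <= 0:
        return 0.0, 0.0
    return outside, 100.0 * outside / ta_total


def slice_diagnostics(margins: SliceMargins, cart_footprint, ta_footprint,
                      path: str | Path | None = None) -> pd.DataFrame:
    """Per-slice diagnostics table (extrusion, overlap, covered length)."""
    rows = []
    for iy in margins.slices():
        cart = cart_footprint.get(iy, [])
        ta = ta_footprint.get(iy, [])
        u_ac, u_ta_ext, u_ta_int = margins.margins[iy]
        rows.append({
            "slice": iy,
            "extrusion_mm": u_ta_ext - u_ac,
            "overlap_distance_mm": u_ta_int - u_ac,
            "covered_length_mm": _interval_length(_intersect(cart, ta)),
            "plateau_length_mm": _interval_length(cart),
        })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
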