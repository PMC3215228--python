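# Methods

This note documents the models, conventions and numerical choices behind
`menmorph`: what each measure means, how the phantom and cohort generators
emulate the study conditions, and where the discretization limits are.

## Coordinate and label conventions

Volumes are integer label grids with axes x (medio-lateral), y
(antero-posterior = the coronal slice axis) and z (inferior-superior);
world = origin + index · spacing with voxel-centre semantics and 0-based
indices.  The right-knee convention is canonical: left knees are mirrored
about the x = 0 plane at read time (recorded on the object), so all
side-aware logic is single-cased.  Structures: `MT_ACdAB`/`LT_ACdAB` for
the medial/lateral tibial plateau region (the area of cartilage surface
including denuded subchondral bone, modelled as one region), `MM`/`LM` for
the meniscus solids, and optional `*_TA/FA/EA` surface shell labels when a
segmentation arrives pre-partitioned.

## Measurement chain

1. **Contours.** Per coronal slice, marching squares at the 0.5 level of
   the zero-padded binary mask (linear interpolation): the boundary passes
   midway between an inside and an outside voxel centre.  Under this
   convention a single voxel encloses 0.5·dx·dz and a 10×10 block at 1 mm
   encloses 99.5 mm² (corner chamfers of 0.125 mm² each).  Multiple
   components per slice are kept.
2. **Slice restriction.** All measures use only slices on which both the
   tibial cartilage and the meniscus have contours, mirroring a protocol in
   which segmentation is restricted to slices where both structures are
   reliably identifiable.
3. **Surface partition.** Each meniscus boundary contour is split by
   outward-normal dominance: |n_z| ≥ |n_x| (ties, i.e. exact 45°, included)
   → tibial (n_z < 0) or femoral surface; x-dominant edges are external
   when the normal points away from the compartment centre (the centroid of
   the compartment's cartilage — a coronal section may legitimately show
   meniscus on both sides of that centre, and both outer rims face away
   from it), internal otherwise.  Internal edges attach to the nearer of
   TA/FA by the z-sign of their normal; purely vertical internal runs are
   split at the contour's mid height, so the meniscal inner rim is always
   the TA/FA junction.
4. **Triangulation.** Adjacent slice contours are connected into triangle
   ribbons: components correspond by x-footprint overlap (a component
   matched by several partners — the inner-rim hole opening — is tiled by
   cutting at the x-midpoints between its partners, so no contour segment is
   ribboned twice); within a pair, vertices advance by normalized arc
   length with shortest-diagonal tie-break.  Vertex order is arranged so
   that counter-clockwise contours yield consistently outward-wound
   triangles.  The anterior-most and posterior-most contours are left
   uncapped: a coronal stack truncates the meniscal horns anyway.
5. **Areas.** TA/FA/EA areas are read off the whole-solid mesh by
   classifying each triangle with the same dominance rule applied to its 3D
   normal (z against the outward radial direction from the compartment
   centre axis).  Classifying in 3D — rather than from in-slice edge
   normals — keeps the parts of the outer wall that run nearly tangent to
   the slice planes (the antero-posterior ends) correctly assigned to the
   external surface; the in-slice partition of step 3 is still what drives
   all position metrics.  `ACdAB` is the ribbon area of the cartilage
   slab's superior surface.  `TOT A = TA + FA + EA` exactly, by summation.
   With pre-partitioned labels, mesh triangles take the label of the
   nearest labelled shell voxel instead.
6. **Staircase filter.** Contours entering the area triangulation are
   first vertex-averaged within a fixed ±0.25 mm arc-length window.
   Marching squares on a binary mask emits only axis-aligned and 45° edges,
   which overestimates the path length of slanted boundaries by 3–8%
   (the classic staircase bias) and hence slanted-surface areas; the
   sub-millimetre filter removes that bias while displacing no vertex by
   more than a fraction of a voxel, and degenerates to the identity at
   voxel pitches at or above the window.  Raw contours are used everywhere
   else (margins, footprints, widths), where extremes must not be pulled
   inward.
7. **Voxel measures.** Volume is the voxel count within the restricted
   slices times the voxel volume (robust to the open mesh); thickness is
   the z-extent of each occupied (x, y) column — matching the "meniscal
   height" reading of maximal thickness — with `Th.Me` the mean over
   occupied columns and `Th.Max` the maximum; width is the per-slice total
   x-extent of the meniscus footprint across components.
8. **Position metrics.** A side-aware outward coordinate u (more medial
   for a medial compartment of a right knee, more lateral for a lateral
   one) is evaluated per slice: extrusion e = u(TA external margin) −
   u(ACdAB external margin), signed, positive beyond the plateau rim;
   overlap distance d = u(TA/FA junction) − u(ACdAB external margin),
   negative when the inner rim lies over the plateau (hence negative means,
   as published).  Means are over the restricted slices; maxima are signed
   maxima (the least-internal slice), so max ≥ mean always.  Slices where
   bottom and top never meet (no inner rim visible) are excluded from the
   overlap statistics.  Coverage intersects the plateau's per-slice
   x-interval footprint with the TA's; the denominator is the projected
   plateau footprint on the restricted slices, not the 3D mesh area.
   Whether a "maximal extrusion" should be the signed maximum or the
   maximum of positive parts is not standardized; the signed maximum is
   used and flagged here.

## The phantom

The phantom is a validation instrument, not an anatomical claim: a flat
elliptical plateau (realised as a thin slab below z = 0, its superior
surface being ACdAB) and a meniscus shaped as an annular wedge — polar
region φ∈[φ0, φ0+Θ], r∈[R−w, R], flat bottom at z = 0, vertical outer wall,
top rising linearly from 0 at the inner rim to h at the outer rim.  Every
measure then has a closed form (TA = Θ·w·(R−w/2); EA = Θ·R·h;
FA = √(1+(h/w)²)·TA; V = Θ·h·w·(w/3+(R−w)/2); Th.Me = V/TA; Th.Max = h;
ACdAB = π·a·b; central-slice extrusion = δ = R − a) or a cheap
one-dimensional-integral oracle when the restricted slice range clips the
footprint.

Preset calibration (per sex and compartment, from the published reference
means): plateau area fixes the circular plateau radius a; mean extrusion
fixes δ (so R = a + δ; negative laterally, where the rim sits inside the
plateau); tibial coverage — evaluated on the restricted slice range exactly
as the pipeline measures it — fixes the inner rim radius; the wedge height
is the published maximal thickness capped at h ≤ w.  Two geometry choices
are deliberate:

* the arc is the posterior half-annulus φ∈[π, 2π], so both arc-end faces
  lie exactly in the central coronal plane: they are then the uncapped ends
  of the slice stack rather than surfaces visible inside slices, which
  would otherwise pollute the three-surface decomposition.  A consequence
  is that the per-slice width of the phantom is the full two-branch extent
  (≈ 2R centrally), not w — phantom widths are therefore checked against
  the footprint geometry, not against published widths;
* the slope cap h ≤ w keeps boundary staircases horizontal/diagonal
  (unambiguous classification) and minimises the sub-voxel-thin inner rim
  that voxelization cannot represent.

Voxelization is by centre-point inclusion, with the z grid aligned so the
plateau plane z = 0 is a voxel boundary.  The noise model is seeded
Gaussian radial jitter of the meniscus and plateau rims per coronal slice
(default SD 0 for validation; 0.2 mm in the noisy-knee analysis), emulating
manual-segmentation variability without changing topology.

**Oracle bounds.**  Mesh-derived areas are compared to the closed-form
integrals over the span of the slice *centres* (a serial-section
reconstruction cannot see beyond its first and last contour); voxel-counted
measures (V, thickness) over the span of the slice *slabs*.  At 0.2 mm
isotropic, every size measure is within 2% of its oracle; at the
acquisition spacing (0.37 × 1.5 × 0.37 mm) within 5%, the residual being
slice-sampling error of a ~15–20 mm structure cut into ~10–13 slices.
Position metrics recover configured offsets within one in-plane voxel and
coverage within 2 percentage points (the tibial footprint loses a ring of
width ≈ dz/(2·slope) at the sub-voxel-thin inner rim, costing ≈ 1 point at
the acquisition spacing).

## The synthetic cohorts

Cohorts are drawn per sex from a multivariate normal over 18 variables (the
size and position measures plus body height and weight) with published
means, SDs and within-sex Pearson correlations for asymptomatic adults
(40 men, 62 women).  Unpublished correlations default to zero, except that
the three drawn surface components echo TOT A's published correlations
scaled by their 0.95 coupling to TOT A — without this the matrix is far
from positive semi-definite and the repair would distort the published
entries.  The assembled matrix is projected to the nearest valid
correlation matrix (eigenvalue clipping at zero, diagonal rescaled to one;
the adjustment magnitude is recorded on the result, and is zero for the
shipped calibrations).  Draws are truncated at physical bounds (positive
sizes, percentages in [0, 100]); truncation counts are recorded.  Two
columns are derived, not drawn: TA/FA/EA are rescaled per subject to sum
exactly to the drawn TOT A, and the normalized size TOT A/ACdAB is the
per-subject quotient — its mean, SD and reduced coefficient of variation
therefore *emerge* from the joint distribution rather than being imposed,
which is precisely the claim the variability analysis tests.  Ages are
drawn uniformly within the per-sex reference ranges and are uncorrelated
with size by construction.

What the cohorts do **not** emulate: non-normal marginals, measurement
error, left-right or within-subject dependence, and any real covariance
beyond the published pairwise correlations.  Passing the statistical tests
shows the estimators and the calibration are faithful — not that real
meniscus data are multivariate normal.

## Statistical conventions

Sample SD uses the n−1 denominator; CV% = 100·SD/mean, undefined (flagged,
not NaN-propagated) at zero mean.  Percent sex differences are
women-referenced: 100·(men − women)/women.  The default two-sample test is
pooled-variance Student's t with df = n1 + n2 − 2 (the summary-statistic
reproduction of the published medial-extrusion p ≈ 0.011 supports the
pooled variant for a 2011-era analysis); Welch is available.  Pearson r
carries a two-tailed p from t = r·√((n−2)/(1−r²)); correlations are
computed within sex only — pooling sexes would inflate every correlation
through the common size difference.  Correlation cells are annotated with
significance bands (p < 0.001 and p < 0.05), an interpretive choice since
published tables of this kind often leave their emphasis legend unstated.
Report rounding: 3 significant figures for means/SDs, one decimal for
percent differences, three decimals for p with a "<0.001" floor.

## Known limitations

* Serial-section reconstruction at 1.5 mm slices under-resolves the
  strongly curved antero-posterior ends; the package reports what the
  slices support and caps nothing.
* The in-slice TA/FA/EA split and the 3D mesh split agree except in
  voxel-scale bands at surface corners; pre-partitioned versus derived
  modes likewise agree to within a corner band that shrinks linearly with
  voxel size (≈ 2% at 0.2 mm).
* Anterior/posterior extrusion is out of scope: coronal stacks cannot
  measure it.
* The wedge phantom has no horns and a single arc; published widths
  (notably the medial maximal width) reflect horn geometry the phantom
  does not attempt, so no width targets are set for it.
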