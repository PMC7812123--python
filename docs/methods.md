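# Methods

`endocompare` quantifies how faithfully an endocast — the cast of the inner
table of the braincase — records the shape and sulcal pattern of the brain
it once enclosed.  The pipeline compares a *brain hull* (a simplified
envelope of the brain surface) with the endocast of the same individual:
surfaces are extracted from volumetric images, sulci are detected as
curvature-extremal lines, the hull is registered onto the endocast with a
smooth invertible deformation, and the hull's sulcal curves are transported
through that deformation so that curve-to-curve distances can be measured
in a common frame.  Because paired clinical MRI/CT data cannot be shipped,
the package includes a synthetic phantom generator with exact ground truth;
every stage is validated against it.

## The phantom

The brain is a flattened-base ellipsoid (default semi-axes 48 x 38 x 33 mm,
base cut at 0.55 of the inferior semi-axis).  Sulci are grooves carved
along well-separated geodesic-like arcs: great-circle segments of the unit
sphere mapped through the ellipsoid's axis scaling, rejected until all
pairs stay at least two groove widths (8 mm) apart — so the 10 mm matching
threshold can still discriminate neighbouring sulci — and until they avoid
both the flattened base and the superior polar cap.  Each groove has an
elliptical cross-section (default depth 3 mm at the centreline, width 4 mm,
depth tapering to zero at the edges), giving a single concave furrow like a
sulcal imprint; a flat-bottomed channel would instead carry two concave rim
lines and no central ravine.

The endocast is the brain surface offset outward by a uniform shell
(default 2 mm, standing for dura and CSF).  Both surfaces are levels of one
analytic signed-distance field, so the offset is exact by construction and
not subject to voxel dilation bias.  The endocast then degrades the brain's
record in the three ways an inner table does:

* groove depth is attenuated (default factor 0.3);
* a fraction of sulci is absent entirely (default 0.2, so
  `round(0.2 x 10) = 2` of the 10 default sulci);
* the superior polar cap (default 40 degrees around +z) is smoothed
  (default 3 mm) and carries a midline sagittal-sinus ridge (default
  2.5 mm), reproducing the well-known superior-region mismatch.

The "MRI" and "CT" volumes share one head geometry (brain, CSF gap, skull,
scalp) with modality-specific contrasts — T1-like bright brain / dark bone
versus CT-like bright bone / faint soft tissue — plus independent Gaussian
noise (sd 0.03 on a 0..1 intensity scale, 1 mm voxels).  The CT volume is
posed under a known rigid(+scale) transform (default 4, -3, 2 mm
translation with a 5 degree rotation), so multimodal rigid registration is
exercised non-trivially; the shared tissue structure is what gives
normalized mutual information a well-defined maximum, as in real head
images.  Ground truth records every groove centre path (sampled at the
groove floor), the dropped labels, and the true inter-modality transform.

What the phantom does *not* emulate: anatomical folding patterns, vascular
and meningeal detail beyond the single ridge, scanner artefacts (bias
fields, geometric distortion), and partial-volume tissue mixtures beyond
simple smoothing.  Passing tests therefore demonstrate that the pipeline's
geometry and statistics behave correctly under controlled degradations —
not that detection would reach the same recall on clinical images.

## Surface extraction

Both surfaces are extracted by shrink-wrapping: a subdivided icosahedron
(edge length about two voxels) either encloses the brain and is shrunk onto
it, or sits inside the endocranial cavity and is inflated onto the inner
table.  The target is the zero level of a signed Euclidean distance field
computed from the thresholded volume; the field is corrected for the
half-voxel bias of centre-to-centre distance transforms and blurred by a
0.6-voxel Gaussian so its zero level is free of voxel staircase (the level
shift this causes is ~sigma^2 x curvature / 2, well below a voxel).  Each
iteration moves every vertex along its normal by the clamped signed
distance (at most `step_size` = 1 mm), blends the result with uniform
Laplacian smoothing (`smoothing_weight` = 0.3), and finally projects any
vertex that ended up inside the solid back to the surface along the
distance gradient, so the wrap remains an enclosing (resp. inscribed)
surface.  Iteration stops when the maximum vertex displacement falls below
0.01 mm; phantom inputs converge in a few dozen iterations.  Because the
mesh topology never changes, outputs are watertight and genus 0 by
construction.

Meshes are then resampled to a fixed budget of exactly 100,000 triangular
faces, the conventional size for this kind of surface comparison.  When the
wrap is below budget it is uniformly subdivided, then shortest-edge
midpoint collapses (with the link condition and a normal-flip guard, so
manifoldness and orientation survive) reduce it to the exact count.  This
in-package decimator exists because no decimation backend is available to
trimesh here; on a 10x decimated sphere its maximal radial error is below
0.2 %.

## Sulcus detection

Sulci are concave furrows, detected as *ravine lines*: zero crossings of
the derivative of the minimal principal curvature along its own principal
direction (the extremality), restricted to vertices where kmin is below a
negative threshold.  Curvature is estimated per vertex by fitting a cubic
height field over the geodesic neighbourhood (default radius: max of
2.5 mm and 2.1 mean edge lengths) in the local tangent frame, with Gaussian
distance weights to suppress the bias that quartic surface terms would
otherwise leak into the quadric; the sign convention makes convexity
with respect to the outward normal positive.  On analytic test surfaces
(sphere r = 10 mm, cylinder r = 5 mm) the principal curvatures are
recovered within 2 %.

On meshes extracted from voxel data the raw cubic-term extremality flips
sign with residual tessellation ripple and fragments the traced lines, so
the production path first relaxes kmin/kmax by two steps of 0.5-weighted
neighbour averaging and recomputes the extremality as the tangent-plane
gradient of the smoothed curvature projected on the (unchanged) principal
directions; on clean analytic meshes the two formulations agree.

Crossings are linked through triangles (at 3-crossing branch triangles the
two strongest-curvature crossings join, so output decomposes into simple
polylines), chains whose endpoints nearly continue one another (gap under
3 mean edge lengths, tangent continuity) are merged, and lines shorter than
12 mm are discarded.  The curvature threshold is scale-adaptive: the 75th
percentile of |kmin| over the mesh.  Detected curves are labeled against a
reference curve set (here the phantom truth; for real data an expert's
file) by minimal mean closest-point distance with a 5 mm acceptance radius;
fragments of one sulcus legitimately share a label, and fragments more than
5 mm from every reference stay unlabeled and are excluded from the counts.

Known limitation: the exact chain decomposition is not stable under rigid
motion at vertices approaching umbilic degeneracy, where principal
directions are numerically arbitrary and eligibility/alignment tie-breaks
can flip; the curve count, total length and the geometry of strong lines
are stable, and the test suite asserts exactly that.

## Registration and curve transport

Pose and global size are removed first by ICP over rotation, translation
and one uniform scale, solved in closed form (Umeyama) from exact
closest-point-on-surface correspondences; the solver restarts from identity
and +/-20 degree rotations about each axis because nearest-neighbour
correspondences otherwise stall in sliding minima on nearly-symmetric
shapes.  On a synthetic 1.2x-scaled, 10 degree-rotated target the scale is
recovered within 0.01 and the rotation within half a degree.

The remaining shape difference is carried by a deformation parameterized by
control points on a regular grid over the source bounding box (default
600), each carrying a momentum vector.  The velocity field is the sum of
Gaussian kernels K(x, c) = exp(-|x - c|^2 / sigma^2) (sigma = 15 mm)
weighted by the momenta; vertices and control points are advected through
10 explicit Euler steps.  Momenta are held constant in time — a
one-parameter subfamily of the usual geodesic flows.  This keeps the
transport a genuine flow of a smooth, time-continuous velocity field (hence
invertible; the no-face-inversion check is asserted on every fixture) while
making the objective gradient exactly computable by reverse-mode
accumulation through the Euler steps, which a finite-difference test
verifies to ~1e-5 relative error.

The data term is a squared varifold distance with a 5 mm spatial kernel:
surfaces enter through face centroids and area-weighted normals with a
squared-cosine orientation weighting, so the measure is insensitive to
winding conventions.  The deformation kernel (15 mm) is deliberately wider
than the sulcal spacing (8 mm minimum) so that curves transport coherently
with the surface they lie on.  The objective adds a kinetic-energy
regularizer (weight 1e-4) in the kernel metric at the initial control
points.  Optimization is gradient descent from zero momenta with
backtracking line search, so the energy trace is non-increasing by
construction.  Registration runs on 2,000-face decimated copies of the two
surfaces — the fitted flow is resolution-independent and is applied to the
full-resolution curves — which keeps a full pipeline run around four
minutes on one CPU.

On the default phantom, over 95 % of deformed hull vertices land within
1 mm of the endocast outside the superior cap; cycle consistency (register
forward, then back) returns vertices to within 1 mm on the sphere fixture.

## Matching statistics and maps

For each endocast curve, the distance to the brain hull is the mean, over
the curve's points, of the distance to the closest point on any same-label
transported brain curve, using point-to-segment projection so the value is
independent of sampling density.  The measure is directional
(endocast -> brain) and uses all same-label fragments jointly; both
properties are pinned by tests, including equivalence with a brute-force
densely-resampled oracle on randomized curve sets.  A sulcus counts as
found when this mean distance is strictly below tau = 10 mm — roughly the
largest distance between neighbouring sulci, so anything farther is sooner
a different sulcus than a displaced one; a distance of exactly 10 mm is not
a match.

The summary table reports, per individual, total curves on the endocast
(TC-E) and brain hull (TC-B), distinct sulci on each (NS-E, NS-B), curves
found in both (NC-EB), and endocast curves with no brain correspondence
(NS-EB), plus the matched ratio NC-EB/TC-E.  The mean row rounds half-up to
integers, matching the convention of printing integer counts; the mean
ratio is the mean of per-row ratios, not the ratio of means.

Two per-vertex maps support interpretation.  The distance map extrapolates
per-curve mean distances over the endocast by inverse-distance weighting
within a 10 mm influence radius (values cannot overshoot the input range);
vertices whose nearest curve failed the criterion are sentinel-masked, as
are vertices beyond every curve's influence.  The displacement map is the
exact point-to-triangle distance from each endocast vertex to the deformed
hull, stored raw and clipped at 5 mm for rendering on a fixed colour scale.

## Reproducibility and sizes

Every stage is deterministic given the run seed, which fans out to
per-stage seeds through a fixed counter scheme, so stages rerun from disk
see the same randomness as a full run; rerunning a configuration reproduces
all outputs bit-identically.  Default problem sizes — 1 mm voxels on a
~126^3 grid, 100,000-face surfaces, 2,000-face registration copies, 600
control points, 40 optimizer iterations — were chosen so a complete
phantom analysis finishes in a few minutes on a single CPU while leaving
every contract measurable; all of them are ordinary config values.
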