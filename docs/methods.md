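# Methods

## Scope and model

`stapplan` plans a straight retrofacial drilling access from the mastoid
surface of the temporal bone (TB) to the proximal surface of the stapedius
muscle (SM), treating the facial nerve (FN), sigmoid sinus (SS) and
vestibulocochlear system (VC) as clearance obstacles. Planning operates on
triangulated surfaces only; bone density, soft-tissue deformation and drill
kinematics are out of scope. Input conventions are declared, not inferred:
STL coordinates are RAS millimetres (+x right, +y anterior, +z superior).
Meshes may be open — every operation works on triangle soups — and a face
count above 200 000 only triggers a warning, since exporter caps are a
pipeline choice, not an algorithmic requirement.

## Reference view and rotation convention

The default reference frame emulates the posterior-tympanotomy view: the
viewing axis runs lateral → medial on the surgery side (−R for a right ear),
up is superior, and screen-right completes the right-handed triad. Instead
of a manual view alignment, the tool auto-selects this frame and validates
it with a plausibility check: the FN centroid must be strictly proximal
(shallower) to the SM centroid along the viewing axis. A user-supplied frame
overrides the default; the check still runs and only warns.

Candidate orientations rotate the scene by roll (about the view-plane
anterior–posterior axis) then yaw (about the inferior–superior axis), both
about the SM centroid as pivot. A fixed pivot keeps the target stationary in
every projected view, which makes projections comparable across the grid;
the roll-then-yaw order is a documented convention (the two differ only by
a second-order reparameterization of the same grid). "Yaw" is read as the
cervical-rotation (inferior–superior) axis. Left-sided cases are mirrored
across the sagittal plane onto the canonical right-side frame before
planning: one code path, and mirror invariance of every scalar metric is a
tested property. Reported angles are therefore in the canonical convention.

## Projection analysis

Each structure's silhouette is the union of its projected triangles,
computed with exact polygon clipping (GEOS via shapely, snap tolerance
1e−6 mm); silhouette accuracy is set by the input tessellation (≈0.5 % area
deficit for the phantom's 1280-face ellipsoids). A structure face is
*proximal* when its centroid is strictly shallower than the most lateral SM
vertex — the conservative reading: anything that could stand in front of any
part of the muscle counts as blocking. The exposed SM subtracts all six
obstacle polygons (proximal and distal); a configuration flag
(`subtract_distal_from_exposure`) switches to proximal-only subtraction,
because distal structures lie behind the muscle and arguably cannot occlude
it — the as-written rule is the default, and for anatomies whose distal
structures do not overlap the SM silhouette (including all phantoms here)
the two modes coincide.

The drillable region subtracts from the exposed SM every **proximal**
obstacle dilated by the MSD; the SM's own boundary is not eroded, and distal
structures are excluded because drilling stops at the SM's proximal surface
(the corridor stage re-checks clearance in full 3D anyway). Dilation discs
are 256-gon buffers with the radius inflated by the secant factor
1/cos(π/256) ≈ 1.00008, so the polygonal dilation *covers* the exact disc
and the safety margin holds by construction rather than up to buffer error.
The drilling target is the centroid of the drillable region; if the
centroid falls outside (non-convex or multi-part regions) the pole of
inaccessibility of the largest component is used, so the target always lies
strictly inside. The 3D target is recovered by casting the view ray through
the 2D target onto the first (most lateral) SM surface intersection.

Two distance families are reported separately because they answer different
questions: `dist_sm_*` (target center → structure polygons, proximal or
distal — the surgeon's "how far is the nerve from where I aim") and
`exposed_to_*` (exposed SM → proximal polygon — the quantity entering the
safety score).

## Safety score and selection

S(i) = α·ASM/maxASM + β·DFN/maxDFN + γ·DSS/maxDSS + δ·DVC/maxDVC
− θ·|Roll|/max|Roll|, weights (0.6, 0.6, 0.6, 0.3, 1.2). Numerical choices:

* Roll enters by magnitude — the penalty prices how much the head must be
  rotated, not the direction.
* Yaw never enters the score; it breaks ties and is reported.
* Normalizer maxima run over feasible orientations only (maxima over
  undefined distances are meaningless); a term with a zero or undefined
  normalizer contributes 0.
* A structure absent from a projection contributes 0 rather than a large
  distance, so views that merely clip a structure out of frame are not
  rewarded.
* Ties prefer the smallest |roll| + |yaw|, then the smallest |roll|, then
  grid order — deterministic, and biased toward the least head repositioning.

## Corridor

The corridor is a truncated cone: small base = drill tip diameter on the
target, axis along the optimal trajectory, entry at the *most lateral*
intersection of the trajectory with the TB (the outer cortex). The
half-angle is maximized by bisection (tolerance 0.05°, cap 45°) under the
constraint that the lateral surface, sampled at 64 circumferential × 32
axial stations, keeps ≥ MSD from the FN/SS/VC meshes in full 3D — the 2D
drillable region seeds the trajectory, but the cone sweeps territory off
the projection plane, so clearance is certified against the meshes. TB and
SM are not obstacles (the one is the material being drilled, the other the
target). The 45° cap avoids degenerate near-hemispherical corridors and is
configurable. Clearance uses exact point–triangle distances with
axis-aligned bounding-box prefiltering; an independent 4×-density resample
re-certifies the final angle in the tests. Note a consequence of applying
the MSD to the cone *surface*: a zero-angle corridor (the bare drill
cylinder) already requires the trajectory axis to clear each obstacle by
MSD + r_drill, which is stricter than the 2D target rule; narrow SM–FN gaps
therefore fail at the corridor stage even when a 2D drillable region exists.

Depth guidelines along the axis: SM thickness (chord of the axis through
the SM, with a 0.05 mm lateral jitter retry for tangential numerical
misses), depth of the SM behind the FN (deepest FN surface point projecting
inside the drill perimeter; when none does — always the case when
MSD > r_drill — the FN surface point nearest the axis), and TB-to-target
drilling depth.

## Feasibility classification

Strict thresholds, boundary values fail: unfeasible unless exposure > 25 %,
SM–FN distance > 0.8 mm and skull-plane corridor diameter > 3 mm; easy when
additionally exposure > 40 %, else difficult. A case without a drillable
orientation, or whose corridor is infeasible, has the corresponding metrics
absent and classifies unfeasible. The skull-plane diameter is the cone base
diameter at the entry plane.

## Synthetic phantoms and ground truth

The phantom module emulates segmentation *outputs* (not images): five
closed analytic primitives for a right ear. SM: ellipsoid, semi-axes
0.45 mm (depth) × 0.6 mm (width) × belly/2 (default belly 3.0 mm,
matching the 2–4 mm anatomical range); FN: vertical 0.6 mm-radius cylinder
anterior to the SM, its projected strip `sm_fn_gap_mm` from the SM center
and its medial surface `sm_depth_behind_fn_mm` lateral to the SM pole
(defaults 2.0 and 1.7 mm); an optional occluding plate merged into the FN
covering exactly `occlusion_fraction` of the SM silhouette from superior;
SS: posterior 2 mm-radius cylinder ≈4.5 mm from the target; VC: ellipsoid
entirely distal, ≈3.5 mm anterior; TB: flat slab with outer cortex 12 mm
lateral (a planar stand-in for the mastoid surface; entry-point behavior on
curved cortices is tested separately against a spherical shell). Phantom
cylinders use a mirror-symmetric triangulation (side quads fanned around
on-surface waist vertices) so the face-level proximal/distal split respects
the scene's axial mirror symmetry — with diagonal-split quads, roll-flip
symmetry of the score field holds only to tessellation error.

Because every occluder projects to an axis-aligned strip, exposure and the
drillable region reduce to ellipse-chord segments with closed-form areas
and centroids; the maximal cone angle is computed independently against
exact point-to-primitive distances (cylinder/box signed forms, a bounding
sphere for the ellipsoid, which never governs). The truth never touches the
mesh pipeline. Truths are defined at the (0, 0) reference view; planner
recovery tests therefore pin the grid to that single orientation, since the
optimizer may legitimately find better views. The scenario catalogue spans
exposures {0, 25, 30, 40, 50, 100} %, gaps {0.5, 0.8, 1.0, 2.0} mm and
depths {0.1, 1.7, 4.7} mm. Default mesh density keeps every structure well
under 10 000 faces.

What the phantoms do **not** emulate: segmentation noise and topology
defects, curved FN and SS courses, population anatomical variability, and
partial-volume artifacts. Passing the suite shows the geometry engine is
correct and self-consistent, not that clinical segmentations of a given
scanner will be this clean.

## Verification oracles and tolerances

Three independent routes check the projection analysis: (1) closed-form
ellipse/chord algebra (agreement within 2 %, absolute floor 0.005 mm² for
sliver regions where relative error is meaningless); (2) a pixel-counting
re-implementation at 0.02 mm resolution — pixel-center inclusion tests
(unbiased for areas) and a Euclidean distance transform for the dilation,
with the threshold shifted by half a pixel to remove the center-to-boundary
discretization bias (agreement within 1 %, floor 0.01 mm²); (3) full-
pipeline recovery of phantom truth (exposure ±0.03, SM–FN distance
±0.1 mm, depth behind FN ±0.15 mm — the occluder plate is 0.2 mm thick and
x-centred on the FN tube, so its depth is defined to ±0.1 mm — thickness
±0.05 mm). Corridor maximality is certified by a 4×-density resample at
θ* (margin 0.05 mm) and a violation check at θ* + 0.1°.

Test-scale problem sizes: property tests that sweep the grid use a
10°-step (7 × 7) grid and recovery tests a single pinned orientation; the
2° clinical protocol remains the tool default and is exercised for grid
construction and in the CLI.

## Known limitations

* Orthographic projection only (the surgical microscope view); no
  perspective or endoscope model.
* The proximal/distal split is binary at the most-lateral-SM-point depth; a
  per-ray comparison would be less conservative for strongly curved FNs.
* The literal all-polygon subtraction can count far-behind structures as
  occluders if their silhouettes overlap the SM; the flag documented above
  exists for that case.
* Corridor clearance applies the MSD to the cone surface (see above), which
  is conservative by one drill radius relative to the 2D target rule.
* The skull map projects entries of the *rotated-scene* trajectories onto
  the fixed TB mesh; for large rotations these entry points are a
  visualization aid, not drilling coordinates.
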