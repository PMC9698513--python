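# Methods

This note documents the models, algorithms, numerical choices, and the
synthetic data on which the engine is validated.

## Coordinate conventions

Image coordinates put the origin at the top-left pixel centre, x
rightward, y downward, units pixels. Quad and marker corners are ordered
counter-clockwise on screen starting at the marker's canonical top-left.
The marker/camera basis (A) is the camera frame: x right, y down, z along
the optical axis, units metres; a visible marker has translation z > 0.
The body-tracking basis (BT) is whatever frame a keypoint source reports;
the calibration below relates the two.

## Marker codebook

Markers are square binary payload grids (default 4×4, 50 ids) inside a
one-cell black border; bit polarity is black = 1 (thresholded ink is the
signal). Codewords are drawn by a seeded greedy search that accepts a
candidate only if (a) its rotational Hamming distance to every accepted
codeword — the minimum over all four relative quarter-turns — is at least
`min_hamming` (default 3), and (b) its distance to each of its own
non-trivial rotations is also at least `min_hamming`. Constraint (b) is
deliberately stronger than merely excluding 4-fold-symmetric patterns:
it makes the *rotation*, not just the identity, recoverable under the
full error-correction budget of `floor((min_hamming−1)/2)` mis-read
cells. The search budget is bounded; exhausting it raises an explicit
capacity error rather than looping. A 4×4 grid at distance 3 places 50
ids comfortably (the greedy search typically accommodates several
hundred).

## Detection pipeline

1. **Adaptive threshold.** A pixel is foreground iff its intensity is
   below the local mean over a `window × window` neighbourhood (default
   23 px, reflect-padded) minus an `offset` (default 7). Being
   mean-relative, the segmentation is stable under slowly varying
   illumination and under global affine intensity changes of reasonable
   gain. Note the complement of mean-relative thresholding: the deep
   interior of a dark region larger than the window reverts to
   background. For markers this only perforates the interior of the
   border ring at close range; the outer boundary survives, and quad
   extraction fills component holes before tracing it.
2. **Quad extraction.** Foreground connected components are traced
   (outer boundary only, after hole filling) and simplified with
   Douglas–Peucker at `epsilon_frac × perimeter` (default 0.05). Because
   Douglas–Peucker anchors the endpoints of a closed curve, the contour
   is first rotated to start at the point farthest from the centroid — a
   guaranteed vertex of a convex outline; without this, axis-aligned
   squares whose trace starts mid-edge simplify to five vertices.
   Exactly-4-vertex convex outlines above `min_area` (default 100 px²)
   with corner separation above 5 px survive. Vertex placement by
   Douglas–Peucker is only approximate, so corners are re-derived by
   assigning every dense contour point to its nearest edge, fitting a
   total-least-squares line per edge (corner neighbourhoods excluded),
   and intersecting adjacent lines.
3. **Sub-pixel refinement.** Each edge is refined on the grayscale
   image: intensity profiles are sampled along the edge normal at 24
   stations, each profile's edge location is estimated by the centroid
   of its gradient (which has far less phase-dependent bias than
   interpolating the mid-level crossing), a TLS line is fit per edge,
   and corners are the line intersections. Profiles with ambiguous
   (multi-crossing) structure are discarded; if an edge keeps too few
   profiles the unrefined corners are kept. The estimator is invariant
   under affine intensity maps since the mid-level and gradient are
   computed per profile. On rendered frames this reaches ~0.01 px RMS.
4. **Rectify and decode.** A 4-point homography maps the quad to the
   canonical bordered square; each cell is sampled at 5×5 interior
   points (bilinear), bit-assigned by majority against the mid-level of
   the sampled values, the border must be ≥ 90% foreground, and the
   payload is matched against the dictionary under all four rotations
   within the correction capacity. Duplicate detections of one id keep
   the lowest decode Hamming distance, ties broken by larger area.

## Pose estimation

The pinhole model (fx, fy, cx, cy; no distortion) projects the four
canonical marker corners (a square of the known printed side length,
z = 0, centred at the origin). Pose is parameterized as axis-angle plus
translation and refined by a small dense Levenberg–Marquardt loop
(λ₀ = 1e-3, multiplicative λ updates, central-difference Jacobian,
cost-decrease tolerance 1e-10, 100 iteration cap) on the sum of squared
corner reprojection residuals, initialized from the DLT homography of
the four correspondences decomposed into [r1 r2 t] with SVD
orthogonalization. The cost after every accepted step is recorded, so
the monotone non-increase of the residual is a testable property rather
than an assumption. Planar targets admit a two-fold pose ambiguity near
frontal views; when the refined residual stays above 1e-3 px the solver
restarts from tilt-mirrored initializations and keeps the candidate with
the lower RMS residual. No lens distortion is modelled anywhere — the
synthetic camera is distortion-free, which keeps the projective oracle
exact; real-camera use would require undistorting corners first.

## Frame calibration

With four correspondences X₁..X₄ between the bases, the linear part is
R_BTA = D_A · D_BT⁻¹ where D = [X₂−X₁ | X₃−X₁ | X₄−X₁], and
T_BTA = X₁_A − R_BTA·X₁_BT; the map interpolates all four points exactly
in exact arithmetic. R_BTA is treated as a general invertible 3×3
matrix — no orthonormality is imposed, because the four-point
construction yields an affine map and projecting it would discard
genuine scale/shear differences between the two trackers; an optional
polar projection onto the nearest rotation is available behind a flag
for users who want a rigid map. The solve is refused when the condition
number of D_BT exceeds 1e6 (configurable): a near-coplanar registration
tetrahedron amplifies keypoint noise roughly in proportion to that
condition number, which the noise-robustness tests measure directly.
One naming clash is worth recording: the transform is conventionally
described as mapping *from* the marker basis, but the defining equation
consumes BT coordinates and produces A coordinates; the implementation
follows the equation and names the direction explicitly
(`apply_transform`: BT → A, `invert_transform` for the reverse).
The joint labels (shoulder, elbow, left hand, right hand) fix the
correspondence order for UX only; the solved transform is invariant
under joint permutations (property-tested).

## Atlas model and selection

The acquisition grid is 35 longitudinal × 10 lateral positions with a
40-frame sweep over (−β, +β) per point, in B-mode and Doppler; two 10 s
Doppler clips attach to fixed grid points. β is not a protocol constant
of the recording hardware but a configuration value; the default is 30°.
The longitudinal display rule i = (l/L)·n is printed without rounding or
clamping; the engine uses the single normative binning rule

    index(x; lo, hi, n) = clamp(floor((x − lo)/(hi − lo) · n) + 1, 1, n)

so l = 0 shows the first image, l = L the last (closed final bin), and
all preimages are contiguous equal-width intervals. The same rule bins
the sweep angle over (−β, +β) and — as a documented extension, since
only the lateral *recording* grid is part of the protocol — the lateral
offset over (−half_width, +half_width), default half-width 4 cm.
The wrist anchor is the registered *hand* point: registration uses the
hand joint while the display rule is phrased elbow-to-wrist, so
hand ≈ wrist is assumed and L is the registered elbow–hand distance.
The sweep angle is the signed angle between the probe axis (marker
plane normal) and the arm surface normal within the (axis, normal)
plane; the session builds arm models with the surface normal oriented
toward the camera, which both matches a forearm presented to a webcam
and keeps the angle away from the ±180° wrap. Doppler clips play when
the probe holds within the clip's bin for ≥ 0.5 s; the frame index is
elapsed time × fps, looping.

## Synthetic data

The generators replace three hardware inputs and define the conditions
under which every quantitative claim in the test suite holds.

* **Scenes.** Frames composite perspective-projected markers (with a
  one-cell white quiet zone) over flat, noise, or smooth-texture
  backgrounds. The marker is warped by the exact pinhole homography; the
  projected bounding box is rasterized at 8× supersampling with bilinear
  sampling of a 16×-upsampled marker image and box-downsampled, so edge
  coverage varies continuously and sub-pixel corner ground truth is
  meaningful to ~0.01 px. Scripted occluders are opaque rectangles over
  given frame intervals. Ground truth (pose and projected corners per
  marker) is emitted alongside every frame; everything is deterministic
  given the script seed.
* **Keypoints.** The four tracked joints follow smooth seeded
  joint-angle splines with constant upper-arm and forearm lengths;
  optional i.i.d. Gaussian noise (σ in metres) is added per frame and
  coordinate. Streams are generated directly in 3-D: the engine
  consumes any keypoint source honouring this contract, and the deep
  body-pose network of the original system is out of scope by design.
* **Atlas.** One procedural image per (mode, u, v, a) key: a
  position-dependent band pattern plus a 16-bit machine-readable strip
  encoding the key itself, so selection correctness is assertable from
  pixels. Doppler frames add seeded speckle in the flow channels; two
  clips (default 15 fps × 10 s) are written as frame sequences.

What the synthetic data does **not** emulate: lens distortion, motion
blur, sensor noise correlated with illumination, deformable skin and
clothing, body-tracker systematic biases, and real ultrasound image
content. Passing tests therefore demonstrate correctness of the
geometry, decoding, calibration algebra, selection logic, and policies —
not robustness to real webcam imagery.

## Validation studies and problem sizes

The acceptance suite (tests/test_acceptance.py and
scripts/acceptance.py, which share `arustrain.evaluation`) runs: the
default 35×10×40 atlas generation with count/clip verification; 200
seeded affine calibration recoveries (≤ 1e-9 relative) cross-checked
against an independent stacked 12-equation least-squares solve, plus
coplanar rejection; a 200-frame rendered corpus (tilt ≤ 45°, marker
≥ 80 px, flat background) requiring 100% detection and ≤ 0.5 px corner
RMS, with pose closure (≤ 0.1°, ≤ 0.1% of range) measured on noise-free
corner projections of the same poses; an exhaustive bin audit for all
n ≤ 64 sampled at bin interiors plus endpoint checks; a scripted
registration (four 18-frame dwells) followed by a 200-frame
elbow-to-wrist sweep requiring a non-decreasing longitudinal log
covering 1..35 and ≥ 99% key agreement with ground-truth geometry, plus
hold/lost accounting for 3- and 10-frame occlusions against
hold_frames = 5; and 50-seed Monte-Carlo noise curves (registration
transfer error vs keypoint σ ∈ {1, 5, 20} mm; pose translation error vs
corner σ ∈ {0.1, 0.5, 1} px) required to be monotone.

## Known limitations

* The detector assumes markers at least ~60 px across; far smaller
  markers fall below `min_area` or lose the border check.
* Sweep-angle selection degrades near grazing probe orientations
  (|angle| ≫ β), where the clamp hides orientation detail.
* The registration dwell detector (translation σ < 3 mm over ≥ 15
  frames) assumes a cooperative script; jittery real input would need a
  robustified dwell rule.
* `hold_frames` trades decode-miss bridging against occlusion masking;
  the default 10 (~0.3 s at 30 fps) matches the session studies, which
  use 5 for compactness of the occlusion arithmetic.
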