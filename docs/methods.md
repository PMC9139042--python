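# Methods

## The measurement model

The package treats a walking video as a stream of per-frame 2D joint
keypoints in a fixed skeleton layout (COCO 18-joint by default; BODY_25 is
down-mapped). Coordinates are image pixels, origin at the top-left pixel
center, x right, y down, 0-based, subpixel reals; a keypoint with
confidence 0 is "undetected" and ignored everywhere. When the upstream
estimator emits per-joint heat maps instead of coordinates, joint centers
are located with the geometric centroid formula
x = Σ a_ij·j / Σ a_ij, y = Σ a_ij·i / Σ a_ij over pixel centers.

Frames are sampled every 0.3 s. Two frame-count conventions circulate for
this sampling and both are implemented as separate operations:
`sample_timestamps` counts round-half-up(duration / interval) — the
convention all pipelines use, since it matches the sampling description
(3 s → 10 frames) — while `expected_djnp_frame_count` preserves the
duration × fps × 0.3 product (10 s at 30 fps → 90) for fidelity to the
printed worked example. The two coincide only when fps·interval² = 1.
Round-half-up (⌊x + 0.5⌋) is used for every count-from-product in the
package because it reproduces all printed examples, including the 70/30
split sizes 71/31 (from 102) and 76/32 (from 108).

A **DJNP** merges the detected keypoints of all sampled frames into one
point cloud tagged with (joint_id, sample_index, timestamp). Superposition
is plain — no decay or temporal weighting — and rendering draws each point
as a filled disc (radius 6 px on a 1080×1920 canvas by default; monochrome,
per-joint coloring optional) so identical inputs yield byte-identical PNGs.
For feature extraction images are bilinearly resized to the extractor's
input size.

The **IPI** bins each sample's points into square blocks (default edge
40 px, i.e. 27 columns across a 1080 px frame; the block size is a free
parameter, chosen to resolve body-width displacements). Occupancy is exact
point-in-block membership with half-open blocks [k·e, (k+1)·e).

## Side angles, SR, displacements, MD

The side of the body is represented per sample by the centroid of its
detected limb joints (shoulder, elbow, wrist, hip, knee, ankle). A centroid
is robust to single-joint dropout; a single named landmark would not be.
Θ_l and Θ_r are the acute angles ([0°, 90°]) between the total-least-squares
line through the side-centroid trajectory and the image vertical (TLS via
SVD of the centered trajectory; a trajectory of identical points has angle
0 by convention). SR = Θ_l/Θ_r, with SR = 1 when both angles are 0 and +inf
when only Θ_r is 0. Ratios within ε = 0.05 of 1 are labelled "straight";
above, "right"; below, "left". The same ε and rules apply to
MD = D_r/D_l, where D_side is the Euclidean distance of the side centroid
between consecutive samples; intervals with missing side joints are
recorded as missing rather than imputed.

Two geometric facts matter when interpreting these ratios under the
recording geometry (camera height h = 1 m, standoff 2 m, walk length 5 m):

1. **The image angle amplifies the ground drift.** For a walk starting a
   distance Z0 from the camera with ground-plane drift θ, a side-centroid
   trace is a straight image line with slope
   dx/dy = (tanθ·Z0 ± w̄)/(h − ȳ), where w̄ ≈ 0.155 m is the mean lateral
   side offset and ȳ ≈ 0.80 m the mean side-joint height. With
   Z0/(h − ȳ) ≈ 35, even a 4° drift pushes both side angles above 59°, and
   at large drifts both saturate toward 90°, compressing SR back toward 1.
   SR's *sign* (above/below 1) still indicates the drift direction, but its
   magnitude is not proportional to the drift. `estimate_drift_angle`
   therefore inverts the projection: averaging the two signed side slopes
   cancels the ±w̄ term, and θ = atan(mean_slope·(h − ȳ)/Z0) (fixed-point
   in Z0 for toward-walks, closed form for away-walks). On noise-free
   simulated walks this recovers the drift angle to within ~0.3°.
2. **The dominant displacement side is contralateral to the skew.** A drift
   toward image right makes the *left* side trace sweep the longer image
   path, so SR > 1 arrives together with MD < 1. MD answers "which side
   moved most", not "which way does the body skew"; the two are distinct,
   complementary readouts.

Horizontally mirroring a DJNP (x → W−1−x with left/right joint relabelling)
maps SR → 1/SR and MD → 1/MD exactly and swaps left/right labels; this
antisymmetry is asserted on random point clouds.

## The synthetic walker

`synthetic_gait` emulates the study conditions, not pixels: a 1.70 m stick
figure with COCO18 joints at standard body proportions walks a 5 m level
path at 0.68 m/s (group means 0.69/0.68 m/s, sd 0.08, drawn per sample),
toward or away from an ideal pinhole camera 1 m above the ground and 2 m
from the path end (1080×1920 portrait, 900 px focal length ≈ a phone
wide-angle lens chosen so the full body stays in frame over the whole
path). Skew is a constant drift angle of the walking line (positive =
image right); the skew class draws |θ| uniformly from 4–12° — separable
from straight walking but not trivially so — and the straight class from
|θ| ≤ 0.8°, below the 1° labelling threshold. An optional lateral trunk
lean adds upper-body asymmetry. Keypoints get Gaussian pixel jitter
(default sd 2 px, typical pose-estimator noise at 1080p); joints projecting
outside the frame are recorded as undetected, and the sequence is truncated
with a warning if the neck leaves the frame.

Limb swing is sinusoidal at the step frequency (1.5 Hz at this slow speed)
with arms antiphase to legs — but **mirror-symmetric across sides**: left
and right limbs move in phase. Real gait alternates sides; under
perspective projection an alternating swing makes consecutive-interval side
displacements differ by large factors, so no per-interval MD invariant
could hold for it. The symmetric swing makes the zero-noise straight walker
exactly bilaterally symmetric, so SR = 1 and every MD = 1 hold to floating
precision by construction, which is what the straight-walk invariants
verify. Consequences: passing tests demonstrate the *measurement* pipeline
(projection, centroids, TLS, ratios) and class separability, not robustness
to stride-phase asymmetry or to appearance-level pose-estimator failure
modes; those require recorded data.

Dataset generation derives per-sample seeds from one master seed
(`default_rng(master_seed)`), so a corpus regenerates byte-identically.

## Classification

`block_stats` is the default feature extractor: resize to 224 px (227 for
the AlexNet-named alias, matching that backbone's input), 16×16 block means
and variances via exact partial sums, plus the 7 Hu moment invariants — 519
deterministic dimensions. The eight CNN names from the original grid are
registered as aliases so the full 8×3×4×20 = 1920-cell protocol runs
without downloads; a torch backend can be requested explicitly and fails
loudly when unavailable. Batch size has no effect on non-trained
extractors and is carried purely as protocol metadata.

Classifiers are standardize-then-fit sklearn pipelines: L2 logistic
regression (lbfgs), SVM (linear kernel by default), and naive Bayes. NB
defaults to the kernel-density variant (per-class Gaussian KDE over the
standardized feature vector, Scott bandwidth): the skew class is inherently
multimodal (left/right drift × toward/away direction), which a single
Gaussian per class underfits — Gaussian NB remains selectable via
`nb_mode="gaussian"`. Splits are stratified 70/30 with round-half-up train
sizes; the same 20 split seeds are shared across the other grid axes. The
positive class for index computation defaults to the class with the smaller
test set — the only assignment under which all six published best-model
indices (kappa 0.71, accuracy 0.86, sen 0.87, spe 0.84, PPV 0.84, NPV 0.87
on a 31/32 test split) are mutually consistent, as the reconstruction
oracle verifies. Failed grid cells are recorded with their error message,
never dropped. Summary filtering uses an inclusive kappa threshold by
default, because published tables print kappa rounded to 2 dp and filtering
"greater than 0.59" must keep rows printed as 0.59.

## Numerical choices and degenerate inputs

- TLS direction from SVD; orientation normalized to vy ≥ 0 so signed
  angles lie in (−90°, 90°].
- Ratio sentinels: 0/0 → 1 ("straight" by convention), x/0 → +inf
  (labelled "right"). Undefined confusion-matrix denominators are flagged
  by name, not NaN-propagated.
- An all-zero heat map has no centroid and raises; an empty `people` array
  is a zero-person frame, flagged but not an error.
- Oversized IPI blocks degrade to a single-block grid with a warning.
- Kappa = (p_o − p_e)/(1 − p_e); p_e = 1 (degenerate single-cell margins)
  returns kappa 0.

## Problem sizes

Tests and the acceptance script use the corpus size the protocol
prescribes: 102 straight + 108 skewed DJNPs, the full 1920-cell grid, and
5-seed means for the end-to-end recovery checks. The whole suite runs in
about one minute on one CPU; the acceptance script in under one minute.

## Known limitations

- The walker is kinematically stylized (symmetric swing, no forward lean,
  planar limbs); it validates geometry and protocol, not biomechanics.
- SR magnitude saturates at large drifts under this camera geometry (see
  above); use `estimate_drift_angle` for a calibrated drift readout.
- Pretrained CNN features are interface-compatible but not bundled; the
  published per-backbone rankings are not reproducible without the original
  recordings, and the synthetic corpus is deliberately cleaner than real
  data (near-ceiling indices).
- Physical units require a user-supplied pixel-per-meter scale or the
  camera model; no self-calibration is attempted.
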