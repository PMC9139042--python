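# gaitskew

Quantifying and classifying walking skewness from 2D pose keypoints.

Markerless pose estimators (OpenPose and kin) turn an ordinary phone video of
a person walking into per-frame 2D joint coordinates. `gaitskew` takes such
keypoint streams and answers a clinically motivated question: *is this person
walking straight, or drifting laterally?* Poor postural control during
walking is associated with a range of neurological and musculoskeletal
conditions, and a phone-camera screen for it needs no wearables. The package
is aimed at movement-analysis and rehabilitation researchers who already have
pose-estimator output (or want simulated walks to prototype on).

## Method

Three representations are built on top of the keypoint stream:

- **DJNP (dynamic joint node plot)** — frames are sampled every 0.3 s and all
  detected joint nodes are superimposed into one time-indexed point cloud,
  rendered as a raster image. A 3 s video yields 10 sampled frames.
- **IPI (iso-block postural identity)** — a uniform grid of equal square
  blocks (default 40 px) fused with the DJNP; per-sample block occupancy
  localizes the body at each sampling time.
- **Skew metrics** — for each body side (shoulder, elbow, wrist, hip, knee,
  ankle), the per-sample side centroids are fit with a total-least-squares
  line, and Θ_l, Θ_r are the acute angles those lines make with the image
  vertical. The skewness ratio is

      SR = Θ_l / Θ_r        (SR > 1: skew right, SR = 1: straight, SR < 1: skew left)

  and per sampling interval the side displacements D_{r,i−1,i}, D_{l,i−1,i}
  give the dominance ratio MD = D_r / D_l identifying the side that moved
  most. A calibrated estimator inverts the camera projection to recover the
  ground-plane drift angle from the side-trace slopes.

For classification, DJNP images are reduced to deterministic `block_stats`
features (16×16 block means and variances plus 7 Hu moments, 519 dims) — or
optional pretrained-CNN backbones — and swept over a model grid of
8 extractors × 3 classifiers (LR, NB, SVM) × 4 batch sizes × 20 random 70/30
splits = 1920 models, each scored on its test set with Cohen's kappa,
accuracy, sensitivity, specificity, PPV and NPV:

      κ = (p_o − p_e) / (1 − p_e)

Because no recorded corpus is distributable, a `synthetic_gait` module
simulates the original recording geometry (phone camera 1 m above the
ground, 2 m from the end of a 5 m walk at ≈0.68 m/s) with a controllable
lateral drift angle, producing labeled keypoint streams and DJNP images for
every stage.

## Worked example

```python
import gaitskew as gs

walk = gs.simulate_walk(gs.WalkConfig(skew_angle=8.0, noise_sd=2.0), seed=3)
print("label:", walk.label, "| frames:", len(walk.frames),
      "| duration: %.2f s" % walk.truth["duration"])

m = gs.compute_skew_metrics(walk.djnp)
print("theta_l = %.1f deg, theta_r = %.1f deg, SR = %.3f -> %s"
      % (m.theta_l, m.theta_r, m.sr, m.skew_label))
print("drift estimate: %.2f deg (true 8.00)"
      % gs.estimate_drift_angle(walk.djnp, direction="toward"))

grid = gs.build_ipi(walk.djnp, block_edge=40)
print("IPI: %d x %d blocks, %d occupied"
      % (grid.n_rows, grid.n_cols, int(grid.occupancy.any(axis=0).sum())))
```

prints

```
label: skew | frames: 25 | duration: 7.35 s
theta_l = 79.8 deg, theta_r = 76.0 deg, SR = 1.050 -> right
drift estimate: 7.68 deg (true 8.00)
IPI: 48 x 27 blocks, 93 occupied
```

The 5 m walk at 0.68 m/s lasts 7.35 s and yields 25 sampled frames. The
left-side trace leans 3.8° further from vertical than the right, so SR > 1
flags a rightward skew; inverting the projection recovers the simulated 8°
drift to within about 0.3°. The walker's joints occupied 93 of the 48×27
IPI blocks over the walk.

The same pipeline is scriptable from the shell:

```sh
gaitskew simulate --out corpus --n-straight 102 --n-skew 108 --seed 42
gaitskew sweep --manifest corpus/manifest.csv --out results.csv --seeds 20
gaitskew report --results results.csv --out summary.json --kappa-threshold 0.59
```

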