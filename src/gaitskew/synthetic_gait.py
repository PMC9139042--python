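"""Synthetic articulated-walker keypoint sequences with controllable skew.

Emulates the study recording geometry — a phone camera 1 m above the ground
and 2 m from the end of a 5 m level walking path, 1080x1920 portrait video —
so that every downstream stage (DJNP construction, IPI/SR/MD metrics,
classification) is testable without recorded data.

The walker is a 3D stick figure with COCO18 joints at standard adult body
proportions. It advances along a straight ground line at constant speed;
lateral skew is modelled as a constant drift angle of that line relative to
the camera axis (positive = drift toward image right), optionally combined
with a lateral trunk lean. Limbs swing sinusoidally at the step frequency.
The swing is mirror-symmetric across the body (left and right limbs move in
phase, arms antiphase to legs within a side): this makes the zero-noise
straight walker exactly bilaterally symmetric, so SR = MD = 1 holds by
construction. Real gait alternates sides; see the methods note for what this
simplification does and does not exercise.

Joints are projected through an ideal pinhole camera, sampled every 0.3 s,
and jittered with Gaussian pixel noise. Joints that project outside the
image are recorded as undetected (confidence 0), matching how a pose
estimator reports occluded or out-of-frame parts; if the neck leaves the
image the remaining samples are truncated with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .djnp import DJNP, CanvasSpec, build_djnp, render_djnp, save_png
from .layouts import COCO18
from .pose_io import PoseFrame, sample_timestamps

# COCO18 joint geometry for a 1.70 m adult: height above ground (m),
# lateral half-offset from the body midline (m), sagittal swing amplitude (m)
# and swing phase group (+1 legs, -1 arms, 0 none).
_JOINT_GEOMETRY: dict[str, tuple[float, float, float, int]] = {
    "Nose": (1.60, 0.00, 0.00, 0),
    "Neck": (1.45, 0.00, 0.00, 0),
    "RShoulder": (1.40, 0.19, 0.00, 0),
    "RElbow": (1.10, 0.21, 0.07, -1),
    "RWrist": (0.82, 0.22, 0.15, -1),
    "LShoulder": (1.40, 0.19, 0.00, 0),
    "LElbow": (1.10, 0.21, 0.07, -1),
    "LWrist": (0.82, 0.22, 0.15, -1),
    "RHip": (0.92, 0.10, 0.00, 0),
    "RKnee": (0.50, 0.11, 0.09, 1),
    "RAnkle": (0.08, 0.10, 0.18, 1),
    "LHip": (0.92, 0.10, 0.00, 0),
    "LKnee": (0.50, 0.11, 0.09, 1),
    "LAnkle": (0.08, 0.10, 0.18, 1),
    "REye": (1.63, 0.03, 0.00, 0),
    "LEye": (1.63, 0.03, 0.00, 0),
    "REar": (1.62, 0.08, 0.00, 0),
    "LEar": (1.62, 0.08, 0.00, 0),
}

#: mean height above ground of the six side-limb joints (m); used when
#: inverting the projection to recover the ground-plane drift angle
MEAN_SIDE_HEIGHT = float(
    np.mean([_JOINT_GEOMETRY[n][0] for n in
             ("RShoulder", "RElbow", "RWrist", "RHip", "RKnee", "RAnkle")])
)

#: vertical bob amplitude of the whole body (m), at twice the step frequency
_BOB_AMPLITUDE = 0.015


@dataclass
class CameraModel:
    """Ideal pinhole camera matching the study recording setup."""

    height: float = 1.0      # m above the ground plane
    standoff: float = 2.0    # m from the end of the walking path
    focal_px: float = 900.0  # focal length in pixels (square pixels)
    width: int = 1080        # portrait 1080p phone video
    frame_height: int = 1920

    def project(self, X: float, Y: float, Z: float) -> tuple[float, float]:
        """World (lateral X, height Y, depth Z) in m -> image pixels."""
        if Z <= 0.05:
            raise ValueError("point at or behind the camera")
        x = self.width / 2 + self.focal_px * X / Z
        y = self.frame_height / 2 + self.focal_px * (self.height - Y) / Z
        return x, y


@dataclass
class WalkConfig:
    path_length: float = 5.0        # m walked per video
    speed: float = 0.68             # m/s, slow free walking
    direction: str = "toward"       # toward or away from the camera
    skew_angle: float = 0.0         # degrees of lateral drift; + = image right
    trunk_lean: float = 0.0         # degrees of lateral upper-body lean
    step_frequency: float = 1.5     # Hz (steps per second)
    swing_scale: float = 1.0        # multiplier on limb-swing amplitudes
    noise_sd: float = 2.0           # px of Gaussian keypoint jitter
    interval: float = 0.3           # s between sampled frames
    straight_threshold: float = 1.0  # deg; |skew| <= threshold labels straight
    camera: CameraModel = field(default_factory=CameraModel)

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.path_length <= 0:
            raise ValueError("speed and path_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if abs(self.skew_angle) >= 45:
            raise ValueError("|skew_angle| must be below 45 degrees")
        if self.direction not in ("toward", "away"):
            raise ValueError("direction must be 'toward' or 'away'")

    @property
    def duration(self) -> float:
        return self.path_length / self.speed


@dataclass
class LabeledSample:
    frames: list[PoseFrame]
    djnp: DJNP
    djnp_image: np.ndarray
    label: str                     # straight | skew
    truth: dict                    # skew_angle, speed, duration, direction


def _joint_world_positions(cfg: WalkConfig, t: float) -> Iterator[tuple[int, float, float, float]]:
    """Yield (joint_id, X, Y, Z) world coordinates at time t."""
    theta = math.radians(cfg.skew_angle)
    s = cfg.speed * t  # distance walked along the path line
    if cfg.direction == "toward":
        z0 = cfg.camera.standoff + cfg.path_length * math.cos(theta)
        cx, cz = s * math.sin(theta), z0 - s * math.cos(theta)
        facing = (math.sin(theta), -math.cos(theta))
    else:
        cx, cz = s * math.sin(theta), cfg.camera.standoff + s * math.cos(theta)
        facing = (math.sin(theta), math.cos(theta))
    right_dir = (facing[1], -facing[0])  # walker's anatomical right, ground plane
    phase = 2 * math.pi * cfg.step_frequency * t
    swing = math.sin(phase)
    bob = _BOB_AMPLITUDE * math.sin(2 * phase)
    lean = math.tan(math.radians(cfg.trunk_lean))
    hip_h = _JOINT_GEOMETRY["RHip"][0]
    for j, name in enumerate(COCO18.joint_names):
        height, half_w, amp, group = _JOINT_GEOMETRY[name]
        side = 1.0 if name.startswith("R") else (-1.0 if name.startswith("L") else 0.0)
        sag = cfg.swing_scale * amp * swing * group
        X = cx + side * half_w * right_dir[0] + sag * facing[0]
        Z = cz + side * half_w * right_dir[1] + sag * facing[1]
        if height > hip_h:  # lateral trunk lean displaces joints above the hips
            X += lean * (height - hip_h)
        yield j, X, height + bob, Z


def simulate_walk(cfg: WalkConfig | None = None, seed: int = 0,
                  canvas: CanvasSpec | None = None) -> LabeledSample:
    """Simulate one recorded walk and its DJNP. Deterministic given (cfg, seed)."""
    cfg = cfg or WalkConfig()
    rng = np.random.default_rng(seed)
    cam = cfg.camera
    frames: list[PoseFrame] = []
    truncated = False
    for k, t in enumerate(sample_timestamps(cfg.duration, cfg.interval)):
        data = np.zeros((COCO18.size, 3))
        neck_ok = True
        for j, X, Y, Z in _joint_world_positions(cfg, t):
            x, y = cam.project(X, Y, Z)
            x += rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0
            y += rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd else 0.0
            conf = rng.uniform(0.75, 1.0)
            if 0 <= x <= cam.width - 1 and 0 <= y <= cam.frame_height - 1:
                data[j] = (x, y, conf)
            else:
                data[j] = (0.0, 0.0, 0.0)
                if COCO18.joint_names[j] == "Neck":
                    neck_ok = False
        if not neck_ok:
            truncated = True
            break
        frames.append(PoseFrame(t, data, COCO18))
    if truncated:
        warnings.warn(
            f"walker left the field of view; sequence truncated to {len(frames)} frames",
            stacklevel=2,
        )
    d = build_djnp(frames, frame_size=(cam.width, cam.frame_height), fps=30.0)
    img = render_djnp(d, canvas)
    label = "straight" if abs(cfg.skew_angle) <= cfg.straight_threshold else "skew"
    truth = {
        "skew_angle": cfg.skew_angle,
        "speed": cfg.speed,
        "duration": cfg.duration,
        "direction": cfg.direction,
    }
    return LabeledSample(frames, d, img, label, truth)


@dataclass
class DatasetRanges:
    """Per-class parameter distributions for generated corpora.

    The straight class drifts uniformly within +/- straight_skew_max (below
    the 1 degree labelling threshold); the skew class draws |skew_angle|
    uniformly from skew_range with a random sign. Speeds are drawn from the
    per-class normal distributions reported for the two groups (mean 0.69 /
    0.68 m/s, sd 0.08) and truncated to a walkable range.
    """

    skew_range: tuple[float, float] = (4.0, 12.0)
    straight_skew_max: float = 0.8
    speed_mean_straight: float = 0.69
    speed_mean_skew: float = 0.68
    speed_sd: float = 0.08
    speed_bounds: tuple[float, float] = (0.4, 1.1)


def _draw_config(label: str, ranges: DatasetRanges, rng: np.random.Generator) -> WalkConfig:
    if label == "straight":
        skew = float(rng.uniform(-ranges.straight_skew_max, ranges.straight_skew_max))
        mean_speed = ranges.speed_mean_straight
    else:
        mag = float(rng.uniform(*ranges.skew_range))
        skew = mag if rng.uniform() < 0.5 else -mag
        mean_speed = ranges.speed_mean_skew
    speed = float(np.clip(rng.normal(mean_speed, ranges.speed_sd), *ranges.speed_bounds))
    direction = "toward" if rng.uniform() < 0.5 else "away"
    return WalkConfig(speed=speed, skew_angle=skew, direction=direction)


def generate_dataset(
    n_straight: int,
    n_skew: int,
    out_dir,
    ranges: DatasetRanges | None = None,
    master_seed: int = 42,
    canvas: CanvasSpec | None = None,
) -> pd.DataFrame:
    """Generate a labeled DJNP image corpus plus a manifest CSV.

    Per-sample seeds and walk parameters derive deterministically from
    ``master_seed``; regenerating with the same seed reproduces the manifest
    and every PNG byte for byte. Returns the manifest (also written to
    ``out_dir/manifest.csv``) with columns file, label, skew_angle, speed,
    duration, direction, seed.
    """
    if n_straight < 0 or n_skew < 0 or n_straight + n_skew == 0:
        raise ValueError("need at least one sample")
    ranges = ranges or DatasetRanges()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(master_seed)
    labels = ["straight"] * n_straight + ["skew"] * n_skew
    rows = []
    for i, label in enumerate(labels):
        sample_seed = int(master.integers(0, 2**31 - 1))
        cfg = _draw_config(label, ranges, np.random.default_rng(sample_seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # FOV truncation is expected at high skew
            sample = simulate_walk(cfg, seed=sample_seed, canvas=canvas)
        fname = f"djnp_{i:04d}_{label}.png"
        save_png(sample.djnp_image, out_dir / fname)
        rows.append(
            {
                "file": fname,
                "label": sample.label,
                "skew_angle": cfg.skew_angle,
                "speed": cfg.speed,
                "duration": cfg.duration,
                "direction": cfg.direction,
                "seed": sample_seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def estimate_drift_angle(d: DJNP, direction: str = "toward",
                         camera: CameraModel | None = None,
                         path_length: float = 5.0,
                         mean_side_height: float = MEAN_SIDE_HEIGHT) -> float:
    """Recover the ground-plane drift (skew) angle from a DJNP, in degrees.

    The image-plane angle of a side trace is a strongly amplified function of
    the ground drift angle theta: for a walk starting a distance Z0 from the
    camera, the side-centroid trace is a straight image line of slope
    dx/dy = (tan(theta) * Z0 +/- w) / (h - ybar), with h the camera height,
    ybar the mean side-joint height and w the mean lateral side offset.
    Averaging the signed slopes of the two sides cancels the +/- w term, and
    inverting the remaining factor yields theta. Positive = image-right drift.
    """
    from .posture_metrics import side_angle_signed

    cam = camera or CameraModel()
    s_l = math.tan(math.radians(side_angle_signed(d, "left")))
    s_r = math.tan(math.radians(side_angle_signed(d, "right")))
    mean_slope = 0.5 * (s_l + s_r)
    scale = cam.height - mean_side_height
    if direction == "away":
        return math.degrees(math.atan(-mean_slope * scale / cam.standoff))
    # toward: start distance depends (weakly) on theta; a few fixed-point steps
    theta = 0.0
    for _ in range(4):
        z0 = cam.standoff + path_length * math.cos(theta)
        theta = math.atan(mean_slope * scale / z0)
    return math.degrees(theta)
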