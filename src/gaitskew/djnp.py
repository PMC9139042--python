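"""Dynamic joint node plots (DJNPs).

A DJNP merges the joint nodes of frames sampled across a walking video into
one time-indexed point cloud, and renders that cloud as a raster image for
downstream feature extraction. Superposition is plain: points from different
timestamps are merged without decay or weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import LayoutError
from .layouts import SkeletonLayout, get_layout
from .pose_io import PoseFrame, round_half_up

POINT_COLUMNS = ["joint_id", "sample_index", "timestamp", "x", "y"]


@dataclass
class SourceMeta:
    duration: float = float("nan")
    fps: float = float("nan")
    interval: float = float("nan")
    frame_width: int = 1080
    frame_height: int = 1920


@dataclass
class DJNP:
    """Merged point cloud of joint nodes across sampled frames.

    ``points`` is a DataFrame with columns joint_id, sample_index,
    timestamp, x, y; only detected (confidence > 0) keypoints contribute.
    """

    points: pd.DataFrame
    n_samples: int
    layout: SkeletonLayout
    meta: SourceMeta

    def sample_points(self, sample_index: int) -> pd.DataFrame:
        return self.points[self.points["sample_index"] == sample_index]

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, layout="COCO18", frame_size=(1080, 1920)) -> "DJNP":
        pts = pd.read_csv(path)
        missing = [c for c in POINT_COLUMNS if c not in pts.columns]
        if missing:
            raise ValueError(f"DJNP CSV lacks columns {missing}")
        n = int(pts["sample_index"].max()) + 1 if len(pts) else 0
        meta = SourceMeta(frame_width=frame_size[0], frame_height=frame_size[1])
        return cls(pts[POINT_COLUMNS], n, get_layout(layout), meta)


@dataclass
class CanvasSpec:
    """Rendering parameters for DJNP rasters."""

    width: int = 1080
    height: int = 1920
    point_radius: int = 6
    background: int = 0
    foreground: int = 255

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.point_radius < 0:
            raise ValueError("point radius must be nonnegative")


def expected_djnp_frame_count(duration: float, fps: float, factor: float = 0.3) -> int:
    """Frame count by the duration x fps x factor convention.

    For a 10 s video at 30 fps and factor 0.3 this gives 90. It is kept as a
    separate operation from ``sample_timestamps`` (count = duration/interval),
    the convention the pipelines use; both conventions circulate for the same
    sampling description and only coincide when fps * factor^2 = 1.
    """
    if duration <= 0 or fps <= 0 or factor <= 0:
        raise ValueError("duration, fps and factor must be positive")
    return round_half_up(duration * fps * factor)


def build_djnp(
    frames: Sequence[PoseFrame],
    frame_size: tuple[int, int] = (1080, 1920),
    fps: float = float("nan"),
) -> DJNP:
    """Merge sampled pose frames into a DJNP.

    One point per detected keypoint per frame; ``sample_index`` follows frame
    order and ``timestamp`` is copied from each frame.
    """
    if len(frames) == 0:
        raise ValueError("cannot build a DJNP from zero frames")
    layout = frames[0].layout
    rows = []
    for i, fr in enumerate(frames):
        if fr.layout.name != layout.name:
            raise LayoutError(
                f"mixed layouts in frame sequence: {layout.name} vs {fr.layout.name}"
            )
        det = fr.detected_mask()
        ids = np.nonzero(det)[0]
        for j in ids:
            rows.append((int(j), i, fr.timestamp, fr.data[j, 0], fr.data[j, 1]))
    pts = pd.DataFrame(rows, columns=POINT_COLUMNS)
    timestamps = [fr.timestamp for fr in frames]
    interval = float(np.median(np.diff(timestamps))) if len(timestamps) > 1 else float("nan")
    duration = timestamps[-1] + interval if len(timestamps) > 1 else float("nan")
    meta = SourceMeta(duration, fps, interval, frame_size[0], frame_size[1])
    return DJNP(pts, len(frames), layout, meta)


def _disc_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dx * dx + dy * dy <= r * r
    return np.stack([dy[keep], dx[keep]], axis=1)


def render_djnp(d: DJNP, c: CanvasSpec | None = None) -> np.ndarray:
    """Render a DJNP as a deterministic 8-bit grayscale raster.

    Points are scaled from source-frame to canvas coordinates and drawn as
    filled discs of ``point_radius``. Points whose center falls outside the
    canvas are clipped and counted in a warning; identical inputs yield
    identical arrays (and hence byte-identical PNGs).
    """
    c = c or CanvasSpec()
    img = np.full((c.height, c.width), c.background, dtype=np.uint8)
    if len(d.points) == 0:
        return img
    sx = c.width / d.meta.frame_width
    sy = c.height / d.meta.frame_height
    xs = np.asarray(d.points["x"], dtype=float) * sx
    ys = np.asarray(d.points["y"], dtype=float) * sy
    cols = np.round(xs).astype(int)
    rows = np.round(ys).astype(int)
    inside = (cols >= 0) & (cols < c.width) & (rows >= 0) & (rows < c.height)
    n_clipped = int((~inside).sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} DJNP point(s) outside canvas were clipped", stacklevel=2)
    offsets = _disc_offsets(c.point_radius)
    for r0, c0 in zip(rows[inside], cols[inside]):
        rr = offsets[:, 0] + r0
        cc = offsets[:, 1] + c0
        ok = (rr >= 0) & (rr < c.height) & (cc >= 0) & (cc < c.width)
        img[rr[ok], cc[ok]] = c.foreground
    return img


def save_png(img: np.ndarray, path) -> None:
    from PIL import Image

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img).save(path, format="PNG")


def load_png(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path).convert("L"))


def mirror_djnp(d: DJNP) -> DJNP:
    """Left/right mirror of a DJNP about the vertical image midline.

    x maps to (frame_width - 1) - x and joint ids are relabelled through the
    layout's mirror map, so the result is the DJNP the mirrored video would
    have produced: left-side joints trace where right-side joints were.
    """
    pts = d.points.copy()
    pts["x"] = (d.meta.frame_width - 1) - pts["x"]
    mm = d.layout.mirror_map()
    pts["joint_id"] = pts["joint_id"].map(mm)
    return DJNP(pts, d.n_samples, d.layout, replace(d.meta))
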