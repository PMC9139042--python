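"""Reading pose keypoint streams and localizing joint-node centers.

Consumes the OpenPose JSON dialect (one file per frame with
``people[i].pose_keypoints_2d`` flattened ``x, y, confidence`` triplets, or a
single-file JSON array of such frame objects) and per-joint heat maps stored
as grayscale PNG or delimited numeric text. Joint-node centers on heat maps
are located with the geometric centroid formula.

Coordinate convention throughout the package: image pixels, origin at the
top-left pixel center, x to the right, y down, 0-based; subpixel (real)
coordinates are allowed everywhere. A keypoint with confidence 0 is
"undetected" and its coordinates are ignored by all consumers.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .errors import LayoutError, NoPersonError, ParseError, UndefinedCentroidError
from .layouts import BODY25_TO_COCO18, COCO18, SkeletonLayout, get_layout


class Keypoint(NamedTuple):
    joint_id: int
    x: float
    y: float
    confidence: float


@dataclass
class PoseFrame:
    """One time-stamped set of 2D joint keypoints for one person.

    ``data`` is an ``(n_joints, 3)`` float array of ``x, y, confidence``
    rows in layout order.
    """

    timestamp: float
    data: np.ndarray
    layout: SkeletonLayout = COCO18
    person_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.layout.size, 3):
            raise LayoutError(
                f"expected {self.layout.size} keypoints for layout "
                f"{self.layout.name}, got shape {self.data.shape}"
            )
        conf = self.data[:, 2]
        if ((conf < 0) | (conf > 1)).any():
            raise ValueError("keypoint confidences must lie in [0, 1]")

    @property
    def keypoints(self) -> list[Keypoint]:
        return [Keypoint(j, x, y, c) for j, (x, y, c) in enumerate(self.data)]

    def detected_mask(self) -> np.ndarray:
        return self.data[:, 2] > 0


@dataclass
class RawFrame:
    """All persons detected in one frame (possibly zero)."""

    timestamp: float
    people: list[np.ndarray]
    layout: SkeletonLayout
    source: str = ""

    @property
    def n_people(self) -> int:
        return len(self.people)


@dataclass
class JointHeatmap:
    joint_id: int
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("heat map grid must be 2D")
        if (self.grid < 0).any():
            raise ValueError("heat map activations must be nonnegative")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]


_FRAME_INDEX_RE = re.compile(r"_(\d+)_keypoints\.json$")


def _parse_people(obj, layout: SkeletonLayout, source: str) -> list[np.ndarray]:
    people = obj.get("people", [])
    out = []
    for person in people:
        flat = person.get("pose_keypoints_2d")
        if flat is None:
            raise ParseError(f"{source}: person entry lacks 'pose_keypoints_2d'")
        if len(flat) != 3 * layout.size:
            raise LayoutError(
                f"{source}: expected {3 * layout.size} values for layout "
                f"{layout.name}, got {len(flat)}"
            )
        out.append(np.asarray(flat, dtype=float).reshape(layout.size, 3))
    return out


def read_openpose_frames(
    directory_or_file, layout="COCO18", interval: float = 0.3
) -> list[RawFrame]:
    """Read an OpenPose JSON frame stream.

    Accepts either a directory of ``<prefix>_<frameindex>_keypoints.json``
    files or a single JSON file holding an array of frame objects. Frames
    are ordered by timestamp ``frame_index * interval``. Undetected joints
    (``x = y = c = 0``) are preserved as confidence-0 keypoints; frames with
    an empty ``people`` array are returned with zero persons, not raised.
    """
    layout = get_layout(layout)
    if interval <= 0:
        raise ValueError("interval must be positive")
    path = Path(directory_or_file)
    frames: list[RawFrame] = []
    if path.is_dir():
        files = sorted(path.glob("*_keypoints.json"))
        if not files:
            raise ParseError(f"{path}: no *_keypoints.json files found")
        for f in files:
            m = _FRAME_INDEX_RE.search(f.name)
            if m is None:
                raise ParseError(f"{f}: cannot extract frame index from name")
            idx = int(m.group(1))
            try:
                obj = json.loads(f.read_text())
            except json.JSONDecodeError as e:
                raise ParseError(f"{f}: malformed JSON ({e})") from e
            frames.append(
                RawFrame(idx * interval, _parse_people(obj, layout, str(f)), layout, str(f))
            )
    else:
        try:
            arr = json.loads(path.read_text())
        except FileNotFoundError:
            raise
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: malformed JSON ({e})") from e
        if not isinstance(arr, list):
            raise ParseError(f"{path}: single-file variant must be a JSON array")
        for idx, obj in enumerate(arr):
            frames.append(
                RawFrame(idx * interval, _parse_people(obj, layout, f"{path}[{idx}]"), layout, str(path))
            )
    frames.sort(key=lambda fr: fr.timestamp)
    return frames


def write_openpose_frames(
    frames: Sequence[PoseFrame], directory, prefix: str = "frame"
) -> list[Path]:
    """Write frames in the one-file-per-frame OpenPose JSON dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, fr in enumerate(frames):
        obj = {
            "version": 1.3,
            "people": [{"pose_keypoints_2d": [float(v) for v in fr.data.ravel()]}],
        }
        p = directory / f"{prefix}_{i:012d}_keypoints.json"
        p.write_text(json.dumps(obj))
        paths.append(p)
    return paths


def select_primary_person(frame: RawFrame) -> int:
    """Index of the person with the highest mean keypoint confidence.

    Ties break toward the lower index. The walker dominates the recording
    geometry, so mean confidence is a reliable pick.
    """
    if frame.n_people == 0:
        raise NoPersonError(f"{frame.source or 'frame'}: no persons detected")
    means = [float(p[:, 2].mean()) for p in frame.people]
    return int(np.argmax(means))  # argmax returns the first (lowest) index on ties


def primary_pose_frames(raw_frames: Sequence[RawFrame]) -> list[PoseFrame]:
    """Reduce multi-person raw frames to the primary person's PoseFrames.

    Frames with zero persons are skipped with a warning rather than raised.
    """
    out = []
    skipped = 0
    for fr in raw_frames:
        if fr.n_people == 0:
            skipped += 1
            continue
        i = select_primary_person(fr)
        out.append(PoseFrame(fr.timestamp, fr.people[i], fr.layout, person_index=i))
    if skipped:
        warnings.warn(f"skipped {skipped} frame(s) with no detected person", stacklevel=2)
    return out


def to_coco18(frame: PoseFrame) -> PoseFrame:
    """Down-map a BODY25 frame to the COCO18 layout (identity on COCO18)."""
    if frame.layout.name == "COCO18":
        return frame
    if frame.layout.name != "BODY25":
        raise LayoutError(f"cannot map layout {frame.layout.name} to COCO18")
    data = frame.data[list(BODY25_TO_COCO18)]
    return PoseFrame(frame.timestamp, data, COCO18, frame.person_index)


def centroid_from_heatmap(h: JointHeatmap) -> tuple[float, float]:
    """Geometric centroid of a joint heat map, in subpixel pixel coordinates.

    x = sum(a_ij * j) / sum(a_ij) and y = sum(a_ij * i) / sum(a_ij) over
    0-based pixel centers (origin top-left, y down).
    """
    total = h.grid.sum()
    if total <= 0:
        raise UndefinedCentroidError(f"joint {h.joint_id}: all-zero heat map")
    ys, xs = np.indices(h.grid.shape)
    x = float((h.grid * xs).sum() / total)
    y = float((h.grid * ys).sum() / total)
    return x, y


def read_heatmap(path, joint_id: int = 0) -> JointHeatmap:
    """Read a heat map from a grayscale PNG or a delimited numeric text file."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        grid = np.asarray(Image.open(path).convert("F"), dtype=float)
    else:
        grid = np.loadtxt(path, ndmin=2)
    return JointHeatmap(joint_id=joint_id, grid=grid)


def round_half_up(x: float) -> int:
    """Round half away from zero toward +inf for nonnegative x."""
    return int(math.floor(x + 0.5))


def sample_timestamps(duration: float, interval: float = 0.3) -> list[float]:
    """Timestamps of the static frames sampled from a video.

    Frames are taken every ``interval`` seconds at t = 0, interval, 2*interval,
    ...; the count is round-half-up(duration / interval), so a 3 s video at
    0.3 s spacing yields 10 frames.
    """
    if duration <= 0 or interval <= 0:
        raise ValueError("duration and interval must be positive")
    n = round_half_up(duration / interval)
    return [k * interval for k in range(n)]
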