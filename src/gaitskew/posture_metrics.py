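"""Iso-block postural identity (IPI) grids and walking-skew quantification.

The IPI is a uniform grid of equal square blocks fused with a DJNP; the
per-sample block occupancy localizes the body at each sampling time. Skewness
is quantified by the angles the left and right body-side traces make with the
image vertical (theta_l, theta_r), their ratio SR = theta_l / theta_r, and by
per-interval side displacements D_r, D_l whose ratio MD = D_r / D_l identifies
the dominant displacement side:

* SR > 1: the body tends to skew to the right; SR = 1: almost straight;
  SR < 1: skew to the left (same rules for MD and side dominance).

Side traces are defined on the per-sample centroids of the detected side
joints (shoulder, elbow, wrist, hip, knee, ankle of that side); the trace
angle is the acute angle between a total-least-squares line through those
centroids and the image vertical. This definition is robust to single-joint
dropout; the landmark set is an explicit, swappable choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .djnp import DJNP
from .errors import InsufficientDataError

#: half-band around 1 inside which SR and MD are read as "almost straight"
DEFAULT_EPSILON = 0.05

#: default IPI block edge: 40 px gives 27 columns on a 1080-px-wide frame
DEFAULT_BLOCK_EDGE = 40.0


@dataclass
class IPIGrid:
    """Per-sample binary occupancy on a uniform square-block grid."""

    block_edge: float
    n_cols: int
    n_rows: int
    occupancy: np.ndarray  # (n_samples, n_rows, n_cols) of {0,1}

    @property
    def n_samples(self) -> int:
        return self.occupancy.shape[0]


def build_ipi(d: DJNP, block_edge: float = DEFAULT_BLOCK_EDGE) -> IPIGrid:
    """Bin DJNP points of each sample into square blocks.

    A block is occupied at sample i iff at least one point of sample i falls
    inside it; blocks tile the frame from the origin, the last row/column may
    be partial. A block edge larger than the frame degenerates to a single
    block (warned, not raised).
    """
    if block_edge <= 0:
        raise ValueError("block_edge must be positive")
    w, h = d.meta.frame_width, d.meta.frame_height
    if block_edge > max(w, h):
        warnings.warn(
            f"block_edge {block_edge} exceeds frame size {w}x{h}; grid has a single block",
            stacklevel=2,
        )
    n_cols = max(1, math.ceil(w / block_edge))
    n_rows = max(1, math.ceil(h / block_edge))
    occ = np.zeros((d.n_samples, n_rows, n_cols), dtype=np.uint8)
    if len(d.points):
        cols = np.clip((d.points["x"] // block_edge).astype(int), 0, n_cols - 1)
        rows = np.clip((d.points["y"] // block_edge).astype(int), 0, n_rows - 1)
        occ[d.points["sample_index"].astype(int), rows, cols] = 1
    return IPIGrid(block_edge, n_cols, n_rows, occ)


def fuse_ipi_djnp(g: IPIGrid, img: np.ndarray, line_value: int = 96, shade: int = 60) -> np.ndarray:
    """Overlay IPI grid lines and occupied-block shading on a DJNP raster.

    Occupancy is unioned over samples for display. Deterministic; raises on
    inconsistent grid/image dimensions.
    """
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale raster")
    h, w = img.shape
    if math.ceil(w / g.block_edge) != g.n_cols or math.ceil(h / g.block_edge) != g.n_rows:
        raise ValueError(
            f"grid ({g.n_rows}x{g.n_cols} @ {g.block_edge}px) does not cover a {w}x{h} image"
        )
    out = img.astype(np.int32).copy()
    union = g.occupancy.any(axis=0)
    for r in range(g.n_rows):
        for c in range(g.n_cols):
            if union[r, c]:
                r0, r1 = int(r * g.block_edge), min(h, int((r + 1) * g.block_edge))
                c0, c1 = int(c * g.block_edge), min(w, int((c + 1) * g.block_edge))
                out[r0:r1, c0:c1] += shade
    for x in range(0, w, max(1, int(g.block_edge))):
        out[:, x] = np.maximum(out[:, x], line_value)
    for y in range(0, h, max(1, int(g.block_edge))):
        out[y, :] = np.maximum(out[y, :], line_value)
    return np.clip(out, 0, 255).astype(np.uint8)


def side_centroids(d: DJNP, side: str) -> pd.DataFrame:
    """Per-sample centroid of the detected side joints.

    Returns a DataFrame with columns sample_index, timestamp, x, y; samples
    with no detected joint on that side are absent.
    """
    ids = d.layout.side_joints(side)
    pts = d.points[d.points["joint_id"].isin(ids)]
    if len(pts) == 0:
        return pd.DataFrame(columns=["sample_index", "timestamp", "x", "y"])
    g = pts.groupby("sample_index", as_index=False).agg(
        timestamp=("timestamp", "first"), x=("x", "mean"), y=("y", "mean")
    )
    return g.sort_values("sample_index").reset_index(drop=True)


def _tls_direction(xy: np.ndarray) -> np.ndarray:
    """Unit direction of the total-least-squares line through points (n, 2)."""
    centered = xy - xy.mean(axis=0)
    # principal axis of the 2x2 scatter matrix
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v
    return v


def side_angle_signed(d: DJNP, side: str) -> float:
    """Signed angle (degrees) of the side trace relative to the image vertical.

    Positive angles lean toward image-right (+x with increasing y). Requires
    at least 2 usable samples with detected joints on that side.
    """
    cen = side_centroids(d, side)
    if len(cen) < 2:
        raise InsufficientDataError(
            f"side_angle needs >=2 samples with detected {side}-side joints, got {len(cen)}"
        )
    xy = cen[["x", "y"]].to_numpy(dtype=float)
    if np.allclose(xy, xy[0]):
        return 0.0
    v = _tls_direction(xy)
    return math.degrees(math.atan2(v[0], v[1]))


def side_angle(d: DJNP, side: str) -> float:
    """Acute angle (degrees, in [0, 90]) between the side trace and vertical."""
    return abs(side_angle_signed(d, side))


def skew_ratio(theta_l: float, theta_r: float) -> float:
    """SR = theta_l / theta_r; both angles 0 gives SR = 1 (straight by convention)."""
    if theta_l < 0 or theta_r < 0:
        raise ValueError("angles must be nonnegative")
    if theta_r == 0:
        return 1.0 if theta_l == 0 else math.inf
    return theta_l / theta_r


def classify_skew(sr: float, epsilon: float = DEFAULT_EPSILON) -> str:
    """Map an SR (or MD) value to a left/straight/right label.

    ``straight`` within |ratio - 1| <= epsilon; ``right`` above the band,
    ``left`` below it.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if math.isinf(sr) or sr > 1 + epsilon:
        return "right"
    if sr < 1 - epsilon:
        return "left"
    return "straight"


def side_displacement(d: DJNP, side: str, i: int) -> float:
    """Euclidean distance of the side centroid between samples i-1 and i (px).

    Raises InsufficientDataError when either sample lacks detected side
    joints; callers batching over intervals record such intervals as missing.
    """
    cen = side_centroids(d, side).set_index("sample_index")
    if i - 1 not in cen.index or i not in cen.index:
        raise InsufficientDataError(
            f"{side}-side centroid missing at sample {i - 1} or {i}"
        )
    a = cen.loc[i - 1, ["x", "y"]].to_numpy(dtype=float)
    b = cen.loc[i, ["x", "y"]].to_numpy(dtype=float)
    return float(np.hypot(*(b - a)))


def dominance_ratio(d_r: float, d_l: float) -> float:
    """MD = D_r / D_l; 0/0 gives 1 (straight), x/0 gives +inf (right-dominant)."""
    if d_r < 0 or d_l < 0:
        raise ValueError("displacements must be nonnegative")
    if d_l == 0:
        return 1.0 if d_r == 0 else math.inf
    return d_r / d_l


def walking_velocity(path_length: float, elapsed: float) -> float:
    """Mean walking velocity in m/s over a straight path."""
    if path_length <= 0 or elapsed <= 0:
        raise ValueError("path_length and elapsed must be positive")
    return path_length / elapsed


@dataclass
class SkewMetrics:
    """Full skew/displacement quantification of one DJNP."""

    theta_l: float
    theta_r: float
    sr: float
    skew_label: str
    displacements: list[tuple[float, float] | None]  # per interval (D_r, D_l)
    md: list[float | None]
    dominance_label: list[str | None]
    epsilon: float = DEFAULT_EPSILON

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, pair in enumerate(self.displacements, start=1):
            d_r, d_l = pair if pair is not None else (math.nan, math.nan)
            rows.append(
                {
                    "sample_index": k,
                    "theta_l": self.theta_l,
                    "theta_r": self.theta_r,
                    "sr": self.sr,
                    "d_r": d_r,
                    "d_l": d_l,
                    "md": self.md[k - 1] if self.md[k - 1] is not None else math.nan,
                    "label": self.dominance_label[k - 1] or "missing",
                }
            )
        if not rows:  # single-interval-free DJNP: still report the angles
            rows.append(
                {
                    "sample_index": 0,
                    "theta_l": self.theta_l,
                    "theta_r": self.theta_r,
                    "sr": self.sr,
                    "d_r": math.nan,
                    "d_l": math.nan,
                    "md": math.nan,
                    "label": self.skew_label,
                }
            )
        return pd.DataFrame(rows)


def compute_skew_metrics(d: DJNP, epsilon: float = DEFAULT_EPSILON) -> SkewMetrics:
    """Compute theta_l, theta_r, SR and all per-interval D/MD values of a DJNP."""
    theta_l = side_angle(d, "left")
    theta_r = side_angle(d, "right")
    sr = skew_ratio(theta_l, theta_r)
    displacements: list[tuple[float, float] | None] = []
    md: list[float | None] = []
    dom: list[str | None] = []
    for i in range(1, d.n_samples):
        try:
            d_r = side_displacement(d, "right", i)
            d_l = side_displacement(d, "left", i)
        except InsufficientDataError:
            displacements.append(None)
            md.append(None)
            dom.append(None)
            continue
        displacements.append((d_r, d_l))
        ratio = dominance_ratio(d_r, d_l)
        md.append(ratio)
        dom.append(classify_skew(ratio, epsilon))
    return SkewMetrics(
        theta_l, theta_r, sr, classify_skew(sr, epsilon), displacements, md, dom, epsilon
    )
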