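"""Skeleton layouts: fixed joint orderings used by 2D pose estimators.

Two layouts are supported: the 18-joint COCO ordering and the 25-joint
BODY_25 ordering. Each layout knows its joint names, which joint indices
belong to the anatomical left and right sides of the body (shoulder,
elbow, wrist, hip, knee, ankle), and how joints pair up under a left/right
mirror of the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SkeletonLayout:
    name: str
    joint_names: tuple[str, ...]
    # per-side limb joints used for side centroids (shoulder..ankle)
    right_side: tuple[int, ...]
    left_side: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.joint_names)

    def side_joints(self, side: str) -> tuple[int, ...]:
        if side == "right":
            return self.right_side
        if side == "left":
            return self.left_side
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    def mirror_map(self) -> dict[int, int]:
        """Joint-id relabelling under a left/right mirror of the body.

        Every ``L<name>`` joint maps to ``R<name>`` and vice versa;
        midline joints map to themselves.
        """
        out: dict[int, int] = {}
        index = {n: i for i, n in enumerate(self.joint_names)}
        for i, n in enumerate(self.joint_names):
            if n.startswith("L") and ("R" + n[1:]) in index:
                out[i] = index["R" + n[1:]]
            elif n.startswith("R") and ("L" + n[1:]) in index:
                out[i] = index["L" + n[1:]]
            else:
                out[i] = i
        return out


COCO18 = SkeletonLayout(
    name="COCO18",
    joint_names=(
        "Nose", "Neck",
        "RShoulder", "RElbow", "RWrist",
        "LShoulder", "LElbow", "LWrist",
        "RHip", "RKnee", "RAnkle",
        "LHip", "LKnee", "LAnkle",
        "REye", "LEye", "REar", "LEar",
    ),
    right_side=(2, 3, 4, 8, 9, 10),
    left_side=(5, 6, 7, 11, 12, 13),
)

BODY25 = SkeletonLayout(
    name="BODY25",
    joint_names=(
        "Nose", "Neck",
        "RShoulder", "RElbow", "RWrist",
        "LShoulder", "LElbow", "LWrist",
        "MidHip",
        "RHip", "RKnee", "RAnkle",
        "LHip", "LKnee", "LAnkle",
        "REye", "LEye", "REar", "LEar",
        "LBigToe", "LSmallToe", "LHeel",
        "RBigToe", "RSmallToe", "RHeel",
    ),
    right_side=(2, 3, 4, 9, 10, 11),
    left_side=(5, 6, 7, 12, 13, 14),
)

# BODY25 index supplying each COCO18 joint, for down-mapping.
BODY25_TO_COCO18: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18)

LAYOUTS: dict[str, SkeletonLayout] = {"COCO18": COCO18, "BODY25": BODY25}


def get_layout(name) -> SkeletonLayout:
    if isinstance(name, SkeletonLayout):
        return name
    key = str(name).upper()
    if key not in LAYOUTS:
        raise ValueError(f"unknown skeleton layout {name!r}; choose from {sorted(LAYOUTS)}")
    return LAYOUTS[key]
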