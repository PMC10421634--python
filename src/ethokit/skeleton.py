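"""Skeleton model for 15-landmark macaque pose recordings.

The skeleton is a tree over 15 named landmarks (head/trunk, two arms with
elbows, two legs, tail).  Joint angles are measured at every pair of bones
sharing a vertex, which for this tree yields exactly 19 angle triplets:
one at the head, six at the neck (degree 4), six at the hip (degree 4),
and one at each shoulder, elbow and knee.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

DEFAULT_LANDMARKS = (
    "nose",
    "head",
    "neck",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "hip",
    "left_knee",
    "left_ankle",
    "right_knee",
    "right_ankle",
    "tail",
)

DEFAULT_EDGES = (
    (0, 1),   # nose - head
    (1, 2),   # head - neck
    (2, 3),   # neck - left_shoulder
    (3, 4),   # left_shoulder - left_elbow
    (4, 5),   # left_elbow - left_wrist
    (2, 6),   # neck - right_shoulder
    (6, 7),   # right_shoulder - right_elbow
    (7, 8),   # right_elbow - right_wrist
    (2, 9),   # neck - hip
    (9, 10),  # hip - left_knee
    (10, 11),  # left_knee - left_ankle
    (9, 12),  # hip - right_knee
    (12, 13),  # right_knee - right_ankle
    (9, 14),  # hip - tail
)


def _angle_triplets_from_edges(edges):
    """All ordered (outer, vertex, outer) triples of adjacent bone pairs."""
    nbrs: dict[int, list[int]] = {}
    for a, b in edges:
        nbrs.setdefault(a, []).append(b)
        nbrs.setdefault(b, []).append(a)
    trips = []
    for v in sorted(nbrs):
        for a, b in combinations(sorted(nbrs[v]), 2):
            trips.append((a, v, b))
    return tuple(trips)


# Resting quadrupedal stance in arena coordinates (meters); bone lengths
# follow adult rhesus proportions.  Used both as the reference for the
# synthetic generator and for the default bone lengths.
DEFAULT_REFERENCE_POSE = np.array(
    [
        (0.42, 0.00, 0.50),   # nose
        (0.36, 0.00, 0.54),   # head
        (0.30, 0.00, 0.48),   # neck
        (0.28, 0.09, 0.46),   # left_shoulder
        (0.27, 0.11, 0.32),   # left_elbow
        (0.26, 0.10, 0.18),   # left_wrist
        (0.28, -0.09, 0.46),  # right_shoulder
        (0.27, -0.11, 0.32),  # right_elbow
        (0.26, -0.10, 0.18),  # right_wrist
        (0.00, 0.00, 0.44),   # hip
        (0.02, 0.09, 0.28),   # left_knee
        (0.05, 0.10, 0.12),   # left_ankle
        (0.02, -0.09, 0.28),  # right_knee
        (0.05, -0.10, 0.12),  # right_ankle
        (-0.12, 0.00, 0.48),  # tail
    ]
)


@dataclass(frozen=True)
class SkeletonModel:
    """Bone graph, angle triplets and torso axes of a tracked skeleton.

    ``spine_pair`` is (neck, hip); the neck->hip vector defines pose scale
    and, with the shoulder axis, the torso plane used for rotational
    normalization.
    """

    landmark_names: tuple[str, ...] = DEFAULT_LANDMARKS
    edges: tuple[tuple[int, int], ...] = DEFAULT_EDGES
    angle_triplets: tuple[tuple[int, int, int], ...] = field(default=None)  # type: ignore[assignment]
    spine_pair: tuple[int, int] = (2, 9)
    shoulder_pair: tuple[int, int] = (3, 6)
    reference_bone_lengths: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.angle_triplets is None:
            object.__setattr__(
                self, "angle_triplets", _angle_triplets_from_edges(self.edges)
            )
        if self.reference_bone_lengths is None:
            ref = DEFAULT_REFERENCE_POSE
            lens = tuple(
                float(np.linalg.norm(ref[a] - ref[b])) for a, b in self.edges
            )
            object.__setattr__(self, "reference_bone_lengths", lens)
        self.validate()

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_names)

    def validate(self) -> None:
        if len(self.landmark_names) != 15:
            raise ValueError(
                f"expected 15 landmarks, got {len(self.landmark_names)}"
            )
        if len(self.angle_triplets) != 19:
            raise ValueError(
                f"expected 19 angle triplets, got {len(self.angle_triplets)}"
            )
        edge_set = {frozenset(e) for e in self.edges}
        for a, v, b in self.angle_triplets:
            if frozenset((a, v)) not in edge_set or frozenset((v, b)) not in edge_set:
                raise ValueError(
                    f"triplet ({a},{v},{b}) vertex not adjacent to both outer landmarks"
                )
        n = self.n_landmarks
        special = set(self.spine_pair) | set(self.shoulder_pair)
        if len(set(self.spine_pair)) != 2 or len(set(self.shoulder_pair)) != 2:
            raise ValueError("spine_pair and shoulder_pair must each be distinct")
        if not all(0 <= i < n for i in special):
            raise ValueError("spine/shoulder indices out of range")

    def index(self, name: str) -> int:
        return self.landmark_names.index(name)

    def bone_lengths(self, coords: np.ndarray) -> np.ndarray:
        """Per-edge lengths for frames of shape (..., n_landmarks, 3)."""
        a = np.asarray([e[0] for e in self.edges])
        b = np.asarray([e[1] for e in self.edges])
        return np.linalg.norm(coords[..., a, :] - coords[..., b, :], axis=-1)


def default_skeleton() -> SkeletonModel:
    return SkeletonModel()
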