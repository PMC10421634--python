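"""Synthetic multi-session 3D pose recordings with planted structure.

The generator plants the structure the downstream pipeline is meant to
recover: a repertoire of posture templates grouped into behavioral
modules (optionally nested in super-modules), a first-order Markov chain
over postures whose transitions prefer to stay within a module, geometric
dwell times, and a rendering step that realizes each posture's joint
angles on the 15-landmark skeleton with observation noise, per-subject
limb scaling, per-session batch offsets and tracking failures.

Every function is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import PoseSequence, write_pose_table
from .skeleton import DEFAULT_REFERENCE_POSE, SkeletonModel, default_skeleton

CAGE_BOUNDS = ((0.0, 0.0, 0.0), (2.45, 2.45, 2.75))


def vertex_angles(coords: np.ndarray, skeleton: SkeletonModel) -> np.ndarray:
    """Joint angles (radians, in [0, pi]) at each skeleton angle triplet.

    ``coords`` has shape (..., n_landmarks, 3); the result has shape
    (..., 19).  Shared with the feature module so the generator and the
    pipeline measure angles identically.
    """
    trips = np.asarray(skeleton.angle_triplets)
    a, v, b = trips[:, 0], trips[:, 1], trips[:, 2]
    u1 = coords[..., a, :] - coords[..., v, :]
    u2 = coords[..., b, :] - coords[..., v, :]
    n1 = np.linalg.norm(u1, axis=-1)
    n2 = np.linalg.norm(u2, axis=-1)
    denom = n1 * n2
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...ij,...ij->...i", u1, u2) / denom
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    ang[denom < 1e-12] = np.nan
    return ang


@dataclass
class BehaviorRepertoire:
    """Posture templates, their module/hierarchy membership and dynamics.

    ``transition`` is the between-run Markov matrix, row-stochastic with
    zero diagonal (a run change always switches posture).
    """

    template_poses: np.ndarray        # (n_postures, 15, 3) canonical poses
    template_angles: np.ndarray       # (n_postures, 19)
    velocity_tendency: np.ndarray     # (n_postures, 3) m/s, arena frame
    module_of_posture: np.ndarray     # (n_postures,) int
    super_of_module: np.ndarray | None  # (n_modules,) int or None (flat)
    transition: np.ndarray            # (n_postures, n_postures) row-stochastic
    within_module_prob: float
    dwell_mean_frames: float

    @property
    def n_postures(self) -> int:
        return len(self.module_of_posture)

    @property
    def n_modules(self) -> int:
        return int(self.module_of_posture.max()) + 1

    def validate(self) -> None:
        if not 0.0 <= self.within_module_prob <= 1.0:
            raise ValueError("within_module_prob must be in [0, 1]")
        rows = self.transition.sum(axis=1)
        bad = np.flatnonzero(~np.isclose(rows, 1.0, atol=1e-9))
        if bad.size:
            raise ValueError(
                f"transition probabilities for posture {bad[0]} sum to "
                f"{rows[bad[0]]:.6f}, not 1"
            )
        if np.any(self.transition < 0):
            raise ValueError("negative transition probability")


@dataclass
class GroundTruth:
    """Planted per-frame labels and batch parameters of a synthetic set."""

    posture_labels: np.ndarray
    module_labels: np.ndarray
    super_labels: np.ndarray | None = None
    run_postures: np.ndarray | None = None
    session_offsets: dict = field(default_factory=dict)
    subject_scale: dict = field(default_factory=dict)


def _planted_transition(
    module_of: np.ndarray,
    super_of: np.ndarray | None,
    within_module_prob: float,
    within_super_prob: float,
) -> np.ndarray:
    """Row-stochastic zero-diagonal chain preferring within-module moves."""
    n = len(module_of)
    P = np.zeros((n, n))
    for j in range(n):
        m = module_of[j]
        same_mod = np.flatnonzero((module_of == m) & (np.arange(n) != j))
        if super_of is not None:
            s = super_of[m]
            same_super = np.flatnonzero(
                (super_of[module_of] == s) & (module_of != m)
            )
            other = np.flatnonzero(super_of[module_of] != s)
        else:
            same_super = np.array([], dtype=int)
            other = np.flatnonzero(module_of != m)
        w_in = within_module_prob if same_mod.size else 0.0
        w_sup = within_super_prob if same_super.size else 0.0
        w_out = 1.0 - w_in - w_sup if other.size else 0.0
        total = w_in + w_sup + w_out
        if total <= 0:
            raise ValueError(f"posture {j} has no admissible transitions")
        if same_mod.size:
            P[j, same_mod] = w_in / total / same_mod.size
        if same_super.size:
            P[j, same_super] = w_sup / total / same_super.size
        if other.size:
            P[j, other] = w_out / total / other.size
    return P


def make_repertoire(
    n_postures: int = 12,
    n_modules: int = 4,
    within_module_prob: float = 0.9,
    n_super: int | None = None,
    within_super_prob: float = 0.07,
    dwell_mean_frames: float = 18.0,
    min_separation: float = 1.0,
    template_spread: float = 0.06,
    max_speed: float = 0.25,
    skeleton: SkeletonModel | None = None,
    seed: int = 0,
) -> BehaviorRepertoire:
    """Sample a frozen repertoire of separable posture templates.

    Templates are perturbations of the reference stance (per-landmark
    Gaussian displacement, sd ``template_spread`` meters), rejected until
    every pair is at least ``min_separation`` apart in Euclidean distance
    over the 19 joint angles.  Defaults plant 12 postures in 4 modules
    with 90% within-module transition mass and a mean dwell of 18 frames
    (0.6 s at 30 Hz).
    """
    skeleton = skeleton or default_skeleton()
    rng = np.random.default_rng(seed)
    base = DEFAULT_REFERENCE_POSE
    poses, angles = [], []
    attempts = 0
    while len(poses) < n_postures:
        attempts += 1
        if attempts > 2000 * n_postures:
            raise RuntimeError(
                "could not sample separable templates; lower min_separation"
            )
        cand = base + rng.normal(0.0, template_spread, base.shape)
        ang = vertex_angles(cand, skeleton)
        if np.isnan(ang).any():
            continue
        if all(np.linalg.norm(ang - a) >= min_separation for a in angles):
            poses.append(cand)
            angles.append(ang)
    module_of = np.arange(n_postures) % n_modules
    module_of.sort()
    super_of = None
    if n_super is not None:
        super_of = np.sort(np.arange(n_modules) % n_super)
    speeds = rng.uniform(0.0, max_speed, n_postures)
    headings = rng.uniform(0.0, 2 * np.pi, n_postures)
    vel = np.stack(
        [speeds * np.cos(headings), speeds * np.sin(headings), np.zeros(n_postures)],
        axis=1,
    )
    P = _planted_transition(
        module_of, super_of, within_module_prob, within_super_prob
    )
    rep = BehaviorRepertoire(
        template_poses=np.asarray(poses),
        template_angles=np.asarray(angles),
        velocity_tendency=vel,
        module_of_posture=module_of,
        super_of_module=super_of,
        transition=P,
        within_module_prob=within_module_prob,
        dwell_mean_frames=dwell_mean_frames,
    )
    rep.validate()
    return rep


def generate_markov_labels(
    repertoire: BehaviorRepertoire, n_frames: int, seed: int = 0
) -> tuple[np.ndarray, GroundTruth]:
    """Sample a per-frame posture label sequence from the planted chain.

    Run postures follow the repertoire's between-run Markov matrix; run
    lengths are geometric with mean ``dwell_mean_frames`` (memoryless,
    matching the first-order transition analysis downstream).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    repertoire.validate()
    rng = np.random.default_rng(seed)
    p_geom = 1.0 / repertoire.dwell_mean_frames
    labels = np.empty(n_frames, dtype=int)
    run_postures = []
    cur = int(rng.integers(repertoire.n_postures))
    t = 0
    while t < n_frames:
        run_postures.append(cur)
        length = int(rng.geometric(p_geom))
        labels[t : t + length] = cur
        t += length
        cur = int(rng.choice(repertoire.n_postures, p=repertoire.transition[cur]))
    module_labels = repertoire.module_of_posture[labels]
    super_labels = None
    if repertoire.super_of_module is not None:
        super_labels = repertoire.super_of_module[module_labels]
    gt = GroundTruth(
        posture_labels=labels,
        module_labels=module_labels,
        super_labels=super_labels,
        run_postures=np.asarray(run_postures),
    )
    return labels, gt


def render_poses(
    labels: np.ndarray,
    skeleton: SkeletonModel,
    repertoire: BehaviorRepertoire,
    noise_sd: float = 0.01,
    seed: int = 0,
    subject_scale: float = 1.0,
    fps: float = 30.0,
    blend_frames: int = 3,
    subject_id: str = "subjA",
    session_id: str = "sess0",
    task_condition: str = "OFF",
) -> PoseSequence:
    """Render a label sequence into arena-frame landmark trajectories.

    Each run places its posture's template (scaled by ``subject_scale``,
    rotated by a per-run random yaw) on a center-of-mass path that
    integrates the posture's velocity tendency inside the cage, with a
    short linear blend (``blend_frames``) across run boundaries and
    additive Gaussian observation noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= repertoire.n_postures:
        raise ValueError("label without a posture template")
    rng = np.random.default_rng(seed)
    n = len(labels)

    # run boundaries
    starts = np.flatnonzero(np.r_[True, labels[1:] != labels[:-1]])
    ends = np.r_[starts[1:], n]

    body = np.empty((n, skeleton.n_landmarks, 3))
    vel = np.empty((n, 3))
    for s, e in zip(starts, ends):
        k = labels[s]
        yaw = rng.uniform(0.0, 2 * np.pi)
        c, sn = np.cos(yaw), np.sin(yaw)
        R = np.array([[c, -sn, 0.0], [sn, c, 0.0], [0.0, 0.0, 1.0]])
        tmpl = repertoire.template_poses[k]
        centered = (tmpl - tmpl.mean(axis=0)) * subject_scale
        body[s:e] = centered @ R.T
        vel[s:e] = R @ repertoire.velocity_tendency[k]

    # blend run boundaries for continuity
    for s in starts[1:]:
        prev = body[s - 1].copy()
        for k in range(min(blend_frames, n - s)):
            a = (k + 1) / (blend_frames + 1)
            body[s + k] = a * body[s + k] + (1 - a) * prev

    # center-of-mass path: integrate velocity, reflect inside cage margins
    lo = np.array([0.35, 0.35, 0.0])
    hi = np.array([2.10, 2.10, 0.0])
    com = np.empty((n, 3))
    pos = np.array([1.2, 1.2, 0.45])
    for t in range(n):
        pos = pos + vel[t] / fps
        for d in range(2):
            if pos[d] < lo[d]:
                pos[d] = 2 * lo[d] - pos[d]
                vel[t:, d] = np.abs(vel[t:, d])
            elif pos[d] > hi[d]:
                pos[d] = 2 * hi[d] - pos[d]
                vel[t:, d] = -np.abs(vel[t:, d])
        com[t] = pos
    coords = body + com[:, None, :]
    if noise_sd > 0:
        coords = coords + rng.normal(0.0, noise_sd, coords.shape)
    return PoseSequence(
        coords=coords,
        valid_mask=np.ones(n, dtype=bool),
        fps=fps,
        subject_id=subject_id,
        session_id=session_id,
        task_condition=task_condition,
    )


def corrupt_session(
    seq: PoseSequence,
    offset: np.ndarray | None = None,
    dropout_runs: list[tuple[int, int]] | None = None,
    outlier_frames: list | None = None,
) -> PoseSequence:
    """Apply batch offset, tracking dropouts and outlier frames.

    ``offset`` (3,) or (15, 3) is added to every frame (the day-to-day
    measurement batch effect that alignment corrects).  ``dropout_runs``
    are (start, length) runs marked missing.  ``outlier_frames`` entries
    are frame indices (displaced outside the cage) or (frame, "collapse")
    pairs (all landmarks collapsed to their centroid).
    """
    out = seq.copy()
    n = out.n_frames
    if offset is not None:
        off = np.asarray(offset, dtype=float)
        out.coords = out.coords + off  # broadcasts (3,) or (15,3)
    for start, length in dropout_runs or []:
        if start < 0 or start + length > n:
            raise IndexError(f"dropout run ({start},{length}) out of bounds")
        out.valid_mask[start : start + length] = False
        out.coords[start : start + length] = np.nan
    for item in outlier_frames or []:
        frame, kind = item if isinstance(item, tuple) else (item, "displace")
        if not 0 <= frame < n:
            raise IndexError(f"outlier frame {frame} out of bounds")
        if kind == "collapse":
            out.coords[frame] = out.coords[frame].mean(axis=0)
        else:
            out.coords[frame] = out.coords[frame] + np.array([5.0, 5.0, 5.0])
    return out


def write_ground_truth(gt: GroundTruth, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "frame": np.arange(len(gt.posture_labels)),
            "posture": gt.posture_labels,
            "module": gt.module_labels,
        }
    )
    if gt.super_labels is not None:
        df["super_module"] = gt.super_labels
    df.to_csv(path, index=False)


def write_manifest(params: dict, path) -> None:
    Path(path).write_text(json.dumps(params, indent=2, default=str))
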