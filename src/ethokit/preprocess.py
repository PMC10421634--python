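"""Pose I/O, quality control, gap interpolation and per-frame normalization.

A recording session is a :class:`PoseSequence`: frames x 15 landmarks x 3
coordinates in the arena frame (meters), a per-frame validity mask and
session metadata.  Preprocessing proceeds QC -> gap interpolation ->
normalization.  Normalization makes every valid frame translation-,
scale- and rotation-free: the neck sits at the origin, the spine
(neck->hip) has unit length and points along -Z, and the component of the
shoulder axis orthogonal to the spine points along +X.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .skeleton import SkeletonModel

DEFAULT_CAGE_BOUNDS = ((0.0, 0.0, 0.0), (2.45, 2.45, 2.75))


@dataclass
class PoseSequence:
    """Raw (arena-frame) landmark trajectories for one session."""

    coords: np.ndarray          # (n_frames, n_landmarks, 3), meters
    valid_mask: np.ndarray      # (n_frames,), bool
    fps: float = 30.0
    subject_id: str = ""
    session_id: str = ""
    task_condition: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (frames, landmarks, 3)")
        if self.valid_mask.shape != (self.coords.shape[0],):
            raise ValueError("valid_mask must have one entry per frame")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "PoseSequence":
        return replace(self, coords=self.coords.copy(), valid_mask=self.valid_mask.copy())


@dataclass
class NormalizedPoseSequence:
    """Dimensionless, canonically oriented poses (neck at origin, spine 1)."""

    coords: np.ndarray
    valid_mask: np.ndarray
    fps: float
    subject_id: str = ""
    session_id: str = ""
    task_condition: str = ""
    source: PoseSequence | None = None
    invalid_reasons: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class QCReport:
    n_frames: int
    n_out_of_bounds: int
    n_collapsed: int
    n_invalidated: int
    fraction_removed: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def pose_columns(skeleton: SkeletonModel) -> list[str]:
    cols = []
    for name in skeleton.landmark_names:
        cols += [f"{name}_x", f"{name}_y", f"{name}_z"]
    return cols


def write_pose_table(seq: PoseSequence, path, metadata_path=None) -> None:
    """Write one row per frame: frame, time_s, then <landmark>_{x,y,z}.

    Invalid frames are written with blank coordinate cells.  A JSON
    metadata sidecar carries subject/session/task and fps.
    """
    path = Path(path)
    n = seq.n_frames
    flat = seq.coords.reshape(n, -1).astype(float).copy()
    flat[~seq.valid_mask] = np.nan
    names = [f"{nm}_{ax}" for nm in range(flat.shape[1] // 3) for ax in "xyz"]
    # proper landmark names require a skeleton; infer 15-landmark default order
    from .skeleton import DEFAULT_LANDMARKS

    if flat.shape[1] == 45:
        names = [f"{nm}_{ax}" for nm in DEFAULT_LANDMARKS for ax in "xyz"]
    df = pd.DataFrame(flat, columns=names)
    df.insert(0, "time_s", np.arange(n) / seq.fps)
    df.insert(0, "frame", np.arange(n))
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "subject": seq.subject_id,
        "session_id": seq.session_id,
        "task": seq.task_condition,
        "fps": seq.fps,
    }
    mpath = Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")
    mpath.write_text(json.dumps(meta, indent=2))


def read_pose_table(path, skeleton: SkeletonModel, metadata_path=None) -> PoseSequence:
    """Read a tab/comma-separated pose table into a :class:`PoseSequence`.

    Missing coordinate cells mark the whole frame invalid.  Rejects
    tables whose columns do not cover the skeleton's landmarks or whose
    frame index is non-monotone, naming the first offending row.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = pose_columns(skeleton)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"pose table {path} lacks landmark columns: {missing[:3]}")
    if "frame" in df.columns:
        frames = df["frame"].to_numpy()
        diffs = np.diff(frames)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0) + 1)
            raise ValueError(f"non-monotone frame index at row {row}")
    coords = df[cols].to_numpy(dtype=float).reshape(len(df), -1, 3)
    valid = ~np.isnan(coords).any(axis=(1, 2))
    coords[~valid] = np.nan
    meta = {}
    mpath = Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")
    if mpath.exists():
        meta = json.loads(mpath.read_text())
    return PoseSequence(
        coords=coords,
        valid_mask=valid,
        fps=float(meta.get("fps", 30.0)),
        subject_id=str(meta.get("subject", "")),
        session_id=str(meta.get("session_id", path.stem)),
        task_condition=str(meta.get("task", "")),
    )


def qc_filter(
    seq: PoseSequence,
    skeleton: SkeletonModel,
    cage_bounds=DEFAULT_CAGE_BOUNDS,
    min_mean_limb: float = 0.10,
) -> tuple[PoseSequence, QCReport]:
    """Invalidate frames with out-of-cage landmarks or collapsed poses.

    A frame fails QC if any landmark lies outside the cage box or if the
    mean bone length falls below ``min_mean_limb`` (tracking collapse,
    default 10 cm).
    """
    lo = np.asarray(cage_bounds[0], dtype=float)
    hi = np.asarray(cage_bounds[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("cage bounds must be well-ordered (lo < hi)")
    out = seq.copy()
    coords = out.coords
    with np.errstate(invalid="ignore"):
        oob = ((coords < lo) | (coords > hi)).any(axis=(1, 2))
        mean_limb = skeleton.bone_lengths(coords).mean(axis=-1)
        collapsed = mean_limb < min_mean_limb
    oob &= out.valid_mask
    collapsed &= out.valid_mask
    bad = oob | collapsed
    n_before = int(out.valid_mask.sum())
    out.valid_mask &= ~bad
    out.coords[~out.valid_mask] = np.nan
    n_removed = n_before - int(out.valid_mask.sum())
    report = QCReport(
        n_frames=seq.n_frames,
        n_out_of_bounds=int(oob.sum()),
        n_collapsed=int(collapsed.sum()),
        n_invalidated=n_removed,
        fraction_removed=n_removed / max(n_before, 1),
    )
    return out, report


def _invalid_runs(valid: np.ndarray):
    """Yield (start, stop) of maximal invalid runs (stop exclusive)."""
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def interpolate_gaps(seq: PoseSequence, max_gap_frames: int = 10) -> PoseSequence:
    """Fill short dropouts by shape-preserving piecewise-cubic interpolation.

    Invalid runs of at most ``max_gap_frames`` frames (1/3 s at 30 Hz)
    bracketed by valid data on both sides are filled per coordinate with
    a monotone (PCHIP) cubic; longer runs and runs touching the sequence
    boundary are left invalid.  Frames outside filled gaps are untouched.
    """
    out = seq.copy()
    valid_idx = np.flatnonzero(seq.valid_mask)
    if valid_idx.size < 2:
        return out
    gaps = [
        (a, b)
        for a, b in _invalid_runs(seq.valid_mask)
        if (b - a) <= max_gap_frames and a > 0 and b < seq.n_frames
        and seq.valid_mask[a - 1] and (b >= seq.n_frames or seq.valid_mask[b])
    ]
    if not gaps:
        return out
    flat = seq.coords.reshape(seq.n_frames, -1)
    interp = PchipInterpolator(valid_idx, flat[valid_idx], axis=0, extrapolate=False)
    for a, b in gaps:
        t = np.arange(a, b)
        out.coords.reshape(seq.n_frames, -1)[a:b] = interp(t)
        out.valid_mask[a:b] = True
    return out


def _canonical_rotation(spine: np.ndarray, shoulder: np.ndarray):
    """Proper rotation sending spine->-Z and spine-orthogonal shoulder->+X.

    Returns None for degenerate geometry (zero spine, shoulders parallel
    to spine).
    """
    ns = np.linalg.norm(spine)
    if ns < 1e-12:
        return None
    u = spine / ns
    w = shoulder - np.dot(shoulder, u) * u
    nw = np.linalg.norm(w)
    if nw < 1e-9:
        return None
    b1 = w / nw
    b3 = u
    b2 = np.cross(b3, b1)
    B = np.stack([b1, b2, b3], axis=1)          # body frame, det +1
    T = np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])  # target frame
    return T @ B.T


def normalize_pose(seq: PoseSequence, skeleton: SkeletonModel) -> NormalizedPoseSequence:
    """Translate/scale/rotate every valid frame to the canonical torso frame.

    Steps per frame: subtract the neck landmark; divide by the spine
    (neck-hip) length so the spine has length 1; rotate so the torso
    plane faces a fixed direction.  Similarity transforms of the input
    therefore normalize to identical coordinates.
    """
    neck, hip = skeleton.spine_pair
    lsh, rsh = skeleton.shoulder_pair
    n = seq.n_frames
    out = np.full_like(seq.coords, np.nan)
    valid = seq.valid_mask.copy()
    reasons: dict[int, str] = {}
    for t in np.flatnonzero(seq.valid_mask):
        x = seq.coords[t] - seq.coords[t, neck]
        spine = x[hip]
        slen = np.linalg.norm(spine)
        if slen < 1e-9:
            valid[t] = False
            reasons[t] = "zero spine length"
            continue
        x = x / slen
        R = _canonical_rotation(x[hip], x[rsh] - x[lsh])
        if R is None:
            valid[t] = False
            reasons[t] = "degenerate torso plane"
            continue
        out[t] = x @ R.T
    return NormalizedPoseSequence(
        coords=out,
        valid_mask=valid,
        fps=seq.fps,
        subject_id=seq.subject_id,
        session_id=seq.session_id,
        task_condition=seq.task_condition,
        source=seq,
        invalid_reasons=reasons,
    )
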