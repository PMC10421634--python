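"""Engineered pose features: 19 joint angles plus 4 speed features.

Per frame the feature vector is the angle at each of the skeleton's 19
joint triplets (computed on normalized coordinates) followed by the
center-of-mass speed and the per-axis X/Y/Z speeds (computed on raw
arena-frame coordinates, since normalization removes translation).
Feature groups are min-max scaled to [0, 1] independently per subject
before PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import NormalizedPoseSequence, PoseSequence
from .simulate import vertex_angles
from .skeleton import SkeletonModel

FEATURE_GROUPS = ("angles",) * 19 + ("com_speed",) + ("axis_speeds",) * 3


@dataclass
class FeatureMatrix:
    """Per-frame 23-dimensional feature vectors with provenance labels."""

    features: np.ndarray          # (n_valid_frames, 23)
    frame_index: np.ndarray       # index into the source session's frames
    subject_id: np.ndarray        # per-row subject label
    session_id: np.ndarray        # per-row session label
    group_index: tuple[str, ...] = FEATURE_GROUPS
    normalized: bool = False

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]


def _smooth(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average along axis 0 (shrinking at boundaries)."""
    if window <= 1:
        return x
    kernel = np.ones(window)
    counts = np.convolve(np.ones(len(x)), kernel, mode="same")
    if x.ndim == 1:
        return np.convolve(x, kernel, mode="same") / counts
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(x[:, j], kernel, mode="same") / counts[: len(x)]
    return out


def compute_features(
    norm: NormalizedPoseSequence,
    raw: PoseSequence,
    skeleton: SkeletonModel,
    speed_smooth_window: int = 5,
) -> FeatureMatrix:
    """Angles from normalized coords; speeds from raw arena-frame coords.

    Speeds use a centered finite difference scaled by fps and a short
    moving-average smoothing window.  Frames invalid in either input, or
    with an undefined angle (zero-length bone), are excluded.
    """
    n = norm.n_frames
    angles = vertex_angles(norm.coords, skeleton)          # (n, 19)

    com = np.nanmean(raw.coords, axis=1)                   # (n, 3)
    dcom = np.empty_like(com)
    dcom[1:-1] = (com[2:] - com[:-2]) / 2.0
    dcom[0] = com[1] - com[0] if n > 1 else 0.0
    dcom[-1] = com[-1] - com[-2] if n > 1 else 0.0
    vel = dcom * raw.fps
    com_speed = np.linalg.norm(vel, axis=1)
    axis_speed = np.abs(vel)
    com_speed = _smooth(com_speed, speed_smooth_window)
    axis_speed = _smooth(axis_speed, speed_smooth_window)

    feats = np.column_stack([angles, com_speed, axis_speed])
    ok = norm.valid_mask & raw.valid_mask & ~np.isnan(feats).any(axis=1)
    # speed differences straddling invalid frames are unreliable
    pad = raw.valid_mask.astype(float)
    neighbor_ok = np.ones(n, dtype=bool)
    if n > 2:
        neighbor_ok[1:-1] = (pad[2:] > 0) & (pad[:-2] > 0)
    ok &= neighbor_ok
    idx = np.flatnonzero(ok)
    return FeatureMatrix(
        features=feats[idx],
        frame_index=idx,
        subject_id=np.full(idx.size, norm.subject_id, dtype=object),
        session_id=np.full(idx.size, norm.session_id, dtype=object),
        normalized=False,
    )


def concat_features(fms: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate per-session feature matrices (all sessions pooled)."""
    return FeatureMatrix(
        features=np.vstack([f.features for f in fms]),
        frame_index=np.concatenate([f.frame_index for f in fms]),
        subject_id=np.concatenate([f.subject_id for f in fms]),
        session_id=np.concatenate([f.session_id for f in fms]),
        normalized=all(f.normalized for f in fms),
    )


def normalize_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Min-max scale each feature group to [0, 1], per subject.

    The three groups (joint angles, COM speed, per-axis speeds) are each
    scaled by their own min and max so within-group geometry is kept;
    scaling is independent per subject.  Constant groups map to 0 with a
    warning.  Idempotent on already-normalized input.
    """
    groups = np.asarray(fm.group_index)
    feats = fm.features.copy()
    for subj in np.unique(fm.subject_id):
        rows = fm.subject_id == subj
        for g in dict.fromkeys(fm.group_index):
            cols = groups == g
            block = feats[np.ix_(rows, cols)]
            lo, hi = block.min(), block.max()
            if hi - lo < 1e-15:
                warnings.warn(
                    f"feature group '{g}' constant for subject {subj}; mapped to 0"
                )
                feats[np.ix_(rows, cols)] = 0.0
            else:
                feats[np.ix_(rows, cols)] = (block - lo) / (hi - lo)
    return replace(fm, features=feats, normalized=True)


def pca_reduce(fm: FeatureMatrix, var_fraction: float = 0.95):
    """PCA on pooled normalized features, keeping the smallest leading set
    of components whose cumulative explained variance reaches
    ``var_fraction``.

    Returns (scores, fitted sklearn PCA object).
    """
    if not 0.0 < var_fraction <= 1.0:
        raise ValueError("var_fraction must be in (0, 1]")
    if fm.n_frames < 2:
        raise ValueError("need at least 2 frames for PCA")
    if var_fraction == 1.0:
        pca = PCA(svd_solver="full")
        scores = pca.fit_transform(fm.features)
        keep = pca.explained_variance_ > 1e-12
        return scores[:, keep], pca
    pca = PCA(n_components=var_fraction, svd_solver="full")
    scores = pca.fit_transform(fm.features)
    return scores, pca
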