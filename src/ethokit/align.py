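"""Cross-session batch alignment via mutual nearest neighbors.

Day-to-day measurement effects shift a session's feature distribution.
The correction follows the MNN batch-correction idea: find sample pairs
that are mutually within each other's K-neighborhood across the two
sets, form per-sample correction vectors from kernel-weighted neighbor
differences, smooth them over time with a running median, and subtract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors


class AlignmentError(RuntimeError):
    pass


@dataclass
class AlignmentCorrection:
    """Per-sample mutual pairs, raw corrections and smoothed matrix C."""

    pair_sets: list[np.ndarray]    # per X2 sample: indices into X1
    raw: np.ndarray                # (n2, d), NaN rows where no pairs
    C: np.ndarray                  # (n2, d) smoothed, NaN-free
    sigma: float                   # kernel scale (median pair distance)

    @property
    def n_paired(self) -> int:
        return sum(1 for p in self.pair_sets if p.size)


def mutual_nearest_neighbors(
    X1: np.ndarray, X2: np.ndarray, K: int = 100
) -> list[np.ndarray]:
    """Mutual K-nearest-neighbor sets of each X2 sample within X1.

    An X1 sample j belongs to the mutual set of X2 sample i iff j is
    among the K nearest X1 neighbors of i AND i is among the K nearest
    X2 neighbors of j (Euclidean distance both ways).
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if len(X1) == 0 or len(X2) == 0:
        raise ValueError("both sample sets must be non-empty")
    if K < 1:
        raise ValueError("K must be >= 1")
    k_eff = min(K, len(X1), len(X2))
    if k_eff < K:
        warnings.warn(f"K={K} truncated to {k_eff} (set sizes)")
    nn1 = NearestNeighbors(n_neighbors=k_eff).fit(X1)
    knn_of_x2 = nn1.kneighbors(X2, return_distance=False)      # (n2, k)
    nn2 = NearestNeighbors(n_neighbors=k_eff).fit(X2)
    knn_of_x1 = nn2.kneighbors(X1, return_distance=False)      # (n1, k)
    reverse = [set(row) for row in knn_of_x1]
    pairs = []
    for i, row in enumerate(knn_of_x2):
        pairs.append(np.asarray([j for j in row if i in reverse[j]], dtype=int))
    return pairs


def correction_vectors(
    X2: np.ndarray,
    X1: np.ndarray,
    pair_sets: list[np.ndarray],
    filter_order: int = 15,
    weighting: str = "kernel",
) -> AlignmentCorrection:
    """Raw and time-smoothed correction vectors for X2.

    Raw correction c_i = weighted mean over mutual neighbors j of
    (x2_i - x1_j), i.e. the local displacement of X2 relative to X1, so
    that X2 - C lands on X1.  Weighting options: Gaussian kernel
    w ~ exp(-d^2/sigma^2) with sigma the median mutual-pair distance
    (default; down-weights far neighbors), inverse distance, or
    proportional to distance.  Samples without mutual neighbors get no
    raw vector; C is the componentwise running median (window =
    ``filter_order``) over time, with remaining gaps filled by temporal
    interpolation.
    """
    X2 = np.asarray(X2, dtype=float)
    X1 = np.asarray(X1, dtype=float)
    n2, d = X2.shape
    if len(pair_sets) != n2:
        raise ValueError("pair_sets must have one entry per X2 sample")
    all_d = np.concatenate(
        [
            np.linalg.norm(X1[p] - X2[i], axis=1)
            for i, p in enumerate(pair_sets)
            if p.size
        ]
        or [np.array([])]
    )
    if all_d.size == 0:
        raise AlignmentError("no mutual nearest neighbors between the two sets")
    sigma = float(np.median(all_d))
    raw = np.full((n2, d), np.nan)
    for i, p in enumerate(pair_sets):
        if not p.size:
            continue
        diffs = X2[i] - X1[p]
        dist = np.linalg.norm(diffs, axis=1)
        if weighting == "kernel":
            w = np.exp(-((dist / max(sigma, 1e-12)) ** 2))
        elif weighting == "inverse":
            w = 1.0 / (dist + 1e-12)
        elif weighting == "proportional":
            w = dist + 1e-12
        else:
            raise ValueError(f"unknown weighting '{weighting}'")
        if w.sum() < 1e-300:
            w = np.ones_like(w)
        raw[i] = (diffs * w[:, None]).sum(axis=0) / w.sum()
    C = (
        pd.DataFrame(raw)
        .rolling(filter_order, center=True, min_periods=1)
        .median()
        .interpolate(limit_direction="both")
        .to_numpy()
    )
    if np.isnan(C).any():
        raise AlignmentError("alignment failed: correction undefined everywhere")
    return AlignmentCorrection(pair_sets=pair_sets, raw=raw, C=C, sigma=sigma)


def align(X2: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Apply the correction: X2' = X2 - C."""
    X2 = np.asarray(X2, dtype=float)
    C = np.asarray(C, dtype=float)
    if X2.shape != C.shape:
        raise ValueError(f"shape mismatch: {X2.shape} vs {C.shape}")
    C = np.where(np.isnan(C), 0.0, C)
    return X2 - C


def align_to_reference(
    X_ref: np.ndarray,
    X: np.ndarray,
    K: int = 100,
    filter_order: int = 15,
    weighting: str = "kernel",
) -> tuple[np.ndarray, AlignmentCorrection]:
    """Convenience wrapper: MNN search, correction, subtraction."""
    pairs = mutual_nearest_neighbors(X_ref, X, K=K)
    corr = correction_vectors(X, X_ref, pairs, filter_order, weighting)
    return align(X, corr.C), corr
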