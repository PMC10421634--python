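"""Posture run sequences, dwell times and lag-T transition graphs.

Frame-wise posture labels are compressed into maximal constant runs;
transition lags count run changes, not frames.  The lag-T transition
matrix M has column-stochastic entries M[i, j] = P(next-but-(T-1) run
posture = i | current run posture = j); at T = 1 a run change always
switches posture, so the diagonal is identically zero by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class PostureRunSequence:
    """Maximal constant-label runs of a posture sequence."""

    postures: np.ndarray   # (n_runs,) posture id per run
    starts: np.ndarray     # (n_runs,) first frame of each run
    lengths: np.ndarray    # (n_runs,) frames
    fps: float = 30.0

    @property
    def n_runs(self) -> int:
        return len(self.postures)

    @property
    def dwell_seconds(self) -> np.ndarray:
        return self.lengths / self.fps

    def mean_dwell(self) -> float:
        return float(self.dwell_seconds.mean())


@dataclass
class TransitionGraph:
    """Lag-T posture transition probabilities as a weighted directed graph."""

    lag: int
    M: np.ndarray               # (n, n) column-stochastic on observed sources
    counts: np.ndarray          # (n, n) raw transition counts
    node_ids: np.ndarray        # posture ids for rows/cols
    column_totals: np.ndarray   # transitions observed out of each source
    zero_columns: np.ndarray    # bool, sources never observed

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def active_subgraph(self) -> "TransitionGraph":
        """Restrict to postures with any observed in- or out-transitions."""
        keep = (self.counts.sum(axis=0) + self.counts.sum(axis=1)) > 0
        idx = np.flatnonzero(keep)
        return TransitionGraph(
            lag=self.lag,
            M=self.M[np.ix_(idx, idx)],
            counts=self.counts[np.ix_(idx, idx)],
            node_ids=self.node_ids[idx],
            column_totals=self.column_totals[idx],
            zero_columns=self.zero_columns[idx],
        )


def compress_runs(labels: np.ndarray, fps: float = 30.0) -> PostureRunSequence:
    """Collapse per-frame labels into maximal constant runs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    starts = np.flatnonzero(np.r_[True, labels[1:] != labels[:-1]])
    lengths = np.diff(np.r_[starts, labels.size])
    return PostureRunSequence(
        postures=labels[starts].astype(int),
        starts=starts,
        lengths=lengths,
        fps=fps,
    )


def transition_matrix(
    runs: PostureRunSequence, T: int = 1, n_postures: int | None = None
) -> TransitionGraph:
    """Column-stochastic lag-T transition matrix over run postures.

    Counts pairs (run k -> run k+T); columns are sources, rows are
    destinations.  Sources never observed at this lag are flagged as
    zero columns rather than filled.
    """
    if T < 1:
        raise ValueError("lag T must be >= 1")
    if T >= runs.n_runs:
        raise ValueError(f"lag T={T} >= number of runs ({runs.n_runs})")
    n = int(n_postures if n_postures is not None else runs.postures.max() + 1)
    src = runs.postures[:-T]
    dst = runs.postures[T:]
    counts = np.zeros((n, n))
    np.add.at(counts, (dst, src), 1.0)
    col_tot = counts.sum(axis=0)
    zero_cols = col_tot == 0
    M = np.divide(counts, col_tot, out=np.zeros_like(counts), where=~zero_cols)
    return TransitionGraph(
        lag=T,
        M=M,
        counts=counts,
        node_ids=np.arange(n),
        column_totals=col_tot,
        zero_columns=zero_cols,
    )


def lag_sweep(
    runs: PostureRunSequence, lags, n_postures: int | None = None
) -> list[TransitionGraph]:
    """One TransitionGraph per requested lag on a shared posture space.

    Lags at or beyond the run count are dropped with a warning.
    """
    n = int(n_postures if n_postures is not None else runs.postures.max() + 1)
    out = []
    for T in lags:
        if T >= runs.n_runs:
            warnings.warn(f"lag {T} exceeds run count {runs.n_runs}; dropped")
            continue
        out.append(transition_matrix(runs, T=T, n_postures=n))
    return out
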