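"""2-D behavioral embedding, density estimation and watershed postures.

PCA scores are embedded with UMAP (min_dist=0.001, n_neighbors=20,
Euclidean), the embedded density is estimated with a Gaussian kernel on
a 200 x 200 lattice, and posture labels are the watershed basins of the
inverted density: each density peak becomes one posture, and every
embedded frame is labeled by the basin its grid cell belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima
from skimage.segmentation import watershed


@dataclass
class DensityGrid:
    """Kernel density of embedded points on a regular lattice."""

    values: np.ndarray      # (grid_n, grid_n), integrates to ~1
    x_edges: np.ndarray
    y_edges: np.ndarray
    bandwidth: tuple[float, float] = (0.0, 0.0)   # per-dim KDE sigma (data units)
    n_points: int = 0

    @property
    def cell_area(self) -> float:
        return float(
            (self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0])
        )

    def cell_of(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.clip(
            np.searchsorted(self.x_edges, points[:, 0], side="right") - 1,
            0,
            self.values.shape[0] - 1,
        )
        iy = np.clip(
            np.searchsorted(self.y_edges, points[:, 1], side="right") - 1,
            0,
            self.values.shape[1] - 1,
        )
        return ix, iy


@dataclass
class EmbeddingMap:
    points: np.ndarray            # (n, 2)
    density: DensityGrid
    basin_labels: np.ndarray      # (grid_n, grid_n) int, 0-based
    posture_labels: np.ndarray    # (n,) int

    @property
    def n_postures(self) -> int:
        return len(np.unique(self.posture_labels))


def umap_embed(
    scores: np.ndarray,
    min_dist: float = 0.001,
    n_neighbors: int = 20,
    metric: str = "euclidean",
    seed: int = 0,
) -> np.ndarray:
    """Embed PCA scores into 2-D with UMAP; deterministic given seed."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} samples, got {len(scores)}"
        )
    import umap

    reducer = umap.UMAP(
        n_components=2,
        min_dist=min_dist,
        n_neighbors=n_neighbors,
        metric=metric,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(scores), dtype=float)


def _silverman_bandwidth(x: np.ndarray) -> float:
    # d=2 Scott/Silverman factor n^(-1/(d+4))
    n = len(x)
    return float(np.std(x) * n ** (-1.0 / 6.0))


def density_map(points: np.ndarray, grid_n: int = 200, margin: float = 0.05) -> DensityGrid:
    """Gaussian kernel density on a grid_n x grid_n lattice.

    Implemented as a binned KDE: a 2-D histogram over the lattice
    followed by Gaussian smoothing with a per-dimension Silverman
    bandwidth, normalized so the density integrates to 1 over the grid.
    The lattice spans the data range plus a fractional margin.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points for a density estimate")
    spans = points.max(axis=0) - points.min(axis=0)
    if np.all(spans < 1e-12):
        raise ValueError("degenerate point set (all points identical)")
    pad = np.maximum(spans * margin, 1e-9)
    lo = points.min(axis=0) - pad
    hi = points.max(axis=0) + pad
    x_edges = np.linspace(lo[0], hi[0], grid_n + 1)
    y_edges = np.linspace(lo[1], hi[1], grid_n + 1)
    hist, _, _ = np.histogram2d(points[:, 0], points[:, 1], bins=[x_edges, y_edges])
    hx = _silverman_bandwidth(points[:, 0]) / (x_edges[1] - x_edges[0])
    hy = _silverman_bandwidth(points[:, 1]) / (y_edges[1] - y_edges[0])
    smooth = ndimage.gaussian_filter(hist, sigma=(max(hx, 0.5), max(hy, 0.5)))
    cell = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    total = smooth.sum() * cell
    bw = (
        max(hx, 0.5) * (x_edges[1] - x_edges[0]),
        max(hy, 0.5) * (y_edges[1] - y_edges[0]),
    )
    return DensityGrid(
        values=smooth / total,
        x_edges=x_edges,
        y_edges=y_edges,
        bandwidth=bw,
        n_points=len(points),
    )


def watershed_postures(
    grid: DensityGrid,
    points: np.ndarray,
    min_peak_rel: float = 1e-6,
    min_peak_points: float = 3.0,
    min_basin_frac: float = 0.002,
) -> EmbeddingMap:
    """Segment the inverted density into basins; label each point.

    Density peaks seed a watershed of the inverted density.  Two
    suppression rules remove spurious modes: peaks below
    ``min_peak_rel`` of the global maximum (numerical speckle in
    near-flat background) and peaks lower than the density that
    ``min_peak_points`` isolated samples would produce under the KDE
    bandwidth (modes supported by only a stray sample or two).  Every
    grid cell gets a basin, so every embedded point gets exactly one
    posture label; labels are relabeled consecutively over basins that
    contain points.
    """
    dens = grid.values
    peaks = local_maxima(dens)
    peaks &= dens > min_peak_rel * dens.max()
    if grid.n_points and grid.bandwidth[0] > 0:
        single = 1.0 / (grid.n_points * 2 * np.pi * grid.bandwidth[0] * grid.bandwidth[1])
        peaks &= dens > min_peak_points * single
    markers, n_peaks = ndimage.label(peaks)
    if n_peaks == 0:
        markers[np.unravel_index(np.argmax(dens), dens.shape)] = 1
    basins = watershed(-dens, markers=markers)
    points = np.asarray(points, dtype=float)
    ix, iy = grid.cell_of(points)
    # a posture is a recurring pose pattern: basins supported by only a
    # handful of stray frames are merged into their deepest neighbor
    min_support = max(5, int(round(min_basin_frac * len(points))))
    while True:
        raw_labels = basins[ix, iy]
        counts = np.bincount(raw_labels, minlength=basins.max() + 1)
        occupied = np.flatnonzero(counts > 0)
        weak = [b for b in occupied if counts[b] < min_support]
        if not weak or len(occupied) <= 1:
            break
        b = min(weak, key=lambda k: counts[k])
        mask = basins == b
        ring = ndimage.binary_dilation(mask) & ~mask
        nbrs = np.unique(basins[ring])
        nbrs = nbrs[nbrs != b]
        if nbrs.size == 0:
            break
        target = max(nbrs, key=lambda k: dens[basins == k].max())
        basins[mask] = target
    raw_labels = basins[ix, iy]
    # consecutive 0-based posture ids over basins that actually contain points
    uniq, posture_labels = np.unique(raw_labels, return_inverse=True)
    return EmbeddingMap(
        points=np.asarray(points, dtype=float),
        density=grid,
        basin_labels=basins - 1,
        posture_labels=posture_labels,
    )


def embed_and_segment(
    scores: np.ndarray,
    grid_n: int = 200,
    min_dist: float = 0.001,
    n_neighbors: int = 20,
    seed: int = 0,
) -> EmbeddingMap:
    """UMAP embedding -> density -> watershed posture labels."""
    pts = umap_embed(scores, min_dist=min_dist, n_neighbors=n_neighbors, seed=seed)
    grid = density_map(pts, grid_n=grid_n)
    return watershed_postures(grid, pts)
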