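"""Hierarchical structure of the transition graph.

Postures that transition preferentially among themselves form behavioral
modules; modules nest into a hierarchy.  This module implements:

- Paris agglomerative graph clustering (node-pair sampling distance,
  the multi-resolution relative of Louvain) on the symmetrized
  transition weights, producing a behavioral dendrogram;
- directed weighted Newman modularity, used to pick the dendrogram cut
  that maximizes within-module transition excess;
- the normalized Dasgupta score, a [0, 1] quality of a hierarchy on a
  graph (1 - cost / worst-case);
- adjusted mutual information between module assignments.

Paris merges the pair of clusters (a, b) minimizing
d(a, b) = p(a) p(b) / p(a, b), where p(a) is cluster a's share of total
edge weight and p(a, b) the share on the (a, b) link; merge heights are
these distances and are non-decreasing (the distance is reducible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

from .transitions import TransitionGraph


@dataclass
class BehavioralDendrogram:
    """Binary merge tree over posture nodes (scipy linkage convention).

    ``merges`` rows are (left, right, height, size); cluster ids < n are
    leaves (indexing ``leaf_ids``), ids >= n are earlier merges.
    """

    leaf_ids: np.ndarray      # (n,) posture ids at the leaves
    merges: np.ndarray        # (n-1, 4)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def _labels_after(self, n_merges: int) -> np.ndarray:
        n = self.n_leaves
        parent = np.arange(n + n_merges)
        for k in range(n_merges):
            a, b = int(self.merges[k, 0]), int(self.merges[k, 1])
            parent[a] = n + k
            parent[b] = n + k
        # resolve leaves to their top cluster
        labels = np.empty(n, dtype=int)
        for i in range(n):
            j = i
            while parent[j] != j and parent[j] < n + n_merges:
                j = parent[j]
            labels[i] = j
        _, labels = np.unique(labels, return_inverse=True)
        return labels

    def cut_height(self, height: float) -> dict:
        """Module per leaf: clusters formed by merges with height <= cut."""
        # heights are non-decreasing, so applying the prefix of merges at or
        # below the cut is equivalent to thresholding
        n_merges = 0
        while n_merges < len(self.merges) and self.merges[n_merges, 2] <= height:
            n_merges += 1
        labels = self._labels_after(n_merges)
        return dict(zip(self.leaf_ids.tolist(), labels.tolist()))

    def cut_k(self, k: int) -> dict:
        """Module per leaf for exactly k clusters (merge order truncation)."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError("k out of range")
        labels = self._labels_after(self.n_leaves - k)
        return dict(zip(self.leaf_ids.tolist(), labels.tolist()))

    def leaves_under(self) -> list[set]:
        """Leaf-index sets under each internal merge node."""
        n = self.n_leaves
        sets: list[set] = [{i} for i in range(n)]
        for a, b, _, _ in self.merges:
            sets.append(sets[int(a)] | sets[int(b)])
        return sets[n:]

    def to_newick(self) -> str:
        n = self.n_leaves
        reprs = [str(self.leaf_ids[i]) for i in range(n)]
        base_h = [0.0] * n
        for a, b, h, _ in self.merges:
            a, b = int(a), int(b)
            la = max(h - base_h[a], 0.0)
            lb = max(h - base_h[b], 0.0)
            reprs.append(f"({reprs[a]}:{la:.6g},{reprs[b]}:{lb:.6g})")
            base_h.append(h)
        return reprs[-1] + ";"


@dataclass
class ModuleAssignment:
    """A flat partition of postures into modules, with its modularity."""

    modules: dict             # posture id -> module id
    cut_height: float
    Q: float
    curve: tuple | None = None   # (heights, Q values, module counts)

    @property
    def n_modules(self) -> int:
        return len(set(self.modules.values()))


def _weight_matrix(g) -> np.ndarray:
    if isinstance(g, TransitionGraph):
        return g.M
    return np.asarray(g, dtype=float)


def paris_dendrogram(g) -> BehavioralDendrogram:
    """Paris agglomeration of the (symmetrized) weighted graph.

    Accepts a TransitionGraph or a square weight matrix.  Directed
    weights are symmetrized; clustering is deterministic (ties broken by
    lowest cluster index).  Disconnected components are clustered
    separately and joined at twice the maximum finite height, with a
    warning.
    """
    if isinstance(g, TransitionGraph):
        node_ids = g.node_ids
        W = g.M
    else:
        W = np.asarray(g, dtype=float)
        node_ids = np.arange(W.shape[0])
    n = W.shape[0]
    if n < 2:
        raise ValueError("graph must have at least 2 nodes")
    A = (W + W.T) / 2.0
    if not np.any(A > 0):
        raise ValueError("graph has no edges")

    w_tot = A.sum()
    size = {i: 1 for i in range(n)}
    deg = {i: A[i].sum() for i in range(n)}
    # adjacency between live clusters (symmetric, excludes internal weight)
    adj = {i: {j: A[i, j] for j in range(n) if j != i and A[i, j] > 0} for i in range(n)}
    merges = []
    next_id = n
    live = set(range(n))

    def distance(a, b):
        w = adj[a].get(b, 0.0)
        if w <= 0:
            return np.inf
        return (deg[a] * deg[b]) / (w * w_tot)

    max_h = 0.0
    while len(live) > 1:
        best = (np.inf, None, None)
        for a in sorted(live):
            for b, w in adj[a].items():
                if b <= a:
                    continue
                d = distance(a, b)
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        if a is None:
            # remaining clusters are disconnected: join at top height
            warnings.warn("disconnected transition graph; joining components")
            rem = sorted(live)
            h = 2.0 * max_h if max_h > 0 else 1.0
            a = rem[0]
            for b in rem[1:]:
                merges.append((a, b, h, size[a] + size[b]))
                size[next_id] = size[a] + size[b]
                deg[next_id] = deg[a] + deg[b]
                adj[next_id] = {}
                live -= {a, b}
                live.add(next_id)
                a = next_id
                next_id += 1
            break
        # merge a and b into next_id
        max_h = max(max_h, d)
        merges.append((a, b, d, size[a] + size[b]))
        size[next_id] = size[a] + size[b]
        deg[next_id] = deg[a] + deg[b]
        new_adj = {}
        for src in (a, b):
            for c, w in adj[src].items():
                if c in (a, b):
                    continue
                new_adj[c] = new_adj.get(c, 0.0) + w
        adj[next_id] = new_adj
        for c, w in new_adj.items():
            adj[c].pop(a, None)
            adj[c].pop(b, None)
            adj[c][next_id] = w
        del adj[a], adj[b]
        live -= {a, b}
        live.add(next_id)
        next_id += 1

    return BehavioralDendrogram(
        leaf_ids=np.asarray(node_ids), merges=np.asarray(merges, dtype=float)
    )


def modularity_score(g, partition: dict | ModuleAssignment, directed: bool = True) -> float:
    """Directed weighted Newman modularity of a partition.

    Q = (1/m) sum_ij [A_ij - k_i^out k_j^in / m] delta(c_i, c_j), with A
    the weight matrix and m its total weight.  The single-module
    partition scores exactly 0.  ``directed=False`` symmetrizes first.
    """
    if isinstance(g, TransitionGraph):
        A = g.M
        node_ids = g.node_ids
    else:
        A = np.asarray(g, dtype=float)
        node_ids = np.arange(A.shape[0])
    if isinstance(partition, ModuleAssignment):
        partition = partition.modules
    if not directed:
        A = (A + A.T) / 2.0
    m = A.sum()
    if m <= 0:
        raise ValueError("empty graph")
    labels = np.asarray([partition[i] for i in node_ids])
    k_out = A.sum(axis=1)
    k_in = A.sum(axis=0)
    same = labels[:, None] == labels[None, :]
    Q = ((A - np.outer(k_out, k_in) / m) * same).sum() / m
    return float(Q)


DEFAULT_CUT_RANGE = (0.4, 1.4)
DEFAULT_N_CUTS = 51


def best_cut(
    d: BehavioralDendrogram,
    g,
    heights: np.ndarray | None = None,
    directed: bool = True,
) -> ModuleAssignment:
    """Modularity-maximizing dendrogram cut.

    Evaluates Q at equally spaced cut heights (default 51 over
    [0.4, 1.4]); the range auto-extends with a warning when the tree's
    merge heights fall outside it.  Ties prefer the coarser (fewer
    modules) partition.
    """
    if heights is None:
        tree_h = d.heights()
        lo, hi = DEFAULT_CUT_RANGE
        if tree_h.min() < lo or tree_h.max() > hi:
            lo, hi = min(lo, float(tree_h.min()) * 0.99), max(
                hi, float(tree_h.max()) * 1.01
            )
            warnings.warn(
                f"dendrogram heights outside default cut range; using [{lo:.3g}, {hi:.3g}]"
            )
        heights = np.linspace(lo, hi, DEFAULT_N_CUTS)
    qs, counts, parts = [], [], []
    for h in heights:
        part = d.cut_height(h)
        qs.append(modularity_score(g, part, directed=directed))
        counts.append(len(set(part.values())))
        parts.append(part)
    qs = np.asarray(qs)
    counts = np.asarray(counts)
    best_q = qs.max()
    tied = np.flatnonzero(np.isclose(qs, best_q, atol=1e-12))
    k = tied[np.argmin(counts[tied])]
    if counts[k] == 1:
        warnings.warn("all cuts trivial: best partition has a single module")
    return ModuleAssignment(
        modules=parts[k],
        cut_height=float(heights[k]),
        Q=float(qs[k]),
        curve=(np.asarray(heights), qs, counts),
    )


def dasgupta_score(d: BehavioralDendrogram, g) -> float:
    """Normalized Dasgupta quality of a tree on a weighted graph.

    cost = sum over node pairs of w_ij * |leaves under lca(i, j)|;
    score = 1 - cost / (n * total weight), so 1 is best.  Edge weights
    are symmetrized; self-loops ignored.
    """
    A = _weight_matrix(g)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    n = d.n_leaves
    if A.shape[0] != n:
        raise ValueError("tree and graph node counts differ")
    if n < 2:
        raise ValueError("need at least 2 leaves")
    total = A.sum() / 2.0
    if total <= 0:
        raise ValueError("graph has no edges")
    sets = [{i} for i in range(n)]
    cost = 0.0
    for a, b, _, sz in d.merges:
        a, b = int(a), int(b)
        left, right = sets[a], sets[b]
        li = np.asarray(sorted(left))
        ri = np.asarray(sorted(right))
        cost += sz * A[np.ix_(li, ri)].sum()
        sets.append(left | right)
    return float(1.0 - cost / (n * total))


def ami(p1, p2) -> float:
    """Adjusted mutual information between two module assignments.

    Accepts dicts (posture id -> module) or aligned label arrays.
    Dict inputs are compared over the shared posture universe; postures
    missing from one side are dropped.  Chance-corrected under the
    permutation model with arithmetic mean normalization.
    """
    if isinstance(p1, ModuleAssignment):
        p1 = p1.modules
    if isinstance(p2, ModuleAssignment):
        p2 = p2.modules
    if isinstance(p1, dict) and isinstance(p2, dict):
        shared = sorted(set(p1) & set(p2))
        if not shared:
            raise ValueError("no shared postures between partitions")
        a = [p1[k] for k in shared]
        b = [p2[k] for k in shared]
    else:
        a = np.asarray(p1)
        b = np.asarray(p2)
        if a.shape != b.shape:
            raise ValueError("label arrays must be aligned")
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


def random_binary_tree(n_leaves: int, rng: np.random.Generator) -> BehavioralDendrogram:
    """Uniformly random merge order; heights = merge index (topology null)."""
    live = list(range(n_leaves))
    merges = []
    sizes = {i: 1 for i in range(n_leaves)}
    next_id = n_leaves
    step = 0
    while len(live) > 1:
        i, j = rng.choice(len(live), size=2, replace=False)
        a, b = live[i], live[j]
        step += 1
        merges.append((a, b, float(step), sizes[a] + sizes[b]))
        sizes[next_id] = sizes[a] + sizes[b]
        live = [x for x in live if x not in (a, b)] + [next_id]
        next_id += 1
    return BehavioralDendrogram(
        leaf_ids=np.arange(n_leaves), merges=np.asarray(merges, dtype=float)
    )
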