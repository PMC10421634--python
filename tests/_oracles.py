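"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by direct enumeration of its
definition, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def brute_mutual_nn(X1, X2, K):
    """Mutual K-NN sets by exhaustive O(n^2) distance enumeration."""
    X1, X2 = np.asarray(X1, float), np.asarray(X2, float)
    d = np.linalg.norm(X2[:, None, :] - X1[None, :, :], axis=2)  # (n2, n1)
    k1 = min(K, X1.shape[0])
    k2 = min(K, X2.shape[0])
    knn_in_x1 = [set(np.argsort(row, kind="stable")[:k1]) for row in d]
    knn_in_x2 = [set(np.argsort(col, kind="stable")[:k2]) for col in d.T]
    return [
        sorted(j for j in knn_in_x1[i] if i in knn_in_x2[j])
        for i in range(X2.shape[0])
    ]


def brute_transition_matrix(run_postures, T, n):
    """Column-stochastic lag-T matrix by explicit pair counting."""
    counts = np.zeros((n, n))
    seq = list(run_postures)
    for k in range(len(seq) - T):
        j, i = seq[k], seq[k + T]
        counts[i, j] += 1
    M = np.zeros_like(counts)
    for j in range(n):
        tot = counts[:, j].sum()
        if tot > 0:
            M[:, j] = counts[:, j] / tot
    return M, counts


def brute_directed_modularity(A, labels):
    """Directed Newman modularity by literal double loop over the formula."""
    A = np.asarray(A, float)
    n = A.shape[0]
    m = A.sum()
    k_out = [A[i, :].sum() for i in range(n)]
    k_in = [A[:, j].sum() for j in range(n)]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - k_out[i] * k_in[j] / m
    return q / m


def brute_dasgupta(leaf_sets_by_internal, A, n):
    """Dasgupta score via explicit smallest-common-ancestor lookup.

    ``leaf_sets_by_internal``: list of leaf-index sets, one per internal
    node, in any order; the lca of (i, j) is the smallest set containing
    both.
    """
    A = (np.asarray(A, float) + np.asarray(A, float).T) / 2.0
    total = 0.0
    cost = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            w = A[i, j]
            total += w
            if w == 0:
                continue
            lca_size = min(
                len(s) for s in leaf_sets_by_internal if i in s and j in s
            )
            cost += w * lca_size
    return 1.0 - cost / (n * total)


def brute_ami(a, b):
    """AMI with hypergeometric-model expected MI, arithmetic normalization."""
    a = np.asarray(a)
    b = np.asarray(b)
    N = len(a)
    cats_a, inv_a = np.unique(a, return_inverse=True)
    cats_b, inv_b = np.unique(b, return_inverse=True)
    R, C = len(cats_a), len(cats_b)
    nij = np.zeros((R, C))
    for x, y in zip(inv_a, inv_b):
        nij[x, y] += 1
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    mi = 0.0
    for i in range(R):
        for j in range(C):
            if nij[i, j] > 0:
                mi += (nij[i, j] / N) * np.log(N * nij[i, j] / (ai[i] * bj[j]))
    emi = 0.0
    for i in range(R):
        for j in range(C):
            lo = int(max(ai[i] + bj[j] - N, 1))
            hi = int(min(ai[i], bj[j]))
            for n_ij in range(lo, hi + 1):
                p = hypergeom.pmf(n_ij, N, ai[i], bj[j])
                emi += p * (n_ij / N) * np.log(N * n_ij / (ai[i] * bj[j]))
    h_a = -sum(p * np.log(p) for p in ai / N if p > 0)
    h_b = -sum(p * np.log(p) for p in bj / N if p > 0)
    denom = 0.5 * (h_a + h_b) - emi
    if denom == 0:
        return 1.0 if (R == C == 1) else 0.0
    return (mi - emi) / denom


def random_similarity_transform(rng):
    """Random proper rotation + translation + positive uniform scale."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=1.0, size=3)
    s = float(np.exp(rng.normal(scale=0.3)))
    return R, t, s
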