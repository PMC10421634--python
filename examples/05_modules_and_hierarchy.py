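"""Behavioral modules and their hierarchy from the transition graph.

Builds the lag-1 posture transition matrix from a planted label
sequence, clusters it with Paris, picks the modularity-maximizing
dendrogram cut, and scores the hierarchy (Dasgupta) against random
trees plus a label-shuffle null for the modularity itself.
"""

import numpy as np

from ethokit import (
    ami,
    best_cut,
    dasgupta_score,
    generate_markov_labels,
    make_repertoire,
    paris_dendrogram,
    shuffle_null,
)
from ethokit.hierarchy import random_binary_tree
from ethokit.transitions import compress_runs, transition_matrix

# two-level hierarchy: 4 modules nested in 2 super-modules
rep = make_repertoire(n_postures=12, n_modules=4, n_super=2, seed=0)
labels, truth = generate_markov_labels(rep, 100000, seed=1)
runs = compress_runs(labels)

g = transition_matrix(runs, T=1, n_postures=12).active_subgraph()
dend = paris_dendrogram(g)
part = best_cut(dend, g)
print(f"best cut at height {part.cut_height:.3f}: {part.n_modules} modules, "
      f"modularity Q = {part.Q:.3f}")

planted = {i: int(m) for i, m in enumerate(rep.module_of_posture)}
print(f"module AMI vs planted partition: {ami(part.modules, planted):.3f}")

null = shuffle_null(runs, metric="modularity", n=100, seed=2)
print(f"label-shuffle null: observed Q {null.observed:.3f}, "
      f"null mean {null.permuted.mean():.3f}, p = {null.p_value:.4f}")

obs = dasgupta_score(dend, g)
rng = np.random.default_rng(3)
tree_null = [dasgupta_score(random_binary_tree(g.n_nodes, rng), g) for _ in range(100)]
print(f"Dasgupta score {obs:.3f} vs random trees "
      f"(95th percentile {np.quantile(tree_null, 0.95):.3f})")

supers = {i: int(rep.super_of_module[m]) for i, m in enumerate(rep.module_of_posture)}
print(f"high cut (2 clusters) AMI vs planted super-modules: "
      f"{ami(dend.cut_k(2), supers):.3f}")
# A modularity p of 1/101 means the observed graph beat all 100
# shuffles; the Dasgupta excess over random trees shows the transition
# structure is genuinely hierarchical, not just modular.
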