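"""Paris clustering, modularity, Dasgupta score and AMI tests.

Every metric is cross-checked against an independent brute-force
implementation on small graphs.
"""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))
from _oracles import brute_ami, brute_dasgupta, brute_directed_modularity

from ethokit import (
    ami,
    best_cut,
    dasgupta_score,
    generate_markov_labels,
    make_repertoire,
    modularity_score,
    paris_dendrogram,
)
from ethokit.hierarchy import random_binary_tree
from ethokit.transitions import compress_runs, transition_matrix


def two_cliques(eps=0.01):
    """Two 3-node cliques joined by one weak edge."""
    A = np.zeros((6, 6))
    for grp in ([0, 1, 2], [3, 4, 5]):
        for i in grp:
            for j in grp:
                if i != j:
                    A[i, j] = 1.0
    A[2, 3] = A[3, 2] = eps
    return A


class TestParis:
    def test_two_cliques_merge_order(self):
        """Within-clique merges come first; cliques join last."""
        d = paris_dendrogram(two_cliques())
        sets = d.leaves_under()
        for s in sets[:4]:
            assert s <= {0, 1, 2} or s <= {3, 4, 5}
        assert sets[-1] == set(range(6))

    def test_two_nodes_single_merge(self):
        d = paris_dendrogram(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert len(d.merges) == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(0.1, 1.0, (8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        d1 = paris_dendrogram(A)
        perm = rng.permutation(8)
        d2 = paris_dendrogram(A[np.ix_(perm, perm)])
        sets1 = {frozenset(s) for s in d1.leaves_under()}
        inv = np.argsort(perm)
        sets2 = {
            frozenset(int(perm[i]) for i in s) for s in d2.leaves_under()
        }
        assert sets1 == sets2
        _ = inv

    def test_heights_non_decreasing(self, repertoire):
        labels, _ = generate_markov_labels(repertoire, 50000, seed=5)
        g = transition_matrix(compress_runs(labels), T=1).active_subgraph()
        d = paris_dendrogram(g)
        assert np.all(np.diff(d.heights()) >= -1e-12)

    def test_disconnected_components_joined_with_warning(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        with pytest.warns(UserWarning, match="disconnected"):
            d = paris_dendrogram(A)
        assert len(d.merges) == 3

    def test_determinism(self):
        A = two_cliques()
        d1, d2 = paris_dendrogram(A), paris_dendrogram(A)
        np.testing.assert_array_equal(d1.merges, d2.merges)


class TestModularity:
    def test_two_disconnected_pairs_half(self):
        """Hand-expanded formula on the 4-node two-community graph: Q=1/2."""
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        part = {0: 0, 1: 0, 2: 1, 3: 1}
        assert modularity_score(A, part) == pytest.approx(0.5, abs=1e-12)

    def test_single_module_exactly_zero(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 1, (7, 7))
        assert modularity_score(A, {i: 0 for i in range(7)}) == pytest.approx(0, abs=1e-12)

    def test_matches_brute_force_all_partitions_small(self):
        """Exhaustive agreement with the literal formula on <=6 node graphs."""
        from itertools import product

        rng = np.random.default_rng(7)
        for n in (3, 4, 5):
            A = rng.uniform(0, 1, (n, n))
            for assignment in product(range(2), repeat=n):
                part = dict(enumerate(assignment))
                got = modularity_score(A, part)
                want = brute_directed_modularity(A, list(assignment))
                assert got == pytest.approx(want, abs=1e-12)

    def test_random_partition_mean_zero(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(0, 1, (10, 10))
        qs = [
            modularity_score(A, dict(enumerate(rng.integers(0, 3, 10))))
            for _ in range(1000)
        ]
        se = np.std(qs) / np.sqrt(len(qs))
        assert abs(np.mean(qs)) < 3 * se + 1e-3

    def test_matches_networkx_directed(self):
        """Cross-check against networkx community modularity on digraphs."""
        import networkx as nx

        rng = np.random.default_rng(3)
        A = rng.uniform(0, 1, (6, 6))
        np.fill_diagonal(A, 0)
        G = nx.from_numpy_array(A, create_using=nx.DiGraph)
        comms = [{0, 1, 2}, {3, 4, 5}]
        want = nx.community.modularity(G, comms, weight="weight")
        part = {i: 0 if i < 3 else 1 for i in range(6)}
        assert modularity_score(A, part) == pytest.approx(want, abs=1e-12)


class TestBestCut:
    def test_planted_modules_recovered(self, repertoire):
        labels, gt = generate_markov_labels(repertoire, 100000, seed=6)
        g = transition_matrix(compress_runs(labels), T=1).active_subgraph()
        part = best_cut(paris_dendrogram(g), g)
        assert part.n_modules == 4
        planted = {i: int(m) for i, m in enumerate(repertoire.module_of_posture)}
        assert ami(part.modules, planted) >= 0.9

    def test_disconnected_cliques_best_cut(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        with pytest.warns(UserWarning, match="disconnected"):
            d = paris_dendrogram(A)
        part = best_cut(d, A)
        assert part.n_modules == 2
        assert part.Q == pytest.approx(0.5, abs=1e-12)

    def test_uniform_graph_near_zero(self):
        A = np.ones((6, 6)) - np.eye(6)
        d = paris_dendrogram(A)
        part = best_cut(d, A)
        assert part.Q <= 0.05

    def test_q_is_max_over_curve(self, repertoire):
        labels, _ = generate_markov_labels(repertoire, 50000, seed=8)
        g = transition_matrix(compress_runs(labels), T=1).active_subgraph()
        part = best_cut(paris_dendrogram(g), g)
        heights, qs, counts = part.curve
        assert part.Q == pytest.approx(qs.max())


class TestDasgupta:
    def test_matches_brute_force_lca_oracle(self):
        """Explicit-LCA evaluation agrees on random small graphs and trees."""
        rng = np.random.default_rng(12)
        for n in (4, 6, 8):
            A = rng.uniform(0, 1, (n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0)
            d = paris_dendrogram(A)
            want = brute_dasgupta(d.leaves_under(), A, n)
            assert dasgupta_score(d, A) == pytest.approx(want, abs=1e-12)

    def test_star_graph_oracle(self):
        n = 6
        A = np.zeros((n, n))
        A[0, 1:] = A[1:, 0] = 1.0
        d = random_binary_tree(n, np.random.default_rng(0))
        want = brute_dasgupta(d.leaves_under(), A, n)
        assert dasgupta_score(d, A) == pytest.approx(want, abs=1e-12)

    def test_generating_tree_beats_random_trees(self):
        """The planted hierarchy's own tree scores above the random-tree mean."""
        rep = make_repertoire(
            n_postures=8, n_modules=4, n_super=2, within_module_prob=0.7,
            within_super_prob=0.2, seed=2,
        )
        labels, _ = generate_markov_labels(rep, 100000, seed=3)
        g = transition_matrix(compress_runs(labels), T=1).active_subgraph()
        d = paris_dendrogram(g)
        observed = dasgupta_score(d, g)
        rng = np.random.default_rng(4)
        null = [
            dasgupta_score(random_binary_tree(g.n_nodes, rng), g) for _ in range(100)
        ]
        assert observed > np.mean(null)

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0, 1, (7, 7))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        d = paris_dendrogram(A)
        perm = rng.permutation(7)
        d2 = paris_dendrogram(A[np.ix_(perm, perm)])
        assert dasgupta_score(d, A) == pytest.approx(
            dasgupta_score(d2, A[np.ix_(perm, perm)]), abs=1e-9
        )


class TestAMI:
    def test_identical_partitions_one(self):
        p = {i: i % 3 for i in range(30)}
        assert ami(p, p) == pytest.approx(1.0)

    def test_label_permutation_invariant(self):
        p1 = {i: i % 3 for i in range(30)}
        p2 = {i: (i % 3 + 1) % 3 for i in range(30)}
        assert ami(p1, p2) == pytest.approx(1.0)

    def test_independent_partitions_mean_zero(self):
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(100):
            a = rng.integers(0, 5, 200)
            b = rng.integers(0, 5, 200)
            vals.append(ami(a, b))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) <= 3 * se + 1e-3

    def test_matches_brute_force_emi_oracle(self):
        """Hypergeometric-EMI formula agreement on random small partitions."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.integers(0, 3, 20)
            b = rng.integers(0, 4, 20)
            assert ami(a, b) == pytest.approx(brute_ami(a, b), abs=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 4, 100)
        b = rng.integers(0, 3, 100)
        assert ami(a, b) == pytest.approx(ami(b, a), abs=1e-12)
        assert ami(a, b) <= 1.0

    def test_dict_universe_intersection(self):
        p1 = {i: i % 2 for i in range(20)}
        p2 = {i: i % 2 for i in range(5, 25)}
        assert ami(p1, p2) == pytest.approx(1.0)
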