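"""Graph-metric tests: closed forms, brute-force oracles on small random
graphs, and invariants under vertex deletion."""

import numpy as np
import pytest

from ablatio import topology as tp
from conftest import random_digraph


# ----------------------------------------------------------- oracles
# Independent brute-force implementations used only for cross-checking.

def oracle_kcore(A):
    n = A.shape[0]
    best = 0
    for K in range(0, 2 * n):
        alive = list(range(n))
        changed = True
        while changed and alive:
            changed = False
            for v in list(alive):
                idx = [u for u in alive if u != v]
                deg = sum(A[v, u] + A[u, v] for u in idx)
                if deg < K:
                    alive.remove(v)
                    changed = True
        if alive:
            best = K
        else:
            break
    return best


def oracle_distances(A, s):
    """Plain BFS distances from s."""
    n = A.shape[0]
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if A[u, v] and v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def oracle_closeness(A, v):
    dist = oracle_distances(A, v)
    far = sum(d for u, d in dist.items() if u != v)
    if far == 0:
        return 0.0
    return A.shape[0] / far


def oracle_clustering(A, v):
    nbrs = [u for u in range(A.shape[0]) if A[v, u]]
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(A[a, b] for a in nbrs for b in nbrs if a != b)
    return links / (k * (k - 1))


def oracle_betweenness(A, v):
    """Sum sigma_st(v)/sigma_st over ordered pairs, by explicit shortest-path
    counting on BFS layers, normalized by (n-1)(n-2)."""
    n = A.shape[0]

    def sigma_from(s):
        dist = oracle_distances(A, s)
        sig = {s: 1}
        for u in sorted(dist, key=dist.get):
            if u == s:
                continue
            sig[u] = sum(sig[w] for w in dist
                         if A[w, u] and dist[w] == dist[u] - 1)
        return dist, sig

    total = 0.0
    for s in range(n):
        if s == v:
            continue
        dist_s, sig_s = sigma_from(s)
        dist_v, sig_v = sigma_from(v)
        for t in range(n):
            if t in (s, v) or t not in dist_s:
                continue
            if v in dist_s and t in dist_v and dist_s[v] + dist_v[t] == dist_s[t]:
                total += sig_s[v] * sig_v[t] / sig_s[t]
    return total / ((n - 1) * (n - 2))


# ------------------------------------------------------- closed forms

def complete(n):
    A = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(A, 0)
    return A


def cycle(n):
    A = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        A[i, (i + 1) % n] = 1
    return A


class TestClosedForms:
    def test_kcore_complete_counts_in_and_out_arcs(self):
        assert tp.kcore_number(complete(5)) == 8

    def test_kcore_directed_cycle(self):
        assert tp.kcore_number(cycle(6)) == 2

    def test_scc_single_cycle_and_disjoint_cycles(self):
        assert tp.scc_count(cycle(5)) == 1
        two = np.zeros((6, 6), dtype=np.int8)
        two[:3, :3] = cycle(3)
        two[3:, 3:] = cycle(3)
        assert tp.scc_count(two) == 2

    def test_mean_degrees_complete_and_empty(self):
        assert tp.mean_degrees(complete(7)) == (6.0, 6.0)
        assert tp.mean_degrees(np.zeros((4, 4), dtype=np.int8)) == (0.0, 0.0)

    def test_clustering_extremes(self):
        A = complete(6)
        assert tp.local_clustering(A, 0) == 1.0
        # hub pointing at an edgeless out-neighborhood
        B = np.zeros((5, 5), dtype=np.int8)
        B[0, 1:] = 1
        assert tp.local_clustering(B, 0) == 0.0

    def test_clustering_low_out_degree_is_zero(self):
        B = np.zeros((4, 4), dtype=np.int8)
        B[0, 1] = 1
        assert tp.local_clustering(B, 0) == 0.0
        assert tp.local_clustering(B, 2) == 0.0

    def test_closeness_complete_graph(self):
        A = complete(5)
        for v in range(5):
            assert tp.closeness_centrality(A, v) == pytest.approx(5 / 4)

    def test_closeness_path_head_and_sink(self):
        A = np.zeros((3, 3), dtype=np.int8)
        A[0, 1] = A[1, 2] = 1
        assert tp.closeness_centrality(A, 0) == pytest.approx(1.0)  # 3/(1+2)
        assert tp.closeness_centrality(A, 2) == 0.0  # reaches nobody

    def test_betweenness_star(self):
        A = np.zeros((5, 5), dtype=np.int8)
        for leaf in range(1, 5):
            A[0, leaf] = A[leaf, 0] = 1
        assert tp.betweenness_centrality(A, 0) == pytest.approx(1.0)
        assert tp.betweenness_centrality(A, 1) == pytest.approx(0.0)

    def test_betweenness_requires_three_vertices(self):
        with pytest.raises(ValueError):
            tp.betweenness_centrality(complete(2), 0)


# ------------------------------------------------ oracle cross-checks

@pytest.mark.parametrize("trial", range(25))
def test_all_metrics_match_bruteforce_on_random_graphs(trial, rng):
    """Each metric equals its independent brute-force oracle on >= 100
    small random graphs (25 trials x 4 graphs)."""
    for p in (0.15, 0.3, 0.5, 0.8):
        n = int(rng.integers(4, 11))
        A = random_digraph(rng, n, p)
        assert tp.kcore_number(A) == oracle_kcore(A)
        for v in range(n):
            assert tp.local_clustering(A, v) == pytest.approx(
                oracle_clustering(A, v))
            assert tp.closeness_centrality(A, v) == pytest.approx(
                oracle_closeness(A, v))
            assert tp.betweenness_centrality(A, v) == pytest.approx(
                oracle_betweenness(A, v), abs=1e-9)


def test_mean_in_equals_mean_out_always(rng):
    for _ in range(50):
        n = int(rng.integers(2, 15))
        A = random_digraph(rng, n, float(rng.random()))
        mi, mo = tp.mean_degrees(A)
        assert mi == pytest.approx(mo)


def test_kcore_monotone_under_deletion(rng):
    A = random_digraph(rng, 12, 0.4)
    prev = tp.kcore_number(A)
    keep = list(range(12))
    while len(keep) > 2:
        keep.pop(int(rng.integers(len(keep))))
        k = tp.kcore_number(A[np.ix_(keep, keep)])
        assert k <= prev
        prev = k


# --------------------------------------------------- deletion tracking

class TestTrackDeletions:
    def test_empty_order_keeps_globals_identical(self, rng):
        A = random_digraph(rng, 8, 0.4)
        rep = tp.track_deletions(A, [])
        assert rep.kcore_initial == rep.kcore_final
        assert rep.scc_initial == rep.scc_final
        assert rep.mean_in_degree_initial == rep.mean_in_degree_final

    def test_local_metrics_computed_on_pre_deletion_graph(self, rng):
        A = random_digraph(rng, 9, 0.5)
        order = [3, 7, 0]
        rep = tp.track_deletions(A, order)
        # first deletion must match metrics on the original graph
        first = rep.deletions[0]
        assert first["local_clustering"] == pytest.approx(
            oracle_clustering(A, 3))
        assert first["closeness_centrality"] == pytest.approx(
            oracle_closeness(A, 3))
        # second deletion: on the graph with vertex 3 removed
        keep = [i for i in range(9) if i != 3]
        B = A[np.ix_(keep, keep)]
        v7 = keep.index(7)
        second = rep.deletions[1]
        assert second["local_clustering"] == pytest.approx(
            oracle_clustering(B, v7))

    def test_cycle_deletions_keep_single_scc(self):
        A = cycle(6)
        rep = tp.track_deletions(A, [0, 1, 2, 3, 4])
        assert rep.scc_initial == 1
        assert rep.scc_final == 1  # a singleton is trivially strongly connected

    def test_repeated_vertex_rejected(self):
        with pytest.raises(ValueError):
            tp.track_deletions(complete(4), [1, 1])
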