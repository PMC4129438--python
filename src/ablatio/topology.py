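"""Graph-topology metrics tracked through a deletion sequence.

The network underlying each simulation is a directed graph on ``n`` vertices
given by its adjacency matrix ``A`` (``A[i, j] == 1`` iff there is a synapse
from ``i`` to ``j``).  Six canonical metrics are computed: three global
(K-core number, number of strongly connected components, mean in/out degree)
and three local (local cluster coefficient over out-neighbors, closeness
centrality, betweenness centrality).  :func:`track_deletions` evaluates the
local metrics of each deleted vertex on the graph *before* its removal, and
the global metrics on the initial and final graphs, mirroring how structural
collapse is ruled out as an explanation for rhythm cessation.

Conventions for degenerate cases (the defining formulas are otherwise
undefined):

* local cluster coefficient is 0 when the out-degree is < 2;
* closeness centrality is 0 for a vertex with no reachable others;
* betweenness requires ``n >= 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "kcore_number",
    "scc_count",
    "mean_degrees",
    "local_clustering",
    "closeness_centrality",
    "betweenness_centrality",
    "track_deletions",
    "TopologyReport",
]


def _as_adjacency(graph) -> np.ndarray:
    """Coerce input (ndarray or object with ``.adjacency``) to a dense 0/1 array."""
    A = getattr(graph, "adjacency", graph)
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency matrix must be square")
    return (A != 0).astype(np.int8)


def kcore_number(graph) -> int:
    """Largest K such that the K-core (peeling on total degree in+out) is non-empty.

    An in-arc and an out-arc each count as one edge, so a vertex of a complete
    directed graph on n vertices has degree 2(n-1).
    """
    A = _as_adjacency(graph)
    if A.shape[0] == 0:
        raise ValueError("K-core number is undefined for the empty graph")
    G = nx.from_numpy_array(A, create_using=nx.DiGraph)
    core = nx.core_number(G)  # directed: uses in+out degree
    return max(core.values())


def scc_count(graph) -> int:
    """Number of strongly connected components; 1 means no isolated islands."""
    A = _as_adjacency(graph)
    if A.shape[0] == 0:
        return 0
    n_comp, _ = connected_components(csr_matrix(A), directed=True, connection="strong")
    return int(n_comp)


def mean_degrees(graph) -> tuple[float, float]:
    """(mean in-degree, mean out-degree); the two are always equal (= |E|/n)."""
    A = _as_adjacency(graph)
    n = A.shape[0]
    if n == 0:
        raise ValueError("degree of the empty graph is undefined")
    return float(A.sum(axis=0).mean()), float(A.sum(axis=1).mean())


def local_clustering(graph, v: int) -> float:
    """Local cluster coefficient of vertex ``v`` over its out-neighborhood.

    C_v = (# ordered linked pairs among out-neighbors) / (k_v (k_v - 1)),
    where k_v is the out-degree; defined as 0 when k_v < 2.
    """
    A = _as_adjacency(graph)
    _check_vertex(A, v)
    nbrs = np.flatnonzero(A[v])
    k = nbrs.size
    if k < 2:
        return 0.0
    sub = A[np.ix_(nbrs, nbrs)]
    return float(sub.sum()) / (k * (k - 1))


def closeness_centrality(graph, v: int) -> float:
    """n times the inverse farness of ``v``.

    Farness is the sum of directed shortest-path lengths from ``v`` to every
    *reachable* vertex; a vertex that reaches no others scores 0.
    """
    A = _as_adjacency(graph)
    _check_vertex(A, v)
    n = A.shape[0]
    dist = shortest_path(csr_matrix(A), method="D", directed=True,
                         unweighted=True, indices=v)
    dist[v] = np.inf  # exclude self
    reachable = np.isfinite(dist)
    if not reachable.any():
        return 0.0
    farness = float(dist[reachable].sum())
    return n / farness


def betweenness_centrality(graph, v: int | None = None):
    """Betweenness C_B(v) = sum over ordered pairs s != v != t of the fraction
    of shortest s->t paths through v, normalized by (n-1)(n-2).

    With ``v=None`` returns the vector for all vertices.
    """
    A = _as_adjacency(graph)
    n = A.shape[0]
    if n < 3:
        raise ValueError("betweenness requires at least 3 vertices")
    g = ig.Graph.Adjacency(A.tolist(), mode="directed")
    raw = np.asarray(g.betweenness(directed=True), dtype=float)
    bc = raw / ((n - 1) * (n - 2))
    if v is None:
        return bc
    _check_vertex(A, v)
    return float(bc[v])


def _check_vertex(A: np.ndarray, v: int) -> None:
    if not 0 <= v < A.shape[0]:
        raise ValueError(f"vertex {v} not in graph of size {A.shape[0]}")


@dataclass
class TopologyReport:
    """Global metrics at the start/end of a deletion sequence plus, for every
    deleted vertex, its local metrics on the graph it was deleted from."""

    n_initial: int
    n_final: int
    kcore_initial: int
    kcore_final: int
    scc_initial: int
    scc_final: int
    mean_in_degree_initial: float
    mean_in_degree_final: float
    mean_out_degree_initial: float
    mean_out_degree_final: float
    deletions: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.deletions)

    def globals_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_initial", "n_final", "kcore_initial", "kcore_final",
                "scc_initial", "scc_final",
                "mean_in_degree_initial", "mean_in_degree_final",
                "mean_out_degree_initial", "mean_out_degree_final",
            )
        }


def track_deletions(graph, order) -> TopologyReport:
    """Delete vertices in ``order`` (labels of the original graph), recording the
    local metrics of each on the pre-deletion graph and global metrics at the
    start and after the final deletion.

    Deletion removes the vertex together with all its in- and out-edges.
    """
    A0 = _as_adjacency(graph)
    order = [int(v) for v in order]
    if len(set(order)) != len(order):
        raise ValueError("deletion order contains a repeated vertex")
    for v in order:
        _check_vertex(A0, v)

    mi0, mo0 = mean_degrees(A0)
    report = TopologyReport(
        n_initial=A0.shape[0], n_final=A0.shape[0] - len(order),
        kcore_initial=kcore_number(A0), kcore_final=0,
        scc_initial=scc_count(A0), scc_final=0,
        mean_in_degree_initial=mi0, mean_in_degree_final=0.0,
        mean_out_degree_initial=mo0, mean_out_degree_final=0.0,
    )

    labels = list(range(A0.shape[0]))  # original label of each current row
    A = A0
    for v in order:
        idx = labels.index(v)
        n = A.shape[0]
        rec = {
            "vertex": v,
            "local_clustering": local_clustering(A, idx),
            "closeness_centrality": closeness_centrality(A, idx),
            "betweenness_centrality": (
                betweenness_centrality(A, idx) if n >= 3 else float("nan")
            ),
        }
        report.deletions.append(rec)
        keep = [i for i in range(n) if i != idx]
        A = A[np.ix_(keep, keep)]
        del labels[idx]

    if A.shape[0] > 0:
        report.kcore_final = kcore_number(A)
        report.scc_final = scc_count(A)
        mi, mo = mean_degrees(A)
        report.mean_in_degree_final = mi
        report.mean_out_degree_final = mo
    return report
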