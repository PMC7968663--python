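"""Degree, closeness, betweenness and eigenvector centrality.

All four measures are implemented directly from their defining formulas so
the direction conventions can be controlled explicitly -- in a directed
drug -> target graph the choice matters: closeness over incoming paths
ranks heavily-drugged targets first, betweenness on the directed graph can
only be nonzero at dual-role compounds (the only possible interior
vertices), and eigenvector centrality is run on the undirected view of a
connected component, where the power iteration is guaranteed to converge
to the Perron vector.

Senses:

``directed_out``
    follow edges drug -> target;
``directed_in``
    follow edges backwards (distances measured *into* a node);
``undirected``
    ignore direction.
"""

from __future__ import annotations

import enum
import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .graph_core import DrugTargetNetwork, extract_component, weak_components

logger = logging.getLogger(__name__)


class Sense(str, enum.Enum):
    DIRECTED_OUT = "directed_out"
    DIRECTED_IN = "directed_in"
    UNDIRECTED = "undirected"


@dataclass(frozen=True)
class CentralityScores:
    """One centrality metric's value per node, with its conventions recorded."""

    metric: str
    values: dict[str, float]
    normalization: str
    parameters: dict = field(default_factory=dict)


def _adjacency(net: DrugTargetNetwork, sense: Sense):
    sense = Sense(sense)
    if sense is Sense.DIRECTED_OUT:
        return {n: net.out_adj[n] for n in net.roles}
    if sense is Sense.DIRECTED_IN:
        return {n: net.in_adj[n] for n in net.roles}
    return {n: net.undirected_neighbors(n) for n in net.roles}


def degree_centrality(
    net: DrugTargetNetwork, direction: str = "total"
) -> CentralityScores:
    """Degree over n - 1, the maximum possible degree on n vertices."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    if direction == "in":
        deg = {v: len(net.in_adj[v]) for v in net.roles}
    elif direction == "out":
        deg = {v: len(net.out_adj[v]) for v in net.roles}
    elif direction == "total":
        deg = {v: len(net.undirected_neighbors(v)) for v in net.roles}
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return CentralityScores(
        metric=f"degree_{direction}",
        values={v: k / (n - 1) for v, k in deg.items()},
        normalization="k / (n - 1)",
        parameters={"direction": direction},
    )


def _bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


@dataclass(frozen=True)
class DistanceOracle:
    """All-pairs shortest-path lengths; unreachable pairs are absent."""

    d: dict[tuple[str, str], int]
    n: int
    sense: Sense


def all_pairs_distances(
    net: DrugTargetNetwork, sense: Sense | str = Sense.UNDIRECTED
) -> DistanceOracle:
    """BFS from every node in the stated sense.

    ``d[(u, v)]`` is the length of the shortest path from u to v along the
    sense adjacency.  Intended for small graphs and as an oracle; closeness
    and betweenness do not materialize it.
    """
    sense = Sense(sense)
    adj = _adjacency(net, sense)
    d: dict[tuple[str, str], int] = {}
    for u in net.roles:
        for v, dist in _bfs_distances(adj, u).items():
            d[(u, v)] = dist
    return DistanceOracle(d=d, n=net.n_nodes, sense=sense)


def closeness_centrality(
    net: DrugTargetNetwork, sense: Sense | str = Sense.DIRECTED_IN
) -> CentralityScores:
    """Component-scaled (Wasserman-Faust) closeness.

    For node v with nonempty reachable set R(v) in the chosen sense,
    ``raw = |R(v)| / sum d`` and the reported value is
    ``raw * |R(v)| / (n - 1)``; on a disconnected graph this damps scores in
    small components instead of rewarding isolation.  Nodes with empty R(v)
    score 0.  The default ``directed_in`` sense measures distances *into*
    each node (how quickly the rest of the network reaches it).
    """
    sense = Sense(sense)
    if net.n_nodes < 2:
        raise ValueError("closeness centrality needs at least 2 nodes")
    # BFS from v over the reversed sense gives distances towards v
    bfs_sense = {
        Sense.DIRECTED_IN: Sense.DIRECTED_IN,
        Sense.DIRECTED_OUT: Sense.DIRECTED_OUT,
        Sense.UNDIRECTED: Sense.UNDIRECTED,
    }[sense]
    adj = _adjacency(net, bfs_sense)
    n = net.n_nodes
    values: dict[str, float] = {}
    for v in net.roles:
        dist = _bfs_distances(adj, v)
        reachable = len(dist) - 1
        if reachable == 0:
            values[v] = 0.0
            continue
        total = sum(dist.values())
        values[v] = (reachable / total) * (reachable / (n - 1))
    return CentralityScores(
        metric="closeness",
        values=values,
        normalization="(|R|/sum d) * (|R|/(n-1)), Wasserman-Faust scaling",
        parameters={"sense": sense.value},
    )


def betweenness_centrality(
    net: DrugTargetNetwork, sense: Sense | str = Sense.DIRECTED_OUT
) -> CentralityScores:
    """Exact betweenness by Brandes-style single-source accumulation.

    C(v) = sum over ordered pairs s != t != v of sigma(s,t|v)/sigma(s,t),
    endpoints excluded, normalized by (n-1)(n-2) in the directed senses and
    (n-1)(n-2)/2 undirected (so values lie in [0, 1]).
    """
    sense = Sense(sense)
    n = net.n_nodes
    if n < 3:
        raise ValueError("betweenness centrality needs at least 3 nodes")
    adj = _adjacency(net, sense)
    nodes = net.nodes
    score = dict.fromkeys(nodes, 0.0)

    for s in nodes:
        # single-source shortest paths with path counting
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    pred[w].append(u)
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for u in pred[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                score[w] += delta[w]

    if sense is Sense.UNDIRECTED:
        # each unordered pair visited from both endpoints
        scale = 1.0 / ((n - 1) * (n - 2))
    else:
        scale = 1.0 / ((n - 1) * (n - 2))
    values = {v: score[v] * scale for v in nodes}
    return CentralityScores(
        metric="betweenness",
        values=values,
        normalization=(
            "sum sigma(s,t|v)/sigma(s,t) / ((n-1)(n-2)); undirected pairs "
            "counted from both endpoints, i.e. 2/((n-1)(n-2)) per unordered pair"
        ),
        parameters={"sense": sense.value},
    )


class PowerIterationError(RuntimeError):
    """Raised when the eigenvector power iteration fails to converge."""

    def __init__(self, message: str, state: dict):
        super().__init__(message)
        self.state = state


def eigenvector_centrality(
    net: DrugTargetNetwork,
    tol: float = 1e-10,
    max_iter: int = 1_000_000,
    component: int | None = 0,
) -> CentralityScores:
    """Eigenvector centrality by power iteration on the undirected adjacency.

    The iteration x(t+1) = B x(t) / ||B x(t)|| starts from the uniform
    positive vector and runs on one connected component (default: the giant
    component, index 0); on a connected non-bipartite-or-aperiodic view it
    converges to the Perron eigenvector.  Convergence is declared when the
    max-norm change drops below ``tol``.  Nodes outside the chosen component
    score 0.  The returned vector has unit Euclidean norm.
    """
    if component is not None:
        decomposition = weak_components(net)
        sub = extract_component(net, component, decomposition)
    else:
        sub = net
    nodes = sub.nodes
    if sub.n_edges == 0:
        raise ValueError("eigenvector centrality needs at least one edge")
    index = {v: i for i, v in enumerate(nodes)}
    m = len(nodes)
    b = np.zeros((m, m))
    for u, v in sub.edges():
        b[index[u], index[v]] = 1.0
        b[index[v], index[u]] = 1.0

    # iterate on B + I: same Perron eigenvector, but the dominant eigenvalue
    # lambda + 1 is strictly largest in magnitude even on bipartite
    # components, where iteration on B alone oscillates between the +/-lambda
    # eigenvector pair and never settles
    x = np.full(m, 1.0 / np.sqrt(m))
    lam = 0.0
    for iteration in range(1, max_iter + 1):
        y = b @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise PowerIterationError(
                "power iteration collapsed to the zero vector",
                {"iteration": iteration, "x": x},
            )
        y /= norm
        lam = norm - 1.0
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        raise PowerIterationError(
            f"no convergence within {max_iter} iterations",
            {"iteration": max_iter, "x": x, "lambda": lam},
        )

    values = dict.fromkeys(net.roles, 0.0)
    for v, i in index.items():
        values[v] = float(x[i])
    return CentralityScores(
        metric="eigenvector",
        values=values,
        normalization="unit Euclidean norm on the chosen component",
        parameters={
            "tol": tol,
            "max_iter": max_iter,
            "component": component,
            "lambda": float(lam),
            "iterations": iteration,
        },
    )


def top_k(scores: CentralityScores, k: int) -> list[tuple[str, float]]:
    """Deterministic top-k ranking: descending value, ties broken by node id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(scores.values.items(), key=lambda kv: (-kv[1], kv[0]))
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds the number of scored nodes ({len(ranked)}); "
            "returning the full ranking",
            stacklevel=2,
        )
    return ranked[:k]
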