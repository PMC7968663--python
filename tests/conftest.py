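"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random
from itertools import combinations

import pytest

from dtnet.graph_core import DrugTargetNetwork, build_network
from dtnet.io_formats import InteractionRecord, InteractionTable


def table_from_pairs(pairs) -> InteractionTable:
    """Interaction table from (drug, target) name pairs (ids = names)."""
    return InteractionTable(
        [InteractionRecord(u, u, v, v) for u, v in pairs]
    )


def net_from_pairs(pairs, merge: bool = True) -> DrugTargetNetwork:
    """Directed network from (source, destination) name pairs."""
    return build_network(table_from_pairs(pairs), merge_dual_roles=merge)


def clique_edges(names):
    return [(a, b) for a, b in combinations(names, 2)]


def random_directed_pairs(rng: random.Random, n_nodes: int, n_edges: int):
    """Random simple directed edges over string-named nodes (no self-loops)."""
    names = [f"n{i}" for i in range(n_nodes)]
    pairs = set()
    attempts = 0
    while len(pairs) < n_edges and attempts < 50 * n_edges:
        u, v = rng.sample(names, 2)
        pairs.add((u, v))
        attempts += 1
    return sorted(pairs)


def random_bipartite_pairs(rng: random.Random, n_drugs: int, n_targets: int,
                           n_edges: int):
    drugs = [f"d{i}" for i in range(n_drugs)]
    targets = [f"t{i}" for i in range(n_targets)]
    pairs = set()
    attempts = 0
    while len(pairs) < n_edges and attempts < 50 * n_edges:
        pairs.add((rng.choice(drugs), rng.choice(targets)))
        attempts += 1
    return sorted(pairs)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def floyd_warshall(net: DrugTargetNetwork, adjacency) -> dict:
    """O(n^3) all-pairs shortest paths (hop counts) over a dict adjacency."""
    nodes = net.nodes
    inf = float("inf")
    dist = {(u, v): (0 if u == v else inf) for u in nodes for v in nodes}
    for u in nodes:
        for v in adjacency[u]:
            dist[(u, v)] = min(dist[(u, v)], 1)
    for k in nodes:
        for i in nodes:
            dik = dist[(i, k)]
            if dik == inf:
                continue
            for j in nodes:
                alt = dik + dist[(k, j)]
                if alt < dist[(i, j)]:
                    dist[(i, j)] = alt
    return {k: v for k, v in dist.items() if v != inf}


def enumerate_shortest_paths(adjacency, source, dest, dist_from_source):
    """All shortest source->dest paths by layered DFS (exponential oracle)."""
    if dest not in dist_from_source:
        return []
    paths = []

    def walk(node, acc):
        if node == dest:
            paths.append(acc[:])
            return
        for nxt in sorted(adjacency[node]):
            if dist_from_source.get(nxt) == dist_from_source[node] + 1 and (
                dist_from_source.get(dest, float("inf"))
                >= dist_from_source[nxt]
            ):
                acc.append(nxt)
                walk(nxt, acc)
                acc.pop()

    walk(source, [source])
    return [p for p in paths if len(p) - 1 == dist_from_source[dest]]


def brute_force_betweenness(net: DrugTargetNetwork, adjacency) -> dict:
    """Unnormalized betweenness by explicit enumeration of all shortest paths."""
    from collections import deque

    nodes = net.nodes
    score = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for t in nodes:
            if t == s or t not in dist:
                continue
            paths = enumerate_shortest_paths(adjacency, s, t, dist)
            if not paths:
                continue
            sigma = len(paths)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                score[v] += through / sigma
    return score


def set_partitions(items):
    """All set partitions of ``items`` as node -> label dicts."""
    items = list(items)
    if not items:
        yield {}
        return
    first, rest = items[0], items[1:]
    for sub in set_partitions(rest):
        labels = sorted(set(sub.values()))
        for label in labels:
            d = dict(sub)
            d[first] = label
            yield d
        d = dict(sub)
        d[first] = (labels[-1] + 1) if labels else 0
        yield d


@pytest.fixture
def toy_coregulation_net():
    return net_from_pairs(
        [("D1", "T1"), ("D2", "T1"), ("D2", "T2"), ("D3", "T2")]
    )
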