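"""Newman-Girvan modularity and seeded multilevel (Louvain) community detection.

Modularity compares the intra-community edge fraction with the expectation
under a degree-preserving random null:

    Q = sum_c [ e_c / m  -  resolution * (d_c / 2m)^2 ]

with e_c the number of intra-community edges, d_c the total degree of
community c and m the edge count, all on the undirected unweighted view.
Q = 0 means the split is no better than random; values near 1 indicate
strong community structure.

The multilevel optimizer starts from singleton communities, repeatedly moves
each node to the neighboring community with the highest positive modularity
gain, then aggregates communities into super-nodes and repeats until Q can
no longer increase.  Node visit order is a seeded random permutation, so a
(graph, resolution, seed) triple is fully reproducible; gain ties break to
the smallest community label.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .graph_core import DrugTargetNetwork


@dataclass(frozen=True)
class Partition:
    """A node -> community assignment with its modularity."""

    assignment: dict[str, int]
    q: float
    resolution: float
    seed: int
    n_communities: int
    levels_q: tuple[float, ...] = ()

    def sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for label in self.assignment.values():
            counts[label] = counts.get(label, 0) + 1
        return sorted(counts.values(), reverse=True)


@dataclass(frozen=True)
class CommunitySizeStats:
    sizes: tuple[int, ...]
    largest: int
    frac_over_100: float
    frac_size_2: float


def _undirected_edges(net: DrugTargetNetwork) -> list[tuple[str, str]]:
    """Distinct undirected edges (self-loops excluded, reciprocal pairs merged)."""
    seen: set[tuple[str, str]] = set()
    for u, v in net.edges():
        if u == v:
            continue
        seen.add((u, v) if u <= v else (v, u))
    return sorted(seen)


def modularity(
    net: DrugTargetNetwork,
    assignment: dict[str, int],
    resolution: float = 1.0,
) -> float:
    """Modularity Q of a full assignment on the undirected unweighted view."""
    missing = [n for n in net.roles if n not in assignment]
    if missing:
        raise ValueError(
            f"assignment misses {len(missing)} nodes, e.g. {missing[:3]}"
        )
    edges = _undirected_edges(net)
    m = len(edges)
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    degree: dict[str, int] = dict.fromkeys(net.roles, 0)
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    e_c: dict[int, int] = {}
    d_c: dict[int, int] = {}
    for u, v in edges:
        if assignment[u] == assignment[v]:
            e_c[assignment[u]] = e_c.get(assignment[u], 0) + 1
    for node, k in degree.items():
        c = assignment[node]
        d_c[c] = d_c.get(c, 0) + k
    q = 0.0
    for c, d in d_c.items():
        q += e_c.get(c, 0) / m - resolution * (d / (2.0 * m)) ** 2
    return q


def louvain(
    net: DrugTargetNetwork,
    resolution: float = 1.0,
    seed: int = 0,
) -> Partition:
    """Seeded multilevel modularity optimization.

    Isolated nodes form singleton communities.  Raises if the graph has no
    edges at all.
    """
    edges = _undirected_edges(net)
    if not edges:
        raise ValueError("multilevel optimization needs at least one edge")
    rng = random.Random(seed)

    # level-0 graph: integer nodes, weighted adjacency (weights start at 1)
    nodes = net.nodes
    index = {v: i for i, v in enumerate(nodes)}
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    for u, v in edges:
        iu, iv = index[u], index[v]
        adj[iu][iv] = adj[iu].get(iv, 0.0) + 1.0
        adj[iv][iu] = adj[iv].get(iu, 0.0) + 1.0
    self_loops = [0.0] * len(nodes)  # aggregated intra-community weight
    m2 = 2.0 * len(edges)  # sum of all degrees, invariant across levels

    membership = list(range(len(nodes)))  # original node -> current label
    levels_q: list[float] = []

    while True:
        n = len(adj)
        comm = list(range(n))
        k = [sum(adj[i].values()) + self_loops[i] for i in range(n)]
        sigma_tot = k[:]  # total degree per community

        improved = False
        moved = True
        while moved:
            moved = False
            order = list(range(n))
            rng.shuffle(order)
            for i in order:
                ci = comm[i]
                # weights from i to each neighboring community
                links: dict[int, float] = {}
                for j, w in adj[i].items():
                    links[comm[j]] = links.get(comm[j], 0.0) + w
                sigma_tot[ci] -= k[i]
                comm[i] = -1
                # gain of joining community c (constant terms dropped):
                #   links[c] - resolution * sigma_tot[c] * k_i / (2m)
                best_c = ci
                best_gain = links.get(ci, 0.0) - resolution * sigma_tot[
                    ci
                ] * k[i] / m2
                for c in sorted(links):
                    if c == ci:
                        continue
                    gain = links[c] - resolution * sigma_tot[c] * k[i] / m2
                    if gain > best_gain + 1e-12 or (
                        abs(gain - best_gain) <= 1e-12 and c < best_c
                    ):
                        best_c, best_gain = c, gain
                comm[i] = best_c
                sigma_tot[best_c] += k[i]
                if best_c != ci:
                    moved = True
                    improved = True

        # relabel communities compactly, deterministically by smallest member
        labels = sorted(set(comm))
        relabel = {c: i for i, c in enumerate(labels)}
        comm = [relabel[c] for c in comm]
        membership = [comm[membership[v]] for v in range(len(membership))]

        assignment = {nodes[v]: membership[v] for v in range(len(nodes))}
        levels_q.append(modularity(net, assignment, resolution))

        if not improved:
            break

        # aggregate: communities become super-nodes
        n_new = len(labels)
        new_adj: list[dict[int, float]] = [dict() for _ in range(n_new)]
        new_self = [0.0] * n_new
        for i in range(n):
            ci = comm[i]
            new_self[ci] += self_loops[i]
            for j, w in adj[i].items():
                cj = comm[j]
                if ci == cj:
                    new_self[ci] += w  # counted twice over (i,j),(j,i)
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
        adj = new_adj
        self_loops = new_self

    assignment = {nodes[v]: membership[v] for v in range(len(nodes))}
    q = levels_q[-1]
    return Partition(
        assignment=assignment,
        q=q,
        resolution=resolution,
        seed=seed,
        n_communities=len(set(assignment.values())),
        levels_q=tuple(levels_q),
    )


def size_stats(partition: Partition) -> CommunitySizeStats:
    """Community-size summary: largest size, fraction > 100 nodes, fraction of pairs."""
    sizes = tuple(partition.sizes())
    n = len(sizes)
    return CommunitySizeStats(
        sizes=sizes,
        largest=sizes[0] if sizes else 0,
        frac_over_100=sum(1 for s in sizes if s > 100) / n if n else 0.0,
        frac_size_2=sum(1 for s in sizes if s == 2) / n if n else 0.0,
    )
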