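"""Directed drug-target graph: construction, roles, bipartiteness, components.

Drugs point at the macromolecules they act on, so the graph G = (V, E) is
directed with every edge running drug -> target.  A compound can appear on
both sides (e.g. nitric oxide is a drug of guanylate cyclase and a target of
albumin); such *dual-role* nodes are what break bipartiteness in real
drug-target networks.  Connectivity is analysed on the undirected view
(weak connectivity) -- under strong connectivity nearly every node would be
its own component.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .io_formats import InteractionTable, canonical

DRUG = "drug"
TARGET = "target"


@dataclass
class DrugTargetNetwork:
    """Directed graph with per-node role sets.

    Node keys are canonicalized display names; ``display`` maps each key back
    to the first-seen original spelling.  ``out_adj``/``in_adj`` are kept
    mutually consistent: ``u in out_adj[v]`` iff ``v in in_adj[u]``.
    """

    roles: dict[str, set[str]] = field(default_factory=dict)
    out_adj: dict[str, set[str]] = field(default_factory=dict)
    in_adj: dict[str, set[str]] = field(default_factory=dict)
    display: dict[str, str] = field(default_factory=dict)

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.roles)

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.out_adj.values())

    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (u, v) for u, succ in self.out_adj.items() for v in succ
        )

    def drug_nodes(self) -> list[str]:
        return sorted(n for n, r in self.roles.items() if DRUG in r)

    def target_nodes(self) -> list[str]:
        return sorted(n for n, r in self.roles.items() if TARGET in r)

    def dual_role_nodes(self) -> list[str]:
        return sorted(n for n, r in self.roles.items() if r == {DRUG, TARGET})

    def undirected_neighbors(self, node: str) -> set[str]:
        return self.out_adj[node] | self.in_adj[node]

    def add_node(self, key: str, role: str, display: str | None = None) -> None:
        self.roles.setdefault(key, set()).add(role)
        self.out_adj.setdefault(key, set())
        self.in_adj.setdefault(key, set())
        self.display.setdefault(key, display if display is not None else key)

    def add_edge(self, u: str, v: str) -> None:
        self.out_adj[u].add(v)
        self.in_adj[v].add(u)

    def to_networkx(self):
        """Export as a networkx DiGraph (node attribute ``roles``)."""
        import networkx as nx

        g = nx.DiGraph()
        for node, roles in self.roles.items():
            g.add_node(node, roles=frozenset(roles), display=self.display[node])
        g.add_edges_from(self.edges())
        return g


@dataclass(frozen=True)
class BipartitenessReport:
    """Role-based and graph-theoretic bipartiteness of a network.

    ``role_disjoint`` is the operative criterion for drug-target networks:
    false as soon as any entity acts as both a drug and a target.
    ``two_colorable`` is the classical 2-coloring test on the undirected
    view; when it fails, ``witness_odd_cycle`` holds an explicit odd cycle.
    """

    role_disjoint: bool
    dual_role_nodes: tuple[str, ...]
    two_colorable: bool
    witness_odd_cycle: tuple[str, ...] | None

    def __post_init__(self) -> None:
        assert self.role_disjoint == (not self.dual_role_nodes)
        assert (self.witness_odd_cycle is not None) == (not self.two_colorable)


@dataclass(frozen=True)
class ComponentDecomposition:
    """Weakly connected components, indexed by descending size.

    Ties in size are broken by the smallest member id so indexing is
    deterministic.  ``giant_index`` points at component 0 by construction
    but is kept explicit for clarity.
    """

    component_of: dict[str, int]
    sizes: tuple[int, ...]
    giant_index: int
    size_histogram: dict[int, int]


def build_network(
    table: InteractionTable, merge_dual_roles: bool = True
) -> DrugTargetNetwork:
    """Build the directed drug -> target graph from an interaction table.

    When ``merge_dual_roles`` (default), a drug and a target whose
    canonicalized names match collapse into a single node carrying both
    roles.  With merging off, same-named drug and target entries stay
    distinct nodes (keys suffixed ``|drug`` / ``|target``).
    """
    table = table.canonicalize()
    net = DrugTargetNetwork()

    def node_key(name: str, role: str) -> str:
        key = canonical(name)
        if not merge_dual_roles:
            key = f"{key}|{role}"
        return key

    for rec in table.records:
        u = node_key(rec.drug_name, DRUG)
        v = node_key(rec.target_name, TARGET)
        net.add_node(u, DRUG, rec.drug_name.strip())
        net.add_node(v, TARGET, rec.target_name.strip())
        net.add_edge(u, v)
    return net


def check_bipartite(net: DrugTargetNetwork) -> BipartitenessReport:
    """Report role-disjointness and 2-colorability of the undirected view."""
    dual = tuple(net.dual_role_nodes())
    color: dict[str, int] = {}
    witness: tuple[str, ...] | None = None

    for start in net.nodes:
        if start in color or witness is not None:
            continue
        color[start] = 0
        parent: dict[str, str | None] = {start: None}
        queue = deque([start])
        while queue and witness is None:
            u = queue.popleft()
            for v in sorted(net.undirected_neighbors(u)):
                if v == u:
                    witness = (u,)  # self-loop: odd cycle of length 1
                    break
                if v not in color:
                    color[v] = 1 - color[u]
                    parent[v] = u
                    queue.append(v)
                elif color[v] == color[u]:
                    witness = _odd_cycle(u, v, parent)
                    break
    return BipartitenessReport(
        role_disjoint=not dual,
        dual_role_nodes=dual,
        two_colorable=witness is None,
        witness_odd_cycle=witness,
    )


def _odd_cycle(
    u: str, v: str, parent: dict[str, str | None]
) -> tuple[str, ...]:
    """Reconstruct the odd cycle closed by the conflict edge (u, v)."""
    ancestors_u: list[str] = []
    node: str | None = u
    while node is not None:
        ancestors_u.append(node)
        node = parent[node]
    u_set = {n: i for i, n in enumerate(ancestors_u)}
    path_v: list[str] = []
    node = v
    while node not in u_set:
        path_v.append(node)
        node = parent[node]  # type: ignore[index]
    meet = node
    cycle = ancestors_u[: u_set[meet] + 1] + list(reversed(path_v))
    assert len(cycle) % 2 == 1
    return tuple(cycle)


def weak_components(net: DrugTargetNetwork) -> ComponentDecomposition:
    """Decompose into weakly connected components via BFS on the undirected view."""
    seen: set[str] = set()
    raw: list[list[str]] = []
    for start in net.nodes:
        if start in seen:
            continue
        members = [start]
        seen.add(start)
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in net.undirected_neighbors(u):
                if v not in seen:
                    seen.add(v)
                    members.append(v)
                    queue.append(v)
        raw.append(members)

    raw.sort(key=lambda m: (-len(m), min(m)))
    component_of = {
        node: idx for idx, members in enumerate(raw) for node in members
    }
    sizes = tuple(len(m) for m in raw)
    histogram: dict[int, int] = {}
    for s in sizes:
        histogram[s] = histogram.get(s, 0) + 1
    return ComponentDecomposition(
        component_of=component_of,
        sizes=sizes,
        giant_index=0 if sizes else -1,
        size_histogram=histogram,
    )


def extract_component(
    net: DrugTargetNetwork,
    index: int,
    decomposition: ComponentDecomposition | None = None,
) -> DrugTargetNetwork:
    """Induced subgraph of one weakly connected component, roles preserved."""
    decomposition = decomposition or weak_components(net)
    if not 0 <= index < len(decomposition.sizes):
        raise IndexError(
            f"component index {index} out of range "
            f"(0..{len(decomposition.sizes) - 1})"
        )
    members = {
        n for n, c in decomposition.component_of.items() if c == index
    }
    sub = DrugTargetNetwork()
    for node in members:
        for role in net.roles[node]:
            sub.add_node(node, role, net.display[node])
    for u in members:
        for v in net.out_adj[u]:
            if v in members:
                sub.add_edge(u, v)
    return sub
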