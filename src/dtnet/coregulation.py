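"""Drug coregulation projection and the randomized minimal covering-drug-set.

Two drugs are *coregulated* when they are in-neighbors of at least one
common target; the projection of the bipartite-like drug -> target graph
onto its drug side therefore links every unordered pair of drugs sharing a
target, weighted by the number of shared targets.

The covering-set reduction asks for a small subset of drugs that still
reaches every target.  Starting from all drug-role nodes, it repeatedly
draws one drug at random and discards it if every target keeps at least one
retained in-neighbor, otherwise keeps it; after the random phase an
optional deterministic sweep tries each survivor once (in seeded random
order), which guarantees the result is minimal: no single retained drug can
be removed without uncovering some target.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations

from .graph_core import DrugTargetNetwork


@dataclass(frozen=True)
class CoregulationGraph:
    """Undirected weighted drug-drug graph; weight = number of shared targets."""

    nodes: tuple[str, ...]
    weights: dict[tuple[str, str], int]  # keys sorted pairs, weight >= 1
    partner_count: dict[str, int]


@dataclass(frozen=True)
class DominatingSetResult:
    """Outcome of the randomized covering-drug-set reduction."""

    retained: frozenset[str]
    removed: frozenset[str]
    iterations: int
    seed: int
    coverage_check: bool
    sweep_applied: bool


def drug_projection(net: DrugTargetNetwork) -> CoregulationGraph:
    """Project onto drugs: +1 edge weight per target shared by a drug pair."""
    drugs = tuple(net.drug_nodes())
    weights: dict[tuple[str, str], int] = {}
    for target in net.target_nodes():
        in_drugs = sorted(net.in_adj[target])
        for a, b in combinations(in_drugs, 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1
    partner_count = dict.fromkeys(drugs, 0)
    for a, b in weights:
        partner_count[a] += 1
        partner_count[b] += 1
    return CoregulationGraph(
        nodes=drugs, weights=weights, partner_count=partner_count
    )


def top_coregulated(
    graph: CoregulationGraph, k: int
) -> list[tuple[str, int]]:
    """Top-k drugs by number of distinct coregulation partners (ties: node id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        graph.partner_count.items(), key=lambda kv: (-kv[1], kv[0])
    )
    return ranked[:k]


def coverage(
    net: DrugTargetNetwork, drug_subset: set[str] | frozenset[str]
) -> tuple[bool, list[str]]:
    """Check that every target keeps >= 1 in-neighbor inside ``drug_subset``.

    Returns ``(covered, uncovered_targets)``; only targets that have at
    least one drug in-neighbor in the full network are required to be
    covered (a node with no in-edges has nothing to lose).
    """
    uncovered = [
        t
        for t in net.target_nodes()
        if net.in_adj[t] and not (net.in_adj[t] & drug_subset)
    ]
    return (not uncovered, uncovered)


def dominating_set_reduction(
    net: DrugTargetNetwork,
    iterations: int = 100_000,
    seed: int = 0,
    minimality_sweep: bool = True,
) -> DominatingSetResult:
    """Randomized reduction to a minimal covering drug set.

    S starts as all drug-role nodes.  For ``iterations`` draws, a drug d is
    sampled uniformly from S and removed iff every target still has an
    in-neighbor in S \\ {d}; a failed draw leaves S unchanged and consumes
    one iteration.  With ``minimality_sweep`` (default) each survivor is
    afterwards tried once in seeded random order, making the result
    provably minimal.

    Raises
    ------
    ValueError
        If some target with in-edges has no drug-role in-neighbor (it could
        never be covered).
    """
    rng = random.Random(seed)
    drugs = net.drug_nodes()
    if not drugs:
        raise ValueError("network has no drug-role nodes")
    targets = [t for t in net.target_nodes() if net.in_adj[t]]

    # cover_count[t] = number of retained drugs pointing at t
    retained = set(drugs)
    cover_count = {t: len(net.in_adj[t] & retained) for t in targets}
    if any(c == 0 for c in cover_count.values()):
        bad = sorted(t for t, c in cover_count.items() if c == 0)
        raise ValueError(f"targets without drug in-neighbors: {bad[:5]}")

    def removable(d: str) -> bool:
        return all(
            cover_count[t] >= 2 for t in net.out_adj[d] if t in cover_count
        )

    # pool mirrors `retained` as a list for uniform draws with O(1) removal
    pool = sorted(retained)
    position = {d: i for i, d in enumerate(pool)}

    def remove(d: str) -> None:
        retained.discard(d)
        for t in net.out_adj[d]:
            if t in cover_count:
                cover_count[t] -= 1
        i = position.pop(d)
        last = pool.pop()
        if last != d:
            pool[i] = last
            position[last] = i

    for _ in range(iterations):
        if not pool:
            break
        d = pool[rng.randrange(len(pool))]
        if removable(d):
            remove(d)

    if minimality_sweep:
        order = sorted(retained)
        rng.shuffle(order)
        for d in order:
            if removable(d):
                remove(d)

    covered, _ = coverage(net, retained)
    return DominatingSetResult(
        retained=frozenset(retained),
        removed=frozenset(set(drugs) - retained),
        iterations=iterations,
        seed=seed,
        coverage_check=covered,
        sweep_applied=minimality_sweep,
    )
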