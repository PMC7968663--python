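"""Degree statistics, power-law fitting and clustering coefficients.

Drug-target networks are scale-free-like: most drugs hit one or two targets
while a handful of promiscuous hubs (kinase inhibitors, metal cofactors)
touch hundreds.  The empirical degree distribution P(k) is summarised by a
power law P(k) = A k^-gamma, fitted either by least squares on the log-log
empirical distribution (the field's historical default, and the package
default) or by discrete maximum likelihood as a cross-check.

The clustering coefficient C_i = 2 E_i / (k_i (k_i - 1)) is computed on the
undirected view; a strictly bipartite drug-target graph has no triangles,
so any nonzero clustering is a signature of dual-role merging.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .graph_core import DrugTargetNetwork


class Which(str, enum.Enum):
    IN = "in"
    OUT = "out"
    TOTAL = "total"


def degrees(net: DrugTargetNetwork) -> pd.DataFrame:
    """Per-node in/out/total degree table (index: node id, sorted)."""
    nodes = net.nodes
    return pd.DataFrame(
        {
            "k_in": [len(net.in_adj[n]) for n in nodes],
            "k_out": [len(net.out_adj[n]) for n in nodes],
            "k_total": [
                len(net.in_adj[n]) + len(net.out_adj[n]) for n in nodes
            ],
        },
        index=pd.Index(nodes, name="node"),
    )


def mean_degree(net: DrugTargetNetwork) -> float:
    """Average number of neighbors per node, 2|E| / |V|."""
    if net.n_nodes == 0:
        raise ValueError("mean degree undefined on an empty graph")
    return 2.0 * net.n_edges / net.n_nodes


@dataclass(frozen=True)
class DegreeDistribution:
    """Empirical P(k) over nodes with k >= 1.

    ``n_observed`` is the number of contributing nodes (needed to recover
    counts for likelihood fitting); ``n_zero`` records how many nodes were
    excluded for having degree zero.
    """

    support: np.ndarray
    probability: np.ndarray
    which: Which
    n_observed: int
    n_zero: int

    def __post_init__(self) -> None:
        assert np.all(self.support >= 1)
        assert np.all((self.probability > 0) & (self.probability <= 1))
        assert math.isclose(float(self.probability.sum()), 1.0, rel_tol=1e-9)


def empirical_distribution(
    deg: pd.DataFrame,
    which: Which | str = Which.TOTAL,
    nodes: set[str] | None = None,
) -> DegreeDistribution:
    """Empirical degree distribution P(k) = #nodes with degree k / #nodes with k >= 1.

    ``nodes`` optionally restricts the normalization to a subset (e.g. only
    drug-role nodes for the out-degree distribution).
    """
    which = Which(which)
    column = {Which.IN: "k_in", Which.OUT: "k_out", Which.TOTAL: "k_total"}[
        which
    ]
    values = deg[column]
    if nodes is not None:
        values = values.loc[values.index.isin(nodes)]
    n_zero = int((values == 0).sum())
    positive = values[values > 0]
    if positive.empty:
        raise ValueError("no node has positive degree; distribution undefined")
    counts = positive.value_counts().sort_index()
    support = counts.index.to_numpy(dtype=np.int64)
    probability = counts.to_numpy(dtype=float) / len(positive)
    return DegreeDistribution(
        support=support,
        probability=probability,
        which=which,
        n_observed=int(len(positive)),
        n_zero=n_zero,
    )


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted P(k) = A k^-gamma."""

    gamma: float
    A: float
    method: str
    k_min: int
    r_squared: float | None = None

    def __post_init__(self) -> None:
        assert self.gamma > 0 and self.A > 0 and self.k_min >= 1


def fit_power_law(
    dist: DegreeDistribution,
    method: str = "loglog_ls",
    k_min: int = 1,
    k_max: int | None = None,
) -> PowerLawFit:
    """Fit a power-law exponent to an empirical degree distribution.

    ``loglog_ls`` regresses log P(k) on log k over support >= k_min by
    ordinary least squares; A is chosen so the fitted curve matches the
    empirical P at the smallest used degree.  ``mle`` maximizes the
    discrete power-law likelihood with Hurwitz-zeta normalization (or a
    finite sum when ``k_max`` is given); it serves as an independent
    cross-check on the least-squares exponent.
    """
    mask = dist.support >= k_min
    support = dist.support[mask].astype(float)
    prob = dist.probability[mask]
    if len(support) < 3:
        raise ValueError(
            f"need at least 3 distinct degrees >= k_min={k_min}, "
            f"got {len(support)}"
        )

    if method == "loglog_ls":
        x = np.log(support)
        y = np.log(prob)
        slope, intercept = np.polyfit(x, y, 1)
        gamma = -float(slope)
        # anchor A so the fitted P(k) passes through the first used point
        k0 = support[0]
        a = float(prob[0] * k0**gamma)
        fitted = intercept + slope * x
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return PowerLawFit(
            gamma=gamma, A=a, method="loglog_ls", k_min=k_min, r_squared=r2
        )

    if method == "mle":
        # recover per-degree counts from probabilities
        counts = prob * dist.n_observed
        n = counts.sum()
        sum_log_k = float((counts * np.log(support)).sum())

        if k_max is None:
            def neg_loglik(g: float) -> float:
                return n * math.log(special.zeta(g, k_min)) + g * sum_log_k
        else:
            ks = np.arange(k_min, k_max + 1, dtype=float)

            def neg_loglik(g: float) -> float:
                return n * math.log(np.sum(ks**-g)) + g * sum_log_k

        res = optimize.minimize_scalar(
            neg_loglik, bounds=(1.000001, 20.0), method="bounded",
            options={"xatol": 1e-8},
        )
        gamma = float(res.x)
        if k_max is None:
            a = 1.0 / float(special.zeta(gamma, k_min))
        else:
            a = 1.0 / float(
                np.sum(np.arange(k_min, k_max + 1, dtype=float) ** -gamma)
            )
        return PowerLawFit(gamma=gamma, A=a, method="mle", k_min=k_min)

    raise ValueError(f"unknown fit method {method!r}")


@dataclass(frozen=True)
class ClusteringProfile:
    """Per-node clustering coefficients plus the C(k) curve.

    ``per_node`` has columns ``C``, ``E_i`` (edges among neighbors) and
    ``k_i`` (undirected neighbor count).  ``c_of_k`` maps each total degree
    to the mean C over nodes of that degree (exact-degree bins).
    """

    per_node: pd.DataFrame
    mean_c: float
    c_of_k: dict[int, float]


def clustering(net: DrugTargetNetwork) -> ClusteringProfile:
    """Clustering coefficients C_i = 2 E_i / (k_i (k_i - 1)) on the undirected view."""
    nodes = net.nodes
    neighbor_sets = {
        n: net.undirected_neighbors(n) - {n} for n in nodes
    }
    rows = []
    for n in nodes:
        nb = neighbor_sets[n]
        k = len(nb)
        if k < 2:
            rows.append((0.0, 0, k))
            continue
        # each linked neighbor pair counted twice in the sum
        twice_e = sum(len(neighbor_sets[u] & nb) for u in nb)
        e_i = twice_e // 2
        rows.append((2.0 * e_i / (k * (k - 1)), e_i, k))
    per_node = pd.DataFrame(
        rows, columns=["C", "E_i", "k_i"], index=pd.Index(nodes, name="node")
    )
    mean_c = float(per_node["C"].mean()) if len(per_node) else 0.0
    c_of_k = {
        int(k): float(group["C"].mean())
        for k, group in per_node.groupby("k_i")
    }
    return ClusteringProfile(per_node=per_node, mean_c=mean_c, c_of_k=c_of_k)
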