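"""Entropy-based centrality for weighted directed and undirected networks.

The total influence of a node is split into a local part and an indirect
part.  The local part combines two Shannon entropies computed on the node's
ego subgraph (the induced subgraph on the node and all of its neighbors):

* **structural entropy** — the entropy of the subgraph-degree distribution
  over the ego subgraph's members, a proxy for the focal node's activity and
  popularity in its immediate neighborhood;
* **interaction frequency entropy** — the entropy of the node's out-edge
  weight distribution (incident weights in the undirected case), a proxy for
  how evenly its attention is spread across its ties.

The indirect part captures two-hop influence propagation: for each node p
reachable by a directed path of length exactly two (and not already a
one-hop out-neighbor), the influence transmitted to p is the mean of
``LI_i * LI_j`` over the common intermediates j, and the indirect influence
of i is the mean of these per-target terms over all two-hop targets.
Influence is assumed undetectable beyond two hops, so no deeper propagation
is modelled.

Total influence is the convex combination ``theta1 * local + theta2 *
indirect``; nodes are ranked by descending total influence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import pandas as pd

from .graph import Node, WeightedNetwork, all_neighbors, out_neighbors

__all__ = [
    "Coefficients",
    "EgoSubgraph",
    "build_ego_subgraph",
    "subgraph_degree_centrality",
    "structural_entropy",
    "frequency_entropy",
    "local_influence",
    "two_hop_neighbors",
    "indirect_influence_on",
    "indirect_influence",
    "total_influence",
    "CENTRALITY_COLUMNS",
]

#: Output schema of :func:`total_influence`.
CENTRALITY_COLUMNS = [
    "node",
    "structural_entropy",
    "frequency_entropy",
    "local_influence",
    "indirect_influence",
    "total_influence",
    "rank",
]


@dataclass(frozen=True)
class Coefficients:
    """Mixing weights and logarithm base of the centrality.

    ``omega1``/``omega2`` mix the structural and frequency entropies into
    the local influence; ``theta1``/``theta2`` mix local and indirect
    influence into the total.  Each pair must be nonnegative and sum to 1.
    The defaults (0.4/0.6 and 0.6/0.4, base-10 logarithms) are the
    published reference setting.
    """

    omega1: float = 0.4
    omega2: float = 0.6
    theta1: float = 0.6
    theta2: float = 0.4
    log_base: float = 10.0

    def __post_init__(self) -> None:
        for a, b, names in (
            (self.omega1, self.omega2, "omega1+omega2"),
            (self.theta1, self.theta2, "theta1+theta2"),
        ):
            if a < 0 or b < 0 or abs(a + b - 1.0) > 1e-9:
                raise ValueError(
                    f"{names} must be nonnegative and sum to 1, got {a} + {b}"
                )
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError(f"log_base must be positive and != 1, got {self.log_base}")


@dataclass(frozen=True)
class EgoSubgraph:
    """Induced subgraph on a focal node and all of its neighbors."""

    focal: Node
    members: frozenset
    g: nx.DiGraph  # induced directed subgraph (symmetric if source undirected)
    directed: bool

    @property
    def n_neighbors(self) -> int:
        """Number of neighbors of the focal node within the subgraph."""
        return len(self.members) - 1


def build_ego_subgraph(net: WeightedNetwork, i: Node) -> EgoSubgraph:
    """The induced subgraph on ``{i} ∪ neighbors(i)``.

    The edge set is *induced*: edges between two neighbors of ``i`` are
    included, not only edges incident to ``i``.  The neighbor set is the
    union of in- and out-neighbors.
    """
    if i not in net:
        raise KeyError(i)
    members = frozenset({i} | all_neighbors(net, i))
    sub = net.g.subgraph(members).copy()
    return EgoSubgraph(focal=i, members=members, g=sub, directed=net.directed)


def subgraph_degree_centrality(sub: EgoSubgraph, v: Node) -> int:
    """In-degree plus out-degree of ``v`` counted within the ego subgraph.

    For undirected networks this is the number of subgraph members adjacent
    to ``v`` (the symmetric storage would otherwise double-count each tie).
    """
    if v not in sub.members:
        raise KeyError(v)
    if sub.directed:
        return sub.g.in_degree(v) + sub.g.out_degree(v)
    return sub.g.out_degree(v)


def _entropy(weights: list[float], base: float) -> float:
    """Shannon entropy of the normalized weight vector; 0·log 0 := 0."""
    total = sum(weights)
    if total <= 0:
        return 0.0
    h = 0.0
    for w in weights:
        if w > 0:
            p = w / total
            h -= p * math.log(p, base)
    # guard against -0.0 and tiny negative round-off on one-point distributions
    return max(h, 0.0)


def structural_entropy(
    net: WeightedNetwork, i: Node, coeffs: Coefficients = Coefficients()
) -> float:
    """Entropy of the subgraph-degree distribution over i's ego subgraph.

    Returns 0 for degenerate cases (isolated node, edgeless subgraph).
    Bounded above by ``log_b(M + 1)`` where M is the neighbor count.
    """
    sub = build_ego_subgraph(net, i)
    sdc = [subgraph_degree_centrality(sub, v) for v in sub.members]
    return _entropy([float(c) for c in sdc], coeffs.log_base)


def frequency_entropy(
    net: WeightedNetwork, i: Node, coeffs: Coefficients = Coefficients()
) -> float:
    """Entropy of i's out-edge weight distribution.

    Directed networks use the out-edge weights (the interaction frequency in
    the given direction); undirected networks use the incident edge weights.
    Returns 0 when the node has no such edges.  Bounded above by
    ``log_b(M)`` for M edges.
    """
    if i not in net:
        raise KeyError(i)
    # symmetric storage makes successors == adjacent nodes when undirected
    weights = [net.g.edges[i, j]["weight"] for j in net.g.successors(i)]
    return _entropy(weights, coeffs.log_base)


def local_influence(
    net: WeightedNetwork, i: Node, coeffs: Coefficients = Coefficients()
) -> float:
    """Convex combination of the two ego-subgraph entropies."""
    return coeffs.omega1 * structural_entropy(net, i, coeffs) + coeffs.omega2 * (
        frequency_entropy(net, i, coeffs)
    )


def two_hop_neighbors(net: WeightedNetwork, i: Node) -> dict[Node, frozenset]:
    """Two-hop targets of ``i`` with their common intermediates.

    A two-hop target is a node ``p != i`` reachable by a directed path
    ``i -> j -> p`` (edge direction followed at both hops; plain adjacency
    when undirected) that is not itself a one-hop out-neighbor of ``i``.
    Returns ``{p: frozenset of intermediates j}``.
    """
    if i not in net:
        raise KeyError(i)
    first_hop = out_neighbors(net, i)
    targets: dict[Node, set[Node]] = {}
    for j in first_hop:
        for p in net.g.successors(j):
            if p != i and p not in first_hop:
                targets.setdefault(p, set()).add(j)
    return {p: frozenset(js) for p, js in targets.items()}


def indirect_influence_on(
    net: WeightedNetwork, i: Node, p: Node, li: Mapping[Node, float]
) -> float:
    """Influence of ``i`` on the single two-hop target ``p``.

    The mean of ``li[i] * li[j]`` over the common intermediates j on the
    length-two paths from i to p.
    """
    targets = two_hop_neighbors(net, i)
    if p not in targets:
        raise ValueError(f"{p!r} is not a two-hop neighbor of {i!r}")
    intermediates = targets[p]
    return sum(li[i] * li[j] for j in intermediates) / len(intermediates)


def indirect_influence(
    net: WeightedNetwork, i: Node, li: Mapping[Node, float]
) -> float:
    """Mean per-target two-hop influence of ``i``; 0 with no two-hop targets."""
    targets = two_hop_neighbors(net, i)
    if not targets:
        return 0.0
    total = 0.0
    for intermediates in targets.values():
        total += sum(li[i] * li[j] for j in intermediates) / len(intermediates)
    return total / len(targets)


def total_influence(
    net: WeightedNetwork, coeffs: Coefficients = Coefficients()
) -> pd.DataFrame:
    """Full centrality table for every node, ranked by total influence.

    Returns a DataFrame with columns ``node, structural_entropy,
    frequency_entropy, local_influence, indirect_influence, total_influence,
    rank``.  Ranks run 1..n by descending total influence; ties are broken
    by ascending node identifier (string order) and flagged in the
    ``tied`` column.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot rank an empty network")
    rows = []
    li: dict[Node, float] = {}
    for v in net.nodes:
        s = structural_entropy(net, v, coeffs)
        f = frequency_entropy(net, v, coeffs)
        li[v] = coeffs.omega1 * s + coeffs.omega2 * f
        rows.append({"node": v, "structural_entropy": s, "frequency_entropy": f,
                     "local_influence": li[v]})
    for row in rows:
        row["indirect_influence"] = indirect_influence(net, row["node"], li)
        row["total_influence"] = (
            coeffs.theta1 * row["local_influence"]
            + coeffs.theta2 * row["indirect_influence"]
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["total_influence", "node"],
        ascending=[False, True],
        key=lambda c: c.map(str) if c.name == "node" else c,
    ).reset_index(drop=True)
    table["rank"] = range(1, len(table) + 1)
    table["tied"] = table["total_influence"].duplicated(keep=False)
    return table[CENTRALITY_COLUMNS + ["tied"]]
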