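"""Comparison centralities: degree, betweenness, closeness, eigenvector.

Conventions are explicit because published evaluations rarely state them:

* degree — unweighted total (in+out) degree;
* betweenness — exact shortest-path betweenness on the directed graph with
  edge distances ``1/weight`` (strong ties are short);
* closeness — harmonic centrality on *outgoing* ``1/weight`` distances,
  normalized by ``n - 1`` (well-defined on weakly connected digraphs);
* eigenvector — principal eigenvector of the weighted adjacency (in-edge
  based), power iteration to 1e-8, L2-normalized.

Each can be switched to other common variants; the variant used is recorded
in the result metadata so rankings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph import WeightedNetwork

__all__ = [
    "BaselineScores",
    "degree_centrality",
    "betweenness_centrality",
    "closeness_centrality",
    "eigenvector_centrality",
    "BASELINE_METHODS",
    "EigenvectorConvergenceError",
]


class EigenvectorConvergenceError(RuntimeError):
    pass


@dataclass
class BaselineScores:
    """Per-node scores of one baseline method, with ranks and metadata."""

    method: str
    table: pd.DataFrame  # columns: node, score, rank
    metadata: dict = field(default_factory=dict)

    @property
    def scores(self) -> dict:
        return dict(zip(self.table["node"], self.table["score"]))


def _to_table(method: str, scores: dict, metadata: dict) -> BaselineScores:
    table = pd.DataFrame(
        {"node": list(scores.keys()), "score": list(scores.values())}
    ).sort_values(
        ["score", "node"],
        ascending=[False, True],
        key=lambda c: c.map(str) if c.name == "node" else c,
    ).reset_index(drop=True)
    table["rank"] = range(1, len(table) + 1)
    return BaselineScores(method=method, table=table, metadata=metadata)


def _distance_graph(net: WeightedNetwork) -> nx.DiGraph:
    """Copy of the graph with a 'distance' attribute = 1/weight per edge."""
    g = net.g.copy()
    for u, v, d in g.edges(data=True):
        d["distance"] = 1.0 / d["weight"]
    return g


def degree_centrality(net: WeightedNetwork, weighted: bool = False) -> BaselineScores:
    """Total (in+out) degree; edge count by default, weight sums if ``weighted``."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    w = "weight" if weighted else None
    scores = dict(net.g.degree(weight=w))
    if not net.directed:
        # symmetric storage double-counts each undirected tie
        scores = {v: d / 2 for v, d in scores.items()}
    return _to_table(
        "degree", scores, {"weighted": weighted, "convention": "total in+out degree"}
    )


def betweenness_centrality(net: WeightedNetwork, weighted: bool = True) -> BaselineScores:
    """Exact Brandes betweenness; distances 1/weight when ``weighted``."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if weighted:
        scores = nx.betweenness_centrality(
            _distance_graph(net), weight="distance", normalized=False
        )
    else:
        scores = nx.betweenness_centrality(net.g, normalized=False)
    if not net.directed:
        scores = {v: s / 2 for v, s in scores.items()}  # each pair counted twice
    return _to_table(
        "betweenness",
        scores,
        {"weighted": weighted, "distance": "1/weight", "normalized": False},
    )


def closeness_centrality(
    net: WeightedNetwork, weighted: bool = True, variant: str = "harmonic"
) -> BaselineScores:
    """Closeness on outgoing shortest-path distances (1/weight when weighted).

    ``variant='harmonic'`` (default) sums reciprocal distances and divides by
    n-1, handling unreachable pairs gracefully; ``variant='reachable'`` is
    the Wasserman–Faust reachable-component-scaled classic closeness.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = _distance_graph(net) if weighted else net.g
    dist = "distance" if weighted else None
    n = net.n_nodes
    if variant == "harmonic":
        # networkx harmonic_centrality sums incoming 1/d; reverse for outgoing
        raw = nx.harmonic_centrality(g.reverse(copy=False), distance=dist)
        scores = {v: s / (n - 1) if n > 1 else 0.0 for v, s in raw.items()}
    elif variant == "reachable":
        scores = nx.closeness_centrality(
            g.reverse(copy=False), distance=dist, wf_improved=True
        )
    else:
        raise ValueError(f"unknown closeness variant {variant!r}")
    return _to_table(
        "closeness",
        scores,
        {"weighted": weighted, "variant": variant, "direction": "outgoing",
         "distance": "1/weight" if weighted else "hops"},
    )


def eigenvector_centrality(
    net: WeightedNetwork,
    weighted: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> BaselineScores:
    """Principal-eigenvector scores of the (weighted) adjacency matrix.

    Power iteration on in-edge weighted sums: ``x_i ∝ Σ_j w_ji x_j``,
    L2-normalized each sweep, stopping when the L1 change per node falls
    below ``tol``.  The iteration matrix is shifted by the identity
    (same principal eigenvector), which guarantees convergence on
    bipartite and other periodic structures where the plain iteration
    oscillates.
    """
    if net.g.number_of_edges() == 0:
        raise ValueError("eigenvector centrality needs at least one edge")
    nodes = list(net.g.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, d in net.g.edges(data=True):
        w[idx[u], idx[v]] = d["weight"] if weighted else 1.0
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        x_new = x + w.T @ x  # in-edge accumulation, identity-shifted
        x_new = x_new / np.linalg.norm(x_new)
        if np.abs(x_new - x).sum() < n * tol:
            scores = {v: float(x_new[idx[v]]) for v in nodes}
            return _to_table(
                "eigenvector",
                scores,
                {"weighted": weighted, "tol": tol, "normalization": "L2",
                 "accumulation": "in-edges"},
            )
        x = x_new
    raise EigenvectorConvergenceError(
        f"power iteration did not converge within {max_iter} iterations"
    )


#: Registry used by the simulator's method comparison and the CLI.
BASELINE_METHODS = {
    "degree": degree_centrality,
    "betweenness": betweenness_centrality,
    "closeness": closeness_centrality,
    "eigenvector": eigenvector_centrality,
}
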