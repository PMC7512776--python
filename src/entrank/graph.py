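"""Weighted-network data model, validation and edge-list I/O.

The container is a thin wrapper around a :class:`networkx.DiGraph` holding
strictly positive edge weights (interaction frequencies: flight counts,
message counts, collaboration strengths).  Undirected networks are stored
symmetrically — both orientations carry the same weight — so that every
downstream algorithm can operate on a single directed representation while
the ``directed`` flag selects the undirected conventions where they differ.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Hashable, Union

import networkx as nx

logger = logging.getLogger(__name__)

Node = Hashable
EdgeRow = tuple[Node, Node, float]

__all__ = [
    "WeightedNetwork",
    "GraphInputError",
    "from_edge_list",
    "read_edge_list",
    "write_edge_list",
    "out_neighbors",
    "in_neighbors",
    "all_neighbors",
    "summarize",
]


class GraphInputError(ValueError):
    """Raised for malformed edge lists: bad weights, empty input."""


@dataclass
class WeightedNetwork:
    """A weighted network G(V, E, W) with positive edge weights.

    Parameters
    ----------
    g
        Backing directed graph.  For ``directed=False`` both orientations
        of every edge are stored with identical weight.
    directed
        Whether edge direction is meaningful.  Algorithms use this flag to
        pick directed or undirected conventions (degree counting, weight
        aggregation, traversal).
    """

    g: nx.DiGraph = field(default_factory=nx.DiGraph)
    directed: bool = True

    @property
    def nodes(self) -> list[Node]:
        return list(self.g.nodes)

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Number of edges: arcs if directed, unordered pairs otherwise."""
        m = self.g.number_of_edges()
        return m if self.directed else m // 2

    def weight(self, u: Node, v: Node) -> float:
        return self.g.edges[u, v]["weight"]

    def has_edge(self, u: Node, v: Node) -> bool:
        return self.g.has_edge(u, v)

    def __contains__(self, node: Node) -> bool:
        return node in self.g

    def edge_weights(self) -> dict[tuple[Node, Node], float]:
        return {(u, v): d["weight"] for u, v, d in self.g.edges(data=True)}

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.g.copy(), self.directed)

    def validate(self) -> None:
        """Check the container invariants; raise ``GraphInputError`` on failure."""
        for u, v, d in self.g.edges(data=True):
            w = d.get("weight")
            if w is None or not math.isfinite(w) or w <= 0:
                raise GraphInputError(f"edge {u!r}->{v!r} has invalid weight {w!r}")
            if u == v:
                raise GraphInputError(f"self-loop on {u!r}")
            if not self.directed and (
                not self.g.has_edge(v, u) or self.g.edges[v, u]["weight"] != w
            ):
                raise GraphInputError(
                    f"undirected network stores asymmetric edge {u!r}--{v!r}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return (
            self.directed == other.directed
            and set(self.g.nodes) == set(other.g.nodes)
            and self.edge_weights() == other.edge_weights()
        )


def from_edge_list(
    rows: Iterable[EdgeRow], directed: bool = True
) -> WeightedNetwork:
    """Build a network from (source, target, weight) rows.

    Duplicate (source, target) rows are aggregated by summing their weights
    (weights are interaction counts, so repeated records add up).  Self-loops
    are dropped with a warning.  For ``directed=False`` each row is stored in
    both orientations.

    Raises
    ------
    GraphInputError
        If a weight is non-positive, non-finite or non-numeric (the offending
        row is named), or if the input contains no rows.
    """
    g = nx.DiGraph()
    n_rows = 0
    for row_no, (u, v, w) in enumerate(rows, start=1):
        n_rows += 1
        try:
            w = float(w)
        except (TypeError, ValueError):
            raise GraphInputError(
                f"row {row_no} ({u!r}, {v!r}): weight {w!r} is not numeric"
            ) from None
        if not math.isfinite(w) or w <= 0:
            raise GraphInputError(
                f"row {row_no} ({u!r}, {v!r}): weight {w!r} must be a finite "
                "positive number"
            )
        if u == v:
            logger.warning("dropping self-loop on node %r (row %d)", u, row_no)
            g.add_node(u)
            continue
        pairs = [(u, v)] if directed else [(u, v), (v, u)]
        for s, t in pairs:
            if g.has_edge(s, t):
                g.edges[s, t]["weight"] += w
            else:
                g.add_edge(s, t, weight=w)
    if n_rows == 0:
        raise GraphInputError("empty edge list: no rows to parse")
    net = WeightedNetwork(g, directed)
    net.validate()
    return net


def _parse_lines(lines: Iterable[str]) -> Iterator[EdgeRow]:
    """Parse delimited lines into edge rows.

    Tab- or comma-separated, auto-detected per line; lines starting with
    '%' or '#' are comments (KONECT-style headers), blank lines ignored.
    Whitespace-separated fields are accepted as a fallback.
    """
    for line_no, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(("%", "#")):
            continue
        if "\t" in line:
            parts = [p.strip() for p in line.split("\t")]
        elif "," in line:
            parts = [p.strip() for p in line.split(",")]
        else:
            parts = line.split()
        if len(parts) < 3:
            raise GraphInputError(
                f"line {line_no}: expected 'source, target, weight', got {line!r}"
            )
        yield parts[0], parts[1], parts[2]  # type: ignore[misc]


def read_edge_list(
    source: Union[str, Path, IO[str]], directed: bool = True
) -> WeightedNetwork:
    """Read a delimited edge list (TSV/CSV, '%'/'#' comments) from a path or file."""
    if hasattr(source, "read"):
        return from_edge_list(_parse_lines(source), directed)  # type: ignore[arg-type]
    with open(source, encoding="utf-8") as fh:
        return from_edge_list(_parse_lines(fh), directed)


def write_edge_list(net: WeightedNetwork, destination: Union[str, Path, IO[str]]) -> None:
    """Write ``source<TAB>target<TAB>weight`` lines; undirected edges once each.

    Round-trips through :func:`read_edge_list` (with the same ``directed``
    flag) to an equal network.
    """
    if net.n_nodes == 0:
        raise GraphInputError("refusing to write an empty network")

    def fmt(w: float) -> str:
        return str(int(w)) if float(w).is_integer() else repr(w)

    seen: set[frozenset] = set()
    lines = []
    for u, v, d in sorted(net.g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        if not net.directed:
            key = frozenset((u, v))
            if key in seen:
                continue
            seen.add(key)
        lines.append(f"{u}\t{v}\t{fmt(d['weight'])}\n")
    if hasattr(destination, "write"):
        destination.writelines(lines)  # type: ignore[union-attr]
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.writelines(lines)


def out_neighbors(net: WeightedNetwork, i: Node) -> set[Node]:
    """Successors of ``i`` (all adjacent nodes when the network is undirected)."""
    if i not in net.g:
        raise KeyError(i)
    return set(net.g.successors(i))


def in_neighbors(net: WeightedNetwork, i: Node) -> set[Node]:
    if i not in net.g:
        raise KeyError(i)
    return set(net.g.predecessors(i))


def all_neighbors(net: WeightedNetwork, i: Node) -> set[Node]:
    """Union of in- and out-neighbors of ``i``, excluding ``i`` itself."""
    if i not in net.g:
        raise KeyError(i)
    nbrs = set(net.g.successors(i)) | set(net.g.predecessors(i))
    nbrs.discard(i)
    return nbrs


def summarize(net: WeightedNetwork) -> dict:
    """Basic statistics: node/edge counts, clustering, average degree.

    The global clustering coefficient (transitivity) is computed on the
    undirected, unweighted skeleton.  ``average_degree`` is the mean total
    (in+out) degree for directed networks and the usual 2m/n for undirected
    ones; the convention is recorded in the returned metadata.
    """
    if net.n_nodes == 0:
        raise GraphInputError("cannot summarize an empty network")
    skeleton = net.g.to_undirected()
    n = net.n_nodes
    m = net.n_edges
    if net.directed:
        avg_degree = sum(d for _, d in net.g.degree()) / n
        degree_convention = "mean total (in+out) degree = 2m/n over directed arcs"
    else:
        avg_degree = 2 * m / n
        degree_convention = "2m/n over undirected edges"
    return {
        "n_nodes": n,
        "n_edges": m,
        "directed": net.directed,
        "clustering_coefficient": nx.transitivity(skeleton),
        "average_degree": avg_degree,
        "conventions": {
            "clustering": "global transitivity on the undirected, unweighted skeleton",
            "average_degree": degree_convention,
        },
    }
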