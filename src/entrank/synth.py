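"""Built-in fixture network and synthetic random weighted networks.

``toy_network`` returns the 8-airport example network used throughout the
documentation: 26 directed routes whose weights count the flights on each
connection.  ``random_network`` generates G(n, p)-style weighted digraphs
with a tunable reciprocity (the toy network is fully reciprocal; real
directed networks are not, and non-reciprocal graphs are what distinguish
in- from out-neighbor conventions in tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import WeightedNetwork, from_edge_list

__all__ = ["TOY_EDGES", "toy_network", "SynthSpec", "random_network"]

#: The 8-airport example: (origin, destination, number of flights).
TOY_EDGES: list[tuple[str, str, int]] = [
    ("A", "B", 5), ("A", "D", 1), ("A", "F", 3),
    ("B", "A", 4), ("B", "C", 2), ("B", "D", 3), ("B", "E", 3),
    ("C", "B", 4), ("C", "E", 2), ("C", "H", 5),
    ("D", "A", 2), ("D", "B", 5), ("D", "E", 4),
    ("E", "B", 3), ("E", "C", 3), ("E", "D", 4), ("E", "F", 2), ("E", "G", 1),
    ("F", "A", 1), ("F", "G", 3), ("F", "E", 2),
    ("G", "E", 1), ("G", "F", 1), ("G", "H", 2),
    ("H", "C", 1), ("H", "G", 4),
]


def toy_network() -> WeightedNetwork:
    """The 8-node, 26-arc directed airline network fixture."""
    return from_edge_list(TOY_EDGES, directed=True)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the random-network generator.

    Exactly one of ``density`` (arc probability) or ``mean_out_degree``
    must be given.  ``reciprocity`` is the probability that a sampled arc
    is augmented with its reverse (a fresh weight is drawn for it).
    ``weight_dist`` is one of ``uniform-integer`` (integers 1..wmax),
    ``geometric`` (support 1, 2, ...) or ``lognormal``.
    """

    n: int = 100
    density: float | None = None
    mean_out_degree: float | None = None
    reciprocity: float = 0.0
    weight_dist: str = "uniform-integer"
    wmax: int = 5
    geom_p: float = 0.5
    lognorm_mu: float = 0.0
    lognorm_sigma: float = 1.0
    directed: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if (self.density is None) == (self.mean_out_degree is None):
            raise ValueError("give exactly one of density or mean_out_degree")
        if not 0.0 <= self.reciprocity <= 1.0:
            raise ValueError("reciprocity must be in [0, 1]")
        if self.weight_dist not in ("uniform-integer", "geometric", "lognormal"):
            raise ValueError(f"unknown weight_dist {self.weight_dist!r}")
        if self.density is not None and not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if self.mean_out_degree is not None and self.mean_out_degree <= 0:
            raise ValueError("mean_out_degree must be positive")


def _arc_probability(spec: SynthSpec) -> float:
    """Base arc probability hitting the requested density / mean out-degree.

    With reciprocity r, an arc i->j exists if sampled directly (prob p) or
    added as the reverse of a sampled j->i (prob (1-p)·p·r), so the
    effective per-arc probability is p(1 + r(1-p)); invert for p.
    """
    if spec.density is not None:
        target = spec.density
    else:
        target = spec.mean_out_degree / (spec.n - 1)
    if target > 1.0:
        raise ValueError("requested mean out-degree exceeds n - 1")
    r = spec.reciprocity
    if not spec.directed or r == 0.0:
        return target
    # solve r p^2 - (1+r) p + target = 0 for the root in (0, 1]
    disc = (1.0 + r) ** 2 - 4.0 * r * target
    return ((1.0 + r) - math.sqrt(disc)) / (2.0 * r)


def _draw_weights(spec: SynthSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    if spec.weight_dist == "uniform-integer":
        return rng.integers(1, spec.wmax + 1, size=size).astype(float)
    if spec.weight_dist == "geometric":
        return rng.geometric(spec.geom_p, size=size).astype(float)
    return rng.lognormal(spec.lognorm_mu, spec.lognorm_sigma, size=size)


def random_network(spec: SynthSpec) -> WeightedNetwork:
    """Sample a random weighted network; deterministic under ``rng_seed``.

    Directed graphs sample every ordered pair independently, then each
    sampled arc gains its reverse with probability ``reciprocity``.
    Undirected graphs sample unordered pairs.  If a draw produces no edges
    the generator resamples with a fresh substream (at most 100 attempts)
    so every returned network has at least one edge.
    """
    p = _arc_probability(spec)
    root = np.random.SeedSequence(spec.rng_seed)
    for attempt_seq in root.spawn(100):
        rng = np.random.default_rng(attempt_seq)
        rows: list[tuple[int, int, float]] = []
        if spec.directed:
            mask = rng.random((spec.n, spec.n)) < p
            np.fill_diagonal(mask, False)
            srcs, dsts = np.nonzero(mask)
            weights = _draw_weights(spec, rng, len(srcs))
            rows = list(zip(srcs.tolist(), dsts.tolist(), weights.tolist()))
            if spec.reciprocity > 0.0:
                add_rev = rng.random(len(srcs)) < spec.reciprocity
                have = set(zip(srcs.tolist(), dsts.tolist()))
                rev = [
                    (int(d), int(s))
                    for s, d, a in zip(srcs, dsts, add_rev)
                    if a and (int(d), int(s)) not in have
                ]
                rev_w = _draw_weights(spec, rng, len(rev))
                rows += [(s, d, w) for (s, d), w in zip(rev, rev_w.tolist())]
        else:
            iu, ju = np.triu_indices(spec.n, k=1)
            mask = rng.random(len(iu)) < p
            srcs, dsts = iu[mask], ju[mask]
            weights = _draw_weights(spec, rng, len(srcs))
            rows = list(zip(srcs.tolist(), dsts.tolist(), weights.tolist()))
        if rows:
            net = from_edge_list(rows, directed=spec.directed)
            # isolated nodes are legitimate; make sure all n are present
            net.g.add_nodes_from(range(spec.n))
            return net
    raise RuntimeError(
        "could not generate a non-empty network in 100 attempts; "
        "increase density or mean_out_degree"
    )
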