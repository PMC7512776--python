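"""Weighted susceptible–infectious (SI) spreading simulator.

Seed sets chosen by a centrality are scored by the mean number of infected
nodes over time: a better ranking seeds a faster, wider spread.  The process
is discrete-time and synchronous.  At every step each susceptible node is
challenged independently by each currently infected in-neighbor j across the
edge j→i, succeeding with a per-edge probability derived from the edge
weight; newly infected nodes become infectious at the next step and never
recover.

Two published weight-to-probability forms are supported:

* ``wang`` (default): ``1 - (1 - beta)**w`` — the edge bundles w independent
  unit-contacts, each transmitting with probability beta;
* ``yan``: ``(w / w_max)**alpha`` — contact probability scaled by the edge's
  weight relative to the network maximum.

The implementation accumulates log-survival probabilities through a sparse
matrix product, which is mathematically identical to drawing the individual
per-edge Bernoulli challenges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .baselines import BASELINE_METHODS, BaselineScores
from .entropy import Coefficients, total_influence
from .graph import Node, WeightedNetwork

__all__ = [
    "SIConfig",
    "SIResult",
    "infection_probability",
    "run_si",
    "top_k_seeds",
    "rank_nodes",
    "compare_methods",
]


@dataclass(frozen=True)
class SIConfig:
    """Parameters of the SI spreading experiment.

    beta — per-unit-weight transmission probability (wang form);
    alpha — exponent of the yan form (ignored by wang);
    model — 'wang' or 'yan';
    t_max — number of synchronous steps simulated;
    replicates — Monte-Carlo repetitions averaged (1000 in the reference
    evaluation protocol);
    rng_seed — seed fully determining the randomness.
    """

    beta: float = 0.1
    alpha: float = 1.0
    model: str = "wang"
    t_max: int = 30
    replicates: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("wang", "yan"):
            raise ValueError(f"unknown infection model {self.model!r}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.t_max < 1 or self.replicates < 1:
            raise ValueError("t_max and replicates must be >= 1")


@dataclass
class SIResult:
    """Mean infected-count trajectory and per-replicate outcomes."""

    mean_infected: np.ndarray  # shape (t_max + 1,), mean over replicates
    sd_infected: np.ndarray  # per-time-point standard deviation
    final_counts: np.ndarray  # shape (replicates,), infected at t_max
    counts: np.ndarray  # shape (replicates, t_max + 1)
    config: SIConfig
    seeds: frozenset = field(default_factory=frozenset)


def infection_probability(config: SIConfig, w: float, w_max: float) -> float:
    """Per-step probability that an infected neighbor transmits over weight-w edge."""
    if w <= 0:
        raise ValueError("edge weight must be positive")
    if config.model == "wang":
        return 1.0 - (1.0 - config.beta) ** w
    if w_max < w:
        raise ValueError("w_max must be >= w for the yan form")
    return (w / w_max) ** config.alpha


def _log_survival_matrix(net: WeightedNetwork, config: SIConfig) -> sparse.csr_array:
    """Sparse matrix L with L[j, i] = log(1 - p(j->i)); -inf encoded as a large negative."""
    nodes = list(net.g.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    weights = [d["weight"] for _, _, d in net.g.edges(data=True)]
    w_max = max(weights) if weights else 1.0
    rows, cols, vals = [], [], []
    for u, v, d in net.g.edges(data=True):
        p = infection_probability(config, d["weight"], w_max)
        with np.errstate(divide="ignore"):
            logq = np.log1p(-p)  # -inf when p == 1
        # a certain infection: use a sentinel the exp of which underflows to 0
        rows.append(idx[u])
        cols.append(idx[v])
        vals.append(logq if np.isfinite(logq) else -1e30)
    n = len(nodes)
    return sparse.csr_array((vals, (rows, cols)), shape=(n, n))


def run_si(net: WeightedNetwork, seeds: Iterable[Node], config: SIConfig) -> SIResult:
    """Simulate the SI process from the given seed set.

    Transmission follows edge direction: an infected node j challenges a
    susceptible node i only through the edge j→i.  Undirected networks store
    both orientations, so infection travels both ways with the tie's weight.
    Identical configs (including ``rng_seed``) give bit-identical results.
    """
    seed_set = frozenset(seeds)
    if not seed_set:
        raise ValueError("seed set must be non-empty")
    nodes = list(net.g.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    for s in seed_set:
        if s not in idx:
            raise KeyError(s)
    n = len(nodes)
    logq = _log_survival_matrix(net, config)

    seed_vec = np.zeros(n, dtype=bool)
    seed_vec[[idx[s] for s in seed_set]] = True

    children = np.random.SeedSequence(config.rng_seed).spawn(config.replicates)
    counts = np.empty((config.replicates, config.t_max + 1), dtype=np.int64)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        infected = seed_vec.copy()
        counts[r, 0] = int(infected.sum())
        for t in range(1, config.t_max + 1):
            if infected.all():
                counts[r, t] = n
                continue
            log_surv = infected.astype(float) @ logq  # total log-survival per node
            p_infect = -np.expm1(np.minimum(log_surv, 0.0))
            p_infect[infected] = 0.0
            newly = rng.random(n) < p_infect
            infected |= newly
            counts[r, t] = int(infected.sum())
    return SIResult(
        mean_infected=counts.mean(axis=0),
        sd_infected=counts.std(axis=0, ddof=0),
        final_counts=counts[:, -1].copy(),
        counts=counts,
        config=config,
        seeds=seed_set,
    )


def rank_nodes(
    net: WeightedNetwork, method: str, coeffs: Coefficients = Coefficients()
) -> pd.DataFrame:
    """Rank table (columns node, rank) for an entropy or baseline method."""
    if method == "entropy":
        return total_influence(net, coeffs)[["node", "rank"]]
    if method in BASELINE_METHODS:
        scores: BaselineScores = BASELINE_METHODS[method](net)
        return scores.table[["node", "rank"]]
    raise ValueError(
        f"unknown method {method!r}; expected 'entropy' or one of "
        f"{sorted(BASELINE_METHODS)}"
    )


def top_k_seeds(scores, k: int) -> set[Node]:
    """The k best-ranked nodes of a centrality table.

    Accepts a :func:`entropy.total_influence` DataFrame, a
    :class:`BaselineScores`, or any DataFrame with ``node`` and ``rank``
    columns.  Deterministic under each method's tie-breaking.
    """
    table = scores.table if isinstance(scores, BaselineScores) else scores
    n = len(table)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be between 1 and the node count {n}")
    return set(table.nsmallest(k, "rank")["node"])


def compare_methods(
    net: WeightedNetwork,
    methods: Sequence[str],
    k_values: Sequence[int],
    config: SIConfig,
    coeffs: Coefficients = Coefficients(),
) -> pd.DataFrame:
    """Mean influence spread of each method × seed-set size.

    Every (method, k) cell runs :func:`run_si` with the same ``rng_seed``,
    so all methods face identical random substreams and the comparison is
    reproducible.  Returns a tidy long-format table with columns
    ``method, k, t, mean_infected, sd``.
    """
    n = net.n_nodes
    for k in k_values:
        if k > n:
            raise ValueError(f"k={k} exceeds the node count {n}")
    rankings = {m: rank_nodes(net, m, coeffs) for m in methods}
    frames = []
    for m in methods:
        for k in k_values:
            seeds = top_k_seeds(rankings[m], k)
            res = run_si(net, seeds, config)
            frames.append(
                pd.DataFrame(
                    {
                        "method": m,
                        "k": k,
                        "t": np.arange(config.t_max + 1),
                        "mean_infected": res.mean_infected,
                        "sd": res.sd_infected,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
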