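"""Independent brute-force reference implementations used only by tests.

Everything here works on a plain ``{(source, target): weight}`` dict and
literally enumerates subgraph members, degree sums, length-two directed
paths and shortest paths, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math


def out_nbrs(edges: dict, i) -> set:
    return {t for (s, t) in edges if s == i}


def in_nbrs(edges: dict, i) -> set:
    return {s for (s, t) in edges if t == i}


def neighbors(edges: dict, i) -> set:
    return (out_nbrs(edges, i) | in_nbrs(edges, i)) - {i}


def ego_members(edges: dict, i) -> set:
    return {i} | neighbors(edges, i)


def induced_edges(edges: dict, members: set) -> dict:
    return {(s, t): w for (s, t), w in edges.items() if s in members and t in members}


def sdc(edges: dict, members: set, v, directed: bool = True) -> int:
    ind = induced_edges(edges, members)
    if directed:
        return sum(1 for (s, t) in ind if t == v) + sum(1 for (s, t) in ind if s == v)
    return sum(1 for (s, t) in ind if s == v)  # symmetric storage: one per tie


def entropy(values, base: float = 10.0) -> float:
    total = sum(values)
    if total <= 0:
        return 0.0
    return -sum((v / total) * math.log(v / total, base) for v in values if v > 0)


def structural_entropy(edges: dict, i, base: float = 10.0, directed: bool = True) -> float:
    members = ego_members(edges, i)
    return entropy([sdc(edges, members, v, directed) for v in members], base)


def frequency_entropy(edges: dict, i, base: float = 10.0) -> float:
    return entropy([w for (s, t), w in edges.items() if s == i], base)


def local_influence(edges: dict, i, omega1=0.4, omega2=0.6, base=10.0,
                    directed: bool = True) -> float:
    return omega1 * structural_entropy(edges, i, base, directed) + (
        omega2 * frequency_entropy(edges, i, base)
    )


def two_hop(edges: dict, i) -> dict:
    """{target: set of intermediates} via directed length-2 paths."""
    one_hop = out_nbrs(edges, i)
    targets: dict = {}
    for j in one_hop:
        for p in out_nbrs(edges, j):
            if p != i and p not in one_hop:
                targets.setdefault(p, set()).add(j)
    return targets


def indirect_influence(edges: dict, i, li: dict) -> float:
    targets = two_hop(edges, i)
    if not targets:
        return 0.0
    per_target = [
        sum(li[i] * li[j] for j in js) / len(js) for js in targets.values()
    ]
    return sum(per_target) / len(targets)


def total_influence(edges: dict, nodes, omega1=0.4, omega2=0.6, theta1=0.6,
                    theta2=0.4, base=10.0, directed: bool = True) -> dict:
    li = {v: local_influence(edges, v, omega1, omega2, base, directed) for v in nodes}
    return {
        v: theta1 * li[v] + theta2 * indirect_influence(edges, v, li) for v in nodes
    }


# ---------------------------------------------------------------- baselines


def _dijkstra(edges: dict, nodes, source) -> dict:
    """Shortest directed distances with edge length 1/weight; no heap, O(n^2)."""
    dist = {v: math.inf for v in nodes}
    dist[source] = 0.0
    unvisited = set(nodes)
    while unvisited:
        u = min(unvisited, key=lambda v: dist[v])
        if dist[u] == math.inf:
            break
        unvisited.remove(u)
        for (s, t), w in edges.items():
            if s == u and t in unvisited:
                nd = dist[u] + 1.0 / w
                if nd < dist[t] - 1e-15:
                    dist[t] = nd
    return dist


def harmonic_closeness(edges: dict, nodes) -> dict:
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = _dijkstra(edges, nodes, v)
        out[v] = sum(
            1.0 / d for u, d in dist.items() if u != v and math.isfinite(d) and d > 0
        ) / (n - 1) if n > 1 else 0.0
    return out


def betweenness(edges: dict, nodes) -> dict:
    """Exact betweenness by enumerating all simple paths (tiny graphs only)."""
    score = {v: 0.0 for v in nodes}
    nodes = list(nodes)
    for s, t in itertools.permutations(nodes, 2):
        # enumerate all simple s->t paths with DFS
        best = math.inf
        paths: list[tuple[float, tuple]] = []

        def dfs(u, d, path):
            nonlocal best
            if u == t:
                paths.append((d, tuple(path)))
                best = min(best, d)
                return
            for (a, b), w in edges.items():
                if a == u and b not in path:
                    dfs(b, d + 1.0 / w, path + [b])

        dfs(s, 0.0, [s])
        if not paths:
            continue
        shortest = [p for d, p in paths if abs(d - best) < 1e-12]
        for v in nodes:
            if v == s or v == t:
                continue
            through = sum(1 for p in shortest if v in p)
            score[v] += through / len(shortest)
    return score


def si_exact_mean(edges: dict, nodes, seeds: frozenset, p_edge: dict, t_max: int):
    """Exact mean infected-count curve by full Markov-chain enumeration.

    ``p_edge[(j, i)]`` is the per-step transmission probability.  State space
    is the set of infected sets reachable from ``seeds``; feasible only for
    a handful of nodes.
    """
    nodes = list(nodes)
    dist = {frozenset(seeds): 1.0}
    means = [sum(len(s) * p for s, p in dist.items())]
    for _ in range(t_max):
        new_dist: dict = {}
        for infected, prob in dist.items():
            susceptible = [v for v in nodes if v not in infected]
            p_inf = {}
            for v in susceptible:
                surv = 1.0
                for j in infected:
                    if (j, v) in p_edge:
                        surv *= 1.0 - p_edge[(j, v)]
                p_inf[v] = 1.0 - surv
            for bits in itertools.product([False, True], repeat=len(susceptible)):
                p_branch = prob
                newly = set()
                for v, got in zip(susceptible, bits):
                    p_branch *= p_inf[v] if got else (1.0 - p_inf[v])
                    if got:
                        newly.add(v)
                if p_branch > 0:
                    key = infected | frozenset(newly)
                    new_dist[key] = new_dist.get(key, 0.0) + p_branch
        dist = new_dist
        means.append(sum(len(s) * p for s, p in dist.items()))
    return means
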