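"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles (exact
rational arithmetic, exhaustive enumeration, naive rescans) without
touching the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx


def hypergeom_upper_tail_exact(k: int, ks: int, N: int, s0: int) -> Fraction:
    """P(X >= ks), X ~ Hypergeometric(N, s0, k), by the exact sum."""
    if ks == 0:
        return Fraction(1)
    num = sum(
        math.comb(s0, i) * math.comb(N - s0, k - i)
        for i in range(ks, min(k, s0) + 1)
    )
    return Fraction(num, math.comb(N, k))


def hypergeom_upper_tail_enumerated(k: int, ks: int, N: int, s0: int) -> Fraction:
    """Same tail by literally enumerating all C(N, k) draws."""
    population = list(range(N))
    successes = set(range(s0))
    favourable = sum(
        1
        for draw in itertools.combinations(population, k)
        if sum(1 for x in draw if x in successes) >= ks
    )
    return Fraction(favourable, math.comb(N, k))


def brute_force_diamond(graph: nx.Graph, seeds, n_iterations: int) -> list[str]:
    """Re-rank the whole network from scratch each round with exact p."""
    module = {s for s in seeds if graph.has_node(s)}
    N = graph.number_of_nodes()
    order = []
    for _ in range(n_iterations):
        s0 = len(module)
        best = None
        for node in sorted(set(graph) - module):
            k = graph.degree(node)
            ks = sum(1 for v in graph.neighbors(node) if v in module)
            p = hypergeom_upper_tail_exact(k, ks, N, s0)
            key = (p, -ks, k, node)
            if best is None or key < best:
                best = key
        order.append(best[3])
        module.add(best[3])
    return order


def enumerate_short_paths(graph: nx.MultiDiGraph, source: str, targets, max_edges: int):
    """All simple directed paths of <= max_edges edges, as
    (nodes, edge signs) pairs, keeping only minimal length per endpoint."""
    targets = set(targets)
    found: dict[str, list[tuple[tuple[str, ...], tuple[int, ...]]]] = {}

    stack = [((source,), ())]
    while stack:
        nodes, signs = stack.pop()
        head = nodes[-1]
        if head in targets and signs:
            found.setdefault(head, []).append((nodes, signs))
        if len(signs) < max_edges:
            for _, nxt, data in graph.out_edges(head, data=True):
                if nxt not in nodes:
                    stack.append((nodes + (nxt,), signs + (data["sign"],)))
    out = {}
    for endpoint, paths in found.items():
        min_len = min(len(s) for _, s in paths)
        out[endpoint] = sorted(p for p in paths if len(p[1]) == min_len)
    return out


def spearman_exact(xs, ys) -> float:
    """Tie-corrected Spearman correlation via Pearson on midranks."""

    def midranks(vals):
        order = sorted(range(len(vals)), key=lambda i: vals[i])
        ranks = [0.0] * len(vals)
        i = 0
        while i < len(vals):
            j = i
            while j + 1 < len(vals) and vals[order[j + 1]] == vals[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(xs)), midranks(list(ys))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    vy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return cov / (vx * vy)
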