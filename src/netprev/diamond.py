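"""Disease-module growth by iterative hypergeometric connectivity.

Disease proteins rarely form dense cliques in an interactome, but they do
sit close together: candidate disease proteins are those whose links into
the known disease neighbourhood are more numerous than chance predicts.
At each iteration the significance of every outside protein's connections
to the current module is scored with an upper-tail hypergeometric test,
and the most significant protein is pulled in.  The iteration index at
which a protein enters is its rank; lower ranks mark stronger candidates.

The module also implements the analyses used to choose and defend a
module-size threshold: saturation curves over reference gene sets,
windowed saturation detection, k-fold seed-recovery cross-validation, and
rank-correlation robustness between reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import networkx as nx
from scipy import stats


@dataclass(frozen=True)
class RankedCandidate:
    """A protein pulled into the growing module."""

    protein: str
    rank: int
    p_value: float
    degree_k: int
    links_to_module_ks: int


@dataclass
class DiamondResult:
    seeds_used: frozenset[str]
    candidates: list[RankedCandidate]
    network_size_N: int

    def ranks(self) -> dict[str, int]:
        return {c.protein: c.rank for c in self.candidates}

    def proteins(self, top_n: int | None = None) -> list[str]:
        cands = self.candidates if top_n is None else self.candidates[:top_n]
        return [c.protein for c in cands]


@dataclass
class SaturationCurve:
    """Cumulative fraction of a reference gene set recovered per iteration."""

    values: np.ndarray
    reference_set_size: int


@dataclass
class RobustnessReport:
    overlap_count: int
    spearman_rho: float | None


def connectivity_pvalue(degree_k: int, links_ks: int, N: int, module_size_s0: int) -> float:
    """Upper-tail hypergeometric probability of a node's module links.

    For a node of degree ``k`` with ``ks`` links into an ``s0``-member
    module in an ``N``-node network: P(X >= ks) with
    X ~ Hypergeometric(population N, successes s0, draws k).
    """
    if not (0 <= links_ks <= degree_k <= N - 1):
        raise ValueError(f"require 0 <= ks <= k <= N-1, got ks={links_ks} k={degree_k} N={N}")
    if not (0 < module_size_s0 < N):
        raise ValueError(f"require 0 < s0 < N, got s0={module_size_s0} N={N}")
    if links_ks == 0:
        return 1.0
    return float(stats.hypergeom.sf(links_ks - 1, N, module_size_s0, degree_k))


def run_diamond(
    graph: nx.Graph,
    seeds: Iterable[str],
    n_iterations: int,
    seed_weight_alpha: int = 1,
) -> DiamondResult:
    """Grow the disease module one protein per iteration.

    At every iteration the hypergeometric connectivity p-value of each
    outside node is computed against the *current* module (seeds plus
    previously accepted candidates) and the minimum-p node is appended.
    Ties at equal p break toward larger ``ks``, then smaller ``k``, then
    the lexicographically smallest identifier, making the ranking fully
    deterministic and independent of node insertion order.

    ``seed_weight_alpha`` > 1 counts each seed link as alpha links and
    enlarges the effective population accordingly (the original
    algorithm's seed weighting); the default alpha = 1 uses plain counts.
    """
    seeds = set(seeds)
    in_network = {s for s in seeds if graph.has_node(s)}
    if not in_network:
        raise ValueError("no seed is present in the network")
    N = graph.number_of_nodes()
    max_iter = N - len(in_network)
    if n_iterations > max_iter:
        raise ValueError(f"n_iterations={n_iterations} exceeds N - |seeds| = {max_iter}")
    alpha = int(seed_weight_alpha)
    # Effective population grows when seed links are over-counted.
    N_eff = N + (alpha - 1) * len(in_network)

    module = set(in_network)
    degree = dict(graph.degree())
    # Weighted degree: seed neighbours count alpha times.
    k_eff = {
        n: degree[n] + (alpha - 1) * sum(1 for v in graph.neighbors(n) if v in in_network)
        for n in graph.nodes()
    }
    # ks tracked incrementally: number of (weighted) links into the module.
    ks = {n: 0 for n in graph.nodes()}
    for s in in_network:
        for v in graph.neighbors(s):
            ks[v] += alpha
    outside = sorted(n for n in graph.nodes() if n not in module)

    candidates: list[RankedCandidate] = []
    for it in range(1, n_iterations + 1):
        s0 = len(in_network) * alpha + (len(module) - len(in_network))
        nodes = [n for n in outside if ks[n] > 0]
        if nodes:
            ks_arr = np.array([ks[n] for n in nodes])
            k_arr = np.array([k_eff[n] for n in nodes])
            p_arr = stats.hypergeom.sf(ks_arr - 1, N_eff, s0, k_arr)
            # p rounded to 12 decimals for comparison only, so float noise in
            # the tail sum cannot break an exact tie (e.g. 0.4999999999999999
            # vs 0.5); genuine ties then fall through to the ks/k/name rule.
            p_key = np.round(p_arr, 12)
            order = sorted(
                range(len(nodes)),
                key=lambda i: (p_key[i], -ks_arr[i], k_arr[i], nodes[i]),
            )
            best_i = order[0]
            best, p = nodes[best_i], float(p_arr[best_i])
        else:
            # No outside node touches the module: everything ties at p = 1,
            # so the ks/k/name tie-break alone decides.
            best, p = min(outside, key=lambda n: (k_eff[n], n)), 1.0
        candidates.append(
            RankedCandidate(
                protein=best,
                rank=it,
                p_value=min(p, 1.0),
                degree_k=degree[best],
                links_to_module_ks=sum(1 for v in graph.neighbors(best) if v in module),
            )
        )
        module.add(best)
        outside.remove(best)
        for v in graph.neighbors(best):
            ks[v] += 1
    return DiamondResult(
        seeds_used=frozenset(in_network), candidates=candidates, network_size_N=N
    )


def saturation_curve(result: DiamondResult, reference_genes: Iterable[str]) -> SaturationCurve:
    """Cumulative fraction of ``reference_genes`` recovered at each rank."""
    reference = set(reference_genes)
    if not reference:
        raise ValueError("reference gene set is empty")
    hits = np.fromiter(
        (c.protein in reference for c in result.candidates), dtype=float
    )
    return SaturationCurve(
        values=np.cumsum(hits) / len(reference), reference_set_size=len(reference)
    )


def detect_saturation(curve: SaturationCurve | np.ndarray, window_w: int = 50, epsilon: float = 0.005) -> int:
    """Smallest iteration t after which the curve gains <= epsilon over the
    next ``window_w`` iterations; the curve length if never saturated."""
    values = curve.values if isinstance(curve, SaturationCurve) else np.asarray(curve, dtype=float)
    if window_w < 1:
        raise ValueError("window_w must be >= 1")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    n = len(values)
    for t in range(1, n + 1):
        upper = min(t + window_w, n)
        if upper <= t:
            return t
        gain = values[upper - 1] - values[t - 1]
        if gain <= epsilon:
            return t
    return n


def crossvalidate_recovery(
    graph: nx.Graph,
    seeds: Iterable[str],
    n_folds: int,
    n_iterations: int,
    rng_seed: int,
) -> np.ndarray:
    """Mean held-out seed recovery curve under k-fold cross-validation.

    The in-network seeds are partitioned into ``n_folds`` shuffled folds;
    each fold is held out in turn, the module is regrown from the retained
    seeds, and the recovery curve of the held-out seeds is recorded.  The
    returned curve is the fold mean, reproducible for a fixed ``rng_seed``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    in_net, _ = _seed_partition(graph, seeds)
    if len(in_net) < n_folds:
        raise ValueError(f"{len(in_net)} in-network seeds cannot fill {n_folds} folds")
    rng = np.random.default_rng(rng_seed)
    order = sorted(in_net)
    rng.shuffle(order)
    folds = [order[i::n_folds] for i in range(n_folds)]
    curves = []
    for fold in folds:
        held_out = set(fold)
        retained = [s for s in order if s not in held_out]
        result = run_diamond(graph, retained, n_iterations)
        curves.append(saturation_curve(result, held_out).values)
    return np.mean(curves, axis=0)


def _seed_partition(graph: nx.Graph, seeds: Iterable[str]) -> tuple[list[str], list[str]]:
    seeds = set(seeds)
    present = sorted(s for s in seeds if graph.has_node(s))
    absent = sorted(seeds - set(present))
    return present, absent


def robustness_rank_correlation(
    result_a: DiamondResult, result_b: DiamondResult, top_n: int
) -> RobustnessReport:
    """Overlap and Spearman rank correlation between two module rankings.

    Compares the top ``top_n`` candidates of each run: the overlap count
    and the tie-corrected Spearman correlation of ranks on the overlap.
    With fewer than two shared proteins the correlation is undefined and
    reported as None.
    """
    if top_n > len(result_a.candidates) or top_n > len(result_b.candidates):
        raise ValueError("top_n exceeds a candidate list length")
    ranks_a = {c.protein: c.rank for c in result_a.candidates[:top_n]}
    ranks_b = {c.protein: c.rank for c in result_b.candidates[:top_n]}
    shared = sorted(set(ranks_a) & set(ranks_b))
    if len(shared) < 2:
        return RobustnessReport(overlap_count=len(shared), spearman_rho=None)
    ra = [ranks_a[p] for p in shared]
    rb = [ranks_b[p] for p in shared]
    rho = float(stats.spearmanr(ra, rb).statistic)
    return RobustnessReport(overlap_count=len(shared), spearman_rho=rho)
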