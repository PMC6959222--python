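"""Module growth: hypergeometric p-values, ranking, saturation, robustness."""

import random

import networkx as nx
import numpy as np
import pytest

from _oracles import (
    brute_force_diamond,
    hypergeom_upper_tail_enumerated,
    spearman_exact,
)
from netprev.diamond import (
    SaturationCurve,
    connectivity_pvalue,
    crossvalidate_recovery,
    detect_saturation,
    robustness_rank_correlation,
    run_diamond,
    saturation_curve,
)


class TestConnectivityPvalue:
    @pytest.mark.parametrize(
        "k,ks,N,s0,expected",
        [
            (3, 0, 10, 4, 1.0),          # P(X >= 0) is certain
            (3, 2, 10, 4, 1 / 3),        # 40 of the 120 draws have >= 2 hits
            (1, 1, 5, 2, 0.4),           # 2 of 5 single draws hit the module
        ],
    )
    def test_known_values(self, k, ks, N, s0, expected):
        assert connectivity_pvalue(k, ks, N, s0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "k,ks,N,s0",
        [(3, 4, 10, 4), (10, 0, 10, 4), (-1, 0, 10, 4), (3, 0, 10, 0), (3, 0, 10, 10)],
    )
    def test_bound_violations_rejected(self, k, ks, N, s0):
        with pytest.raises(ValueError):
            connectivity_pvalue(k, ks, N, s0)

    def test_matches_literal_enumeration_of_draws(self):
        for N, s0, k, ks in [(10, 4, 3, 2), (8, 3, 4, 1), (9, 5, 2, 2), (7, 2, 5, 2)]:
            expected = float(hypergeom_upper_tail_enumerated(k, ks, N, s0))
            assert connectivity_pvalue(k, ks, N, s0) == pytest.approx(expected, abs=1e-12)


class TestRunDiamond:
    def test_hand_enumerated_growth_order(self, toy_graph):
        result = run_diamond(toy_graph, {"A", "B"}, 3)
        assert result.proteins() == ["C", "D", "E"]
        # C: degree 3, two links into the 2-seed module of a 5-node network:
        # P(X >= 2) = C(2,2)*C(3,1)/C(5,3) = 3/10
        assert result.candidates[0].p_value == pytest.approx(0.3, abs=1e-12)
        # D and E tie at 3/5 when compared; lexicographic order decides.
        # E's recorded p is evaluated at its own inclusion, against the
        # 4-member module: P(X >= 1) = 4/5.
        assert result.candidates[1].p_value == pytest.approx(0.6, abs=1e-12)
        assert result.candidates[2].p_value == pytest.approx(0.8, abs=1e-12)

    def test_star_centre_seed_breaks_leaf_ties_lexicographically(self):
        g = nx.star_graph(["HUB", "L3", "L1", "L2"])
        result = run_diamond(g, {"HUB"}, 3)
        assert result.proteins() == ["L1", "L2", "L3"]

    def test_no_seed_in_network_is_an_error(self, toy_graph):
        with pytest.raises(ValueError):
            run_diamond(toy_graph, {"Z"}, 1)

    def test_recorded_k_ks_p_are_self_consistent(self, planted_network):
        graph, truth = planted_network
        result = run_diamond(graph, truth["seeds"], 50)
        N = graph.number_of_nodes()
        for c in result.candidates:
            s0 = len(result.seeds_used) + c.rank - 1
            expected = connectivity_pvalue(c.degree_k, c.links_to_module_ks, N, s0)
            assert c.p_value == pytest.approx(expected, rel=1e-9)

    def test_matches_brute_force_oracle_on_random_graphs(self):
        for instance in range(30):
            rnd = random.Random(instance)
            n = rnd.randint(8, 12)
            g = nx.gnp_random_graph(n, rnd.uniform(0.25, 0.5), seed=instance)
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
            seeds = rnd.sample(sorted(g), rnd.randint(2, 4))
            n_iter = min(5, n - len(seeds))
            got = run_diamond(g, seeds, n_iter).proteins()
            assert got == brute_force_diamond(g, seeds, n_iter)

    def test_invariant_to_node_relabelling_order(self, planted_network):
        graph, truth = planted_network
        a = run_diamond(graph, truth["seeds"], 30).proteins()
        shuffled = nx.Graph()
        edges = list(graph.edges(data=True))
        random.Random(3).shuffle(edges)
        shuffled.add_nodes_from(sorted(graph.nodes(), reverse=True))
        shuffled.add_edges_from(edges)
        assert run_diamond(shuffled, truth["seeds"], 30).proteins() == a


class TestSaturation:
    def test_disjoint_reference_gives_zero_curve(self, toy_graph):
        result = run_diamond(toy_graph, {"A", "B"}, 3)
        curve = saturation_curve(result, {"Q1", "Q2"})
        assert np.all(curve.values == 0)

    def test_reference_equal_to_head_reaches_one_and_stays(self, planted_network):
        graph, truth = planted_network
        result = run_diamond(graph, truth["seeds"], 30)
        head = set(result.proteins(10))
        curve = saturation_curve(result, head)
        assert curve.values[9] == pytest.approx(1.0)
        assert np.all(curve.values[9:] == 1.0)

    def test_curve_matches_direct_counting(self, planted_network):
        graph, truth = planted_network
        result = run_diamond(graph, truth["seeds"], 60)
        reference = set(truth["module_members"]) - set(truth["seeds"])
        curve = saturation_curve(result, reference)
        proteins = result.proteins()
        for t in range(1, 61):
            expected = len(set(proteins[:t]) & reference) / len(reference)
            assert curve.values[t - 1] == pytest.approx(expected)
        assert np.all(np.diff(curve.values) >= 0)

    def test_empty_reference_rejected(self, toy_graph):
        result = run_diamond(toy_graph, {"A", "B"}, 2)
        with pytest.raises(ValueError):
            saturation_curve(result, set())


class TestDetectSaturation:
    def test_step_curve_flat_after_600(self):
        values = np.concatenate([np.linspace(0, 0.8, 600), np.full(200, 0.8)])
        assert detect_saturation(SaturationCurve(values, 100), window_w=50, epsilon=0.0) == 600

    def test_strictly_increasing_curve_never_saturates(self):
        values = np.linspace(0, 1, 300)
        assert detect_saturation(SaturationCurve(values, 10), window_w=50, epsilon=0.0) == 300

    def test_agrees_with_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(0)
        values = np.cumsum(rng.random(400) * (rng.random(400) < 0.1)) / 40
        values = np.clip(values / max(values[-1], 1), 0, 1)
        w, eps = 30, 0.01
        n = len(values)
        expected = n
        for t in range(1, n + 1):
            upper = min(t + w, n)
            if values[upper - 1] - values[t - 1] <= eps:
                expected = t
                break
        assert detect_saturation(SaturationCurve(values, 40), w, eps) == expected


class TestCrossValidation:
    def test_reproducible_for_fixed_rng_seed(self, planted_network):
        graph, truth = planted_network
        a = crossvalidate_recovery(graph, truth["seeds"], 5, 40, rng_seed=11)
        b = crossvalidate_recovery(graph, truth["seeds"], 5, 40, rng_seed=11)
        assert np.array_equal(a, b)

    def test_isolated_held_out_seeds_recover_nothing(self):
        g = nx.Graph()
        nx.add_path(g, ["A", "B", "C", "D"])
        g.add_nodes_from(["ISO1", "ISO2"])
        curve = crossvalidate_recovery(g, {"A", "ISO1", "ISO2", "D"}, 2, 2, rng_seed=0)
        # every fold holds out at least one unreachable/isolated seed
        assert curve[-1] < 1.0

    def test_fewer_seeds_than_folds_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            crossvalidate_recovery(toy_graph, {"A", "B"}, 3, 1, rng_seed=0)


class TestRobustness:
    def test_identical_results_give_full_overlap_and_rho_one(self, planted_network):
        graph, truth = planted_network
        result = run_diamond(graph, truth["seeds"], 40)
        report = robustness_rank_correlation(result, result, 40)
        assert report.overlap_count == 40
        assert report.spearman_rho == pytest.approx(1.0)

    def test_reversed_order_gives_rho_minus_one(self, planted_network):
        graph, truth = planted_network
        result = run_diamond(graph, truth["seeds"], 20)
        import copy

        reversed_result = copy.deepcopy(result)
        reversed_result.candidates = [
            type(c)(protein=c.protein, rank=21 - c.rank, p_value=c.p_value,
                    degree_k=c.degree_k, links_to_module_ks=c.links_to_module_ks)
            for c in reversed(result.candidates)
        ]
        report = robustness_rank_correlation(result, reversed_result, 20)
        assert report.spearman_rho == pytest.approx(-1.0)

    def test_perturbed_rerun_matches_independent_correlation(self, planted_network):
        graph, truth = planted_network
        seeds = sorted(truth["seeds"])
        full = run_diamond(graph, seeds, 60)
        reduced = run_diamond(graph, seeds[: max(2, int(len(seeds) * 0.9))], 60)
        report = robustness_rank_correlation(full, reduced, 60)
        shared = set(full.proteins(60)) & set(reduced.proteins(60))
        assert report.overlap_count == len(shared)
        ra = [full.ranks()[p] for p in sorted(shared)]
        rb = [reduced.ranks()[p] for p in sorted(shared)]
        assert report.spearman_rho == pytest.approx(spearman_exact(ra, rb), abs=1e-12)

    def test_tiny_overlap_reports_undefined_rho(self, toy_graph):
        r1 = run_diamond(toy_graph, {"A", "B"}, 1)
        r2 = run_diamond(toy_graph, {"A", "B"}, 1)
        report = robustness_rank_correlation(r1, r2, 1)
        assert report.overlap_count == 1 and report.spearman_rho is None
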