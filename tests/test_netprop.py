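import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirpath.io import GeneSet
from mirpath.netprop import (GeneRanking, PropagationConfig, auc_permutation_null,
                             evaluate_auc, naive_bayes_score, normalize_adjacency,
                             prioritize, propagate_rwr, rank_genes)
from mirpath.simulate import NetworkSimSpec, SeedSimSpec, simulate_gene_sets, simulate_network
from tests.conftest import make_network


def ranking_from_scores(scores: dict) -> GeneRanking:
    return rank_genes(pd.Series(scores))


class TestNormalizeAdjacency:
    def test_unit_degree_pair(self, two_node_network):
        nodes, W, isolated = normalize_adjacency(two_node_network)
        assert nodes == ["A", "B"]
        assert W[0, 1] == pytest.approx(1.0)
        assert isolated == []

    def test_star_normalization(self, star_network):
        nodes, W, _ = normalize_adjacency(star_network)
        hub = nodes.index("HUB")
        leaf = nodes.index("L1")
        assert W[hub, leaf] == pytest.approx(0.5)  # 1/sqrt(4 * 1)

    def test_spectral_radius_at_most_one(self):
        for seed in range(5):
            net, _ = simulate_network(NetworkSimSpec(n_genes=60, module_size=6), seed=seed)
            _, W, _ = normalize_adjacency(net)
            rho = max(abs(np.linalg.eigvalsh(W.toarray())))
            assert rho <= 1.0 + 1e-9

    def test_isolated_nodes_flagged(self):
        net = make_network([("A", "B", 0.5)])
        net.graph.add_node("LONER")
        _, W, isolated = normalize_adjacency(net)
        assert isolated == ["LONER"]


class TestPropagateRWR:
    def test_two_node_closed_form(self, two_node_network, seed_a):
        """Seed A, alpha 0.5: fixed point is (2/3, 1/3)."""
        res = propagate_rwr(two_node_network, seed_a,
                            PropagationConfig(method="rwr", alpha=0.5))
        assert res.converged
        assert res.scores["A"] == pytest.approx(2 / 3, abs=1e-7)
        assert res.scores["B"] == pytest.approx(1 / 3, abs=1e-7)

    def test_restart_only_limit(self, two_node_network, seed_a):
        res = propagate_rwr(two_node_network, seed_a,
                            PropagationConfig(method="rwr", alpha=1e-9))
        assert res.scores["A"] == pytest.approx(1.0, abs=1e-6)
        assert res.scores["B"] == pytest.approx(0.0, abs=1e-6)

    def test_seedless_component_scores_zero(self, seed_a):
        net = make_network([("A", "B", 1.0), ("C", "D", 1.0)])
        res = propagate_rwr(net, seed_a, PropagationConfig(method="rwr"))
        assert res.scores["C"] == 0.0 and res.scores["D"] == 0.0

    def test_fixed_point_satisfies_linear_system(self):
        """Iterative solution matches a direct solve of (I - aW')F = (1-a)F0."""
        for seed in (0, 1):
            net, module = simulate_network(NetworkSimSpec(n_genes=150, module_size=10), seed=seed)
            seeds = GeneSet.from_iterable("s", module[:5])
            cfg = PropagationConfig(method="rwr", alpha=0.6, tol=1e-10)
            res = propagate_rwr(net, seeds, cfg)
            nodes, W, _ = normalize_adjacency(net)
            f0 = np.zeros(len(nodes))
            for g in res.effective_seeds:
                f0[nodes.index(g)] = 1 / len(res.effective_seeds)
            direct = np.linalg.solve(np.eye(len(nodes)) - cfg.alpha * W.toarray(),
                                     (1 - cfg.alpha) * f0)
            assert np.abs(res.scores[nodes].to_numpy() - direct).max() < 1e-7

    def test_absent_seeds_dropped_missing_all_is_error(self, two_node_network):
        res = propagate_rwr(two_node_network,
                            GeneSet.from_iterable("s", ["A", "ZZZ"]),
                            PropagationConfig(method="rwr"))
        assert res.dropped_seeds == ("ZZZ",)
        with pytest.raises(ValueError, match="empty effective seed"):
            propagate_rwr(two_node_network, GeneSet.from_iterable("s", ["ZZZ"]),
                          PropagationConfig(method="rwr"))


class TestNaiveBayesScore:
    def test_two_unit_seed_neighbours(self):
        net = make_network([("G", "S1", 1.0), ("G", "S2", 1.0), ("G", "N1", 1.0)])
        seeds = GeneSet.from_iterable("s", ["S1", "S2"])
        res = naive_bayes_score(net, seeds)
        assert res.scores["G"] == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_no_seed_neighbour_scores_zero(self):
        net = make_network([("G", "N1", 0.9), ("N1", "S1", 0.9)])
        res = naive_bayes_score(net, GeneSet.from_iterable("s", ["S1"]))
        assert res.scores["G"] == 0.0

    def test_additional_seed_neighbour_strictly_increases_score(self):
        net1 = make_network([("G", "S1", 0.8)])
        net2 = make_network([("G", "S1", 0.8), ("G", "S2", 0.8)])
        seeds = GeneSet.from_iterable("s", ["S1", "S2"])
        s1 = naive_bayes_score(net1, seeds).scores["G"]
        s2 = naive_bayes_score(net2, seeds).scores["G"]
        assert s2 > s1


class TestRankGenes:
    def test_descending_order(self):
        r = ranking_from_scores({"A": 3.0, "B": 1.0, "C": 2.0})
        assert list(r.table["gene"]) == ["A", "C", "B"]
        assert list(r.table["rank"]) == [1.0, 2.0, 3.0]

    def test_ties_share_midrank(self):
        r = ranking_from_scores({"A": 1.0, "B": 1.0})
        assert list(r.table["rank"]) == [1.5, 1.5]
        assert list(r.table["gene"]) == ["A", "B"]  # display tie-break by id

    def test_excluding_top_gene_shifts_positions(self):
        scores = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})
        full = rank_genes(scores)
        without = rank_genes(scores, exclude=GeneSet.from_iterable("x", ["A"]))
        assert without.excluded == ("A",)
        assert list(without.table["position"]) == [1, 2]
        assert list(without.table["gene"]) == list(full.table["gene"])[1:]

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            rank_genes(pd.Series({"A": np.nan}))


class TestEvaluateAUC:
    def test_perfect_separation(self):
        r = ranking_from_scores({"P1": 5.0, "P2": 4.0, "N1": 1.0, "N2": 0.5})
        res = evaluate_auc(r, GeneSet.from_iterable("v", ["P1", "P2"]))
        assert res.auc == 1.0
        assert res.roc_points[0] == (0.0, 0.0) and res.roc_points[-1] == (1.0, 1.0)

    def test_pairwise_counting_example(self):
        """Positives {0.9, 0.4} vs negatives {0.5, 0.1}: 3 of 4 pairs concordant."""
        r = ranking_from_scores({"P1": 0.9, "P2": 0.4, "N1": 0.5, "N2": 0.1})
        res = evaluate_auc(r, GeneSet.from_iterable("v", ["P1", "P2"]))
        assert res.auc == pytest.approx(0.75)

    def test_rank_sum_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(6, 50))
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            genes = [f"G{i}" for i in range(n)]
            pos = set(rng.choice(genes, size=int(rng.integers(1, n // 2 + 1)), replace=False))
            r = ranking_from_scores(dict(zip(genes, scores)))
            res = evaluate_auc(r, GeneSet.from_iterable("v", pos))
            sp = [scores[i] for i, g in enumerate(genes) if g in pos]
            sn = [scores[i] for i, g in enumerate(genes) if g not in pos]
            brute = np.mean([[1.0 if a > b else 0.5 if a == b else 0.0 for b in sn]
                             for a in sp])
            assert res.auc == pytest.approx(brute, abs=1e-12)

    def test_roc_is_monotone(self):
        rng = np.random.default_rng(4)
        scores = dict(zip([f"G{i}" for i in range(30)], np.round(rng.normal(size=30), 1)))
        r = ranking_from_scores(scores)
        res = evaluate_auc(r, GeneSet.from_iterable("v", list(scores)[:7]))
        pts = np.array(res.roc_points)
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_random_positive_null_is_centred_at_half(self):
        rng = np.random.default_rng(5)
        scores = dict(zip([f"G{i}" for i in range(200)], rng.normal(size=200)))
        null = auc_permutation_null(ranking_from_scores(scores), n_positives=12,
                                    n_draws=200, seed=6)
        sd = null.std(ddof=1) / math.sqrt(null.size)
        assert abs(null.mean() - 0.5) < 3 * sd + 1e-9

    def test_no_positives_is_error(self):
        r = ranking_from_scores({"A": 1.0, "B": 0.5})
        with pytest.raises(ValueError, match="validation"):
            evaluate_auc(r, GeneSet.from_iterable("v", ["ZZZ"]))


@pytest.fixture(scope="module")
def fixture_inputs():
    net, module = simulate_network(NetworkSimSpec(n_genes=300, module_size=20), seed=8)
    seeds, val = simulate_gene_sets(
        module, net, SeedSimSpec(n_seed=25, n_validation=10, overlap_with_module=0.6,
                                 seed_validation_overlap=2), seed=9)
    return net, seeds, val


class TestPrioritize:
    @pytest.mark.parametrize("method", ["naive_bayes", "rwr"])
    def test_planted_module_beats_chance(self, fixture_inputs, method):
        net, seeds, val = fixture_inputs
        res = prioritize(net, seeds, val, PropagationConfig(method=method))
        assert res.validation.auc > 0.5
        assert res.summary["n_shared_excluded_from_positives"] == 2

    def test_seeds_equal_validation_is_error(self, fixture_inputs):
        net, seeds, _ = fixture_inputs
        with pytest.raises(ValueError, match="validation"):
            prioritize(net, seeds, seeds)

    def test_deterministic_rerun(self, fixture_inputs):
        net, seeds, val = fixture_inputs
        r1 = prioritize(net, seeds, val)
        r2 = prioritize(net, seeds, val)
        assert r1.ranking.table.equals(r2.ranking.table)
        assert r1.summary == r2.summary

    def test_gene_relabeling_leaves_auc_unchanged(self, fixture_inputs):
        net, seeds, val = fixture_inputs
        mapping = {g: f"Z_{g}" for g in net.graph.nodes}
        relabeled = type(net)(nx.relabel_nodes(net.graph, mapping))
        seeds2 = GeneSet.from_iterable("s", [mapping[g] for g in seeds])
        val2 = GeneSet.from_iterable("v", [mapping[g] for g in val])
        r1 = prioritize(net, seeds, val)
        r2 = prioritize(relabeled, seeds2, val2)
        assert r1.validation.auc == pytest.approx(r2.validation.auc, abs=1e-12)
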