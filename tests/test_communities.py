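"""Resolution modularity, Louvain optimisation, exhaustive oracle, stability."""

import numpy as np
import pytest

from carefrag.communities import (GAIN_TOL, ModularityScore, Partition,
                                  UndefinedModularityError, adjusted_rand_index,
                                  exhaustive_best_partition, louvain, modularity,
                                  stability_sweep)
from carefrag.event_log import canonical_sort
from carefrag.metrics import extract_transitions
from carefrag.network import build_network, from_mapping
from carefrag.synthetic import SimulationConfig, generate_event_log

from conftest import random_weighted_net


class TestModularity:
    def test_one_community_is_zero_at_unit_resolution(self, barbell_net):
        part = {v: 0 for v in barbell_net.nodes}
        assert modularity(barbell_net, part).q == pytest.approx(0.0, abs=1e-15)

    def test_singleton_partition_closed_form(self, barbell_net):
        part = {v: i for i, v in enumerate(sorted(barbell_net.nodes))}
        m = barbell_net.total_weight
        expected = -sum((k / (2 * m)) ** 2 for k in barbell_net.degree().values())
        assert modularity(barbell_net, part).q == pytest.approx(expected)

    def test_barbell_of_triangles_brute_force_value(self, barbell_net):
        part = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        assert modularity(barbell_net, part).q == pytest.approx(10 / 28)

    def test_agrees_with_networkx_on_random_graphs(self):
        import networkx as nx

        rng = np.random.default_rng(17)
        for _ in range(10):
            net = random_weighted_net(rng, int(rng.integers(5, 12)))
            labels = {v: int(rng.integers(0, 3)) for v in net.nodes}
            gamma = float(rng.uniform(0.3, 2.5))
            g = nx.Graph()
            g.add_nodes_from(net.nodes)
            for (a, b), w in net.weights.items():
                g.add_edge(a, b, weight=w)
            comms = [{v for v in net.nodes if labels[v] == c} for c in range(3)]
            comms = [c for c in comms if c]
            q_nx = nx.community.modularity(g, comms, weight="weight",
                                           resolution=gamma)
            assert modularity(net, labels, gamma).q == pytest.approx(q_nx)

    def test_label_permutation_invariance(self, two_cliques_net):
        labels = {v: int(i % 3) for i, v in enumerate(sorted(two_cliques_net.nodes))}
        permuted = {v: (c + 1) % 3 for v, c in labels.items()}
        assert (modularity(two_cliques_net, labels).q
                == pytest.approx(modularity(two_cliques_net, permuted).q))

    def test_zero_weight_graph_is_undefined(self):
        net = from_mapping({}, nodes=["A", "B"])
        with pytest.raises(UndefinedModularityError):
            modularity(net, {"A": 0, "B": 0})

    def test_uncovered_node_rejected(self, barbell_net):
        with pytest.raises(ValueError, match="cover"):
            modularity(barbell_net, {"a": 0})


class TestExhaustiveOracle:
    def test_two_node_path_optimum_is_one_community(self):
        net = from_mapping({("a", "b"): 1.0})
        part, score = exhaustive_best_partition(net)
        assert part.n_communities == 1
        assert score.q == pytest.approx(0.0, abs=1e-15)

    def test_barbell_optimum_is_the_triangles(self, barbell_net):
        part, score = exhaustive_best_partition(barbell_net)
        assert score.q == pytest.approx(10 / 28)
        assert part.assignment == {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}

    def test_refuses_large_graphs(self):
        net = from_mapping({(f"n{i}", f"n{i+1}"): 1.0 for i in range(11)})
        with pytest.raises(ValueError, match="exhaustive"):
            exhaustive_best_partition(net)


class TestLouvain:
    def test_two_cliques_found_for_any_seed(self, two_cliques_net):
        expected = {"a": 0, "b": 0, "c": 0, "d": 0, "e": 1, "f": 1, "g": 1, "h": 1}
        for seed in range(8):
            part, score = louvain(two_cliques_net, seed=seed)
            assert part.assignment == expected

    def test_single_clique_stays_whole(self):
        w = {(a, b): 1.0 for i, a in enumerate("abcde")
             for b in "abcde"[i + 1:]}
        part, _ = louvain(from_mapping(w), seed=1)
        assert part.n_communities == 1

    def test_same_seed_reproducible(self, barbell_net):
        p1, s1 = louvain(barbell_net, seed=123)
        p2, s2 = louvain(barbell_net, seed=123)
        assert p1.assignment == p2.assignment and s1 == s2

    def test_labels_canonical_consecutive_from_zero(self, two_cliques_net):
        part, _ = louvain(two_cliques_net, seed=0)
        labels = [part.assignment[v] for v in sorted(part.assignment)]
        assert labels[0] == 0
        assert set(labels) == set(range(part.n_communities))

    def test_isolated_nodes_end_in_singletons(self, barbell_net):
        net = from_mapping(dict(barbell_net.weights), nodes=["zz1", "zz2"])
        part, _ = louvain(net, seed=0)
        assert part.assignment["zz1"] != part.assignment["zz2"]
        assert sum(1 for v, c in part.assignment.items()
                   if c == part.assignment["zz1"]) == 1

    def test_invalid_gamma_and_empty_graph_rejected(self, barbell_net):
        with pytest.raises(ValueError, match="gamma"):
            louvain(barbell_net, gamma=0.0)
        empty = from_mapping({}, nodes=["a", "b"])
        with pytest.raises(UndefinedModularityError):
            louvain(empty)

    def test_never_below_singletons_never_above_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            net = random_weighted_net(rng, int(rng.integers(5, 9)))
            m = net.total_weight
            q_singletons = -sum((k / (2 * m)) ** 2 for k in net.degree().values())
            _, oracle = exhaustive_best_partition(net)
            _, score = louvain(net, seed=int(rng.integers(100)))
            assert score.q >= q_singletons - 1e-12
            assert score.q <= oracle.q + 1e-9

    def test_planted_four_communities_recovered_exactly(self):
        cfg = SimulationConfig(n_providers=40, n_communities=4, n_patients=5000,
                               p_within_community=0.95, p_switch_provider=0.3,
                               seed=1)
        log, truth = generate_event_log(cfg)
        tr = extract_transitions(canonical_sort(log), check_sorted=False)
        net = build_network(tr)
        part, _ = louvain(net, seed=1)
        nodes = sorted(net.nodes)
        ari = adjusted_rand_index(part.labels_for(nodes),
                                  [truth.provider_community[v] for v in nodes])
        assert ari == 1.0


class TestResolutionLimits:
    def test_small_gamma_favours_one_community(self, barbell_net):
        part, _ = louvain(barbell_net, gamma=0.01, seed=0)
        assert part.n_communities == 1
        opart, _ = exhaustive_best_partition(barbell_net, gamma=0.01)
        assert opart.n_communities == 1

    def test_large_gamma_favours_singletons(self, barbell_net):
        # singletons dominate once gamma > 2m * max(A) / min over connected
        # pairs of k_i k_j; for the barbell 2*7*1/(2*2) = 3.5
        gamma = 4.0
        part, _ = louvain(barbell_net, gamma=gamma, seed=0)
        assert part.n_communities == barbell_net.n_nodes
        opart, _ = exhaustive_best_partition(barbell_net, gamma=gamma)
        assert opart.n_communities == barbell_net.n_nodes


class TestStabilitySweep:
    def test_disconnected_cliques_fully_stable(self):
        w = {}
        for grp in ("abc", "xyz"):
            for i in range(3):
                for j in range(i + 1, 3):
                    w[(grp[i], grp[j])] = 1.0
        net = from_mapping(w)
        report = stability_sweep(net, [1.0], n_seeds=6)
        row = report["gammas"][0]
        assert row["mean_pairwise_ari"] == 1.0
        assert row["stable"] is True
        assert row["n_communities_modal"] == 2

    def test_single_gamma_matches_multi_seed_louvain(self, two_cliques_net):
        report = stability_sweep(two_cliques_net, [1.0], n_seeds=4)
        best_q = max(louvain(two_cliques_net, seed=s)[1].q for s in range(4))
        assert report["gammas"][0]["best_q"] == pytest.approx(best_q)

    def test_unstructured_dense_graph_not_flagged_stable(self):
        rng = np.random.default_rng(3)
        nodes = [f"n{i:02d}" for i in range(24)]
        w = {}
        for i in range(24):
            for j in range(i + 1, 24):
                if rng.random() < 0.5:
                    w[(nodes[i], nodes[j])] = 1.0
        net = from_mapping(w, nodes=nodes)
        report = stability_sweep(net, [1.0], n_seeds=8)
        assert report["gammas"][0]["mean_pairwise_ari"] < 0.95
        assert report["gammas"][0]["stable"] is False

    def test_preconditions(self, barbell_net):
        with pytest.raises(ValueError, match="n_seeds"):
            stability_sweep(barbell_net, [1.0], n_seeds=1)
        with pytest.raises(ValueError, match="gamma"):
            stability_sweep(barbell_net, [0.0, 1.0], n_seeds=2)


class TestPartitionContainer:
    def test_from_labels_canonicalises(self):
        part = Partition.from_labels({"b": 7, "a": 3, "c": 7})
        assert part.assignment == {"a": 0, "b": 1, "c": 1}
        assert part.n_communities == 2

    def test_serialisation_round_trip(self, tmp_path):
        part = Partition.from_labels({"a": 0, "b": 1, "c": 1})
        part.to_csv(tmp_path / "p.csv")
        part.to_json(tmp_path / "p.json")
        import json

        with open(tmp_path / "p.json") as fh:
            back = json.load(fh)
        assert back["assignment"] == part.assignment
        lines = (tmp_path / "p.csv").read_text().splitlines()
        assert lines == ["provider_code,community", "a,0", "b,1", "c,1"]
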