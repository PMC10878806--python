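import networkx as nx
import numpy as np
import pytest
from scipy import stats

from bowtienet import (
    CascadeConfig,
    SnapshotNetwork,
    component_influence_distributions,
    info_influence,
    initializer_sweep,
    run_cascade,
    simulate_ensemble,
)


def make_net(node_spec, edges, label="feb"):
    """node_spec: {id: (polarity, fans)}"""
    g = nx.DiGraph()
    for n, (pol, f) in node_spec.items():
        g.add_node(n, polarity=pol, fans=f)
    g.add_edges_from(edges)
    return SnapshotNetwork(label=label, graph=g)


@pytest.fixture(scope="module")
def chain_net():
    # recommendations a->b->c: information flows c => b => a
    return make_net(
        {"a": ("r", 1), "b": ("r", 2), "c": ("r", 4)},
        [("a", "b"), ("b", "c")],
    )


class TestRunCascade:
    def test_beta_zero_only_seed(self, chain_net):
        assert run_cascade(chain_net, "c", 0.0, 0.5, rng=0) == {"c"}

    def test_beta_one_reverse_closure(self, small_pair_truth):
        net = small_pair_truth[0].early
        g = net.graph
        nodes = list(g.nodes)
        rng = np.random.default_rng(3)
        for seed_page in rng.choice(nodes, size=5, replace=False):
            closure = nx.ancestors(g, seed_page) | {seed_page}
            for gamma in (0.1, 1.0):
                impacted = run_cascade(
                    net, seed_page, 1.0, gamma, rng=rng
                )
                assert impacted == closure

    def test_flow_is_reversed(self, chain_net):
        # seed at the chain's recommender end: nobody recommends a,
        # so the piece stays put even at beta = 1
        assert run_cascade(chain_net, "a", 1.0, 1.0, rng=0) == {"a"}
        assert run_cascade(chain_net, "c", 1.0, 1.0, rng=0) == {
            "a", "b", "c"
        }

    def test_single_edge_doubling_frequency(self):
        # u recommends the seed, gamma = 1: exactly one transmission
        # opportunity, so the cascade doubles with probability beta
        net = make_net(
            {"u": ("r", 1), "s": ("r", 1)}, [("u", "s")]
        )
        rng = np.random.default_rng(8)
        n, beta = 4000, 0.5
        doubles = sum(
            len(run_cascade(net, "s", beta, 1.0, rng=rng)) == 2
            for _ in range(n)
        )
        se = np.sqrt(beta * (1 - beta) / n)
        assert abs(doubles / n - beta) < 3 * se

    def test_invalid_rates_rejected(self, chain_net):
        with pytest.raises(ValueError):
            run_cascade(chain_net, "a", 1.5, 0.5)
        with pytest.raises(ValueError):
            run_cascade(chain_net, "a", 0.5, 0.0)

    def test_monotone_in_beta(self, small_pair_truth):
        net = small_pair_truth[0].early
        pool = [n for n in net.nodes if net.polarity[n] != "g"]
        seeds = np.random.default_rng(1).choice(pool, size=60)
        means = []
        for beta in (0.1, 0.3, 0.5, 0.7, 0.9):
            rng = np.random.default_rng(99)  # paired randomness
            sizes = [
                len(run_cascade(net, s, beta, 0.3, rng=rng))
                for s in seeds
            ]
            means.append(np.mean(sizes))
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestInfoInfluence:
    def test_seed_only(self):
        pols, fans = {"s": "r"}, {"s": 10}
        assert info_influence({"s"}, "r", pols, fans) == (10.0, 0.0)

    def test_mixed_polarities(self):
        pols = {"s": "r", "x": "g", "y": "b"}
        fans = {"s": 10, "x": 7, "y": 4}
        w, a = info_influence({"s", "x", "y"}, "r", pols, fans)
        assert (w, a) == (10.0, 7.0)  # opposite stance y discarded

    def test_zero_fan_seed_all_neutral(self):
        pols = {"s": "b", "x": "g", "y": "g"}
        fans = {"s": 0, "x": 3, "y": 5}
        assert info_influence(
            {"s", "x", "y"}, "b", pols, fans
        ) == (0.0, 8.0)

    def test_neutral_seed_rejected(self):
        with pytest.raises(ValueError):
            info_influence({"s"}, "g", {"s": "g"}, {"s": 1})


class TestEnsemble:
    def test_conservation_exact(self, small_pair_truth):
        pair, truth = small_pair_truth
        roles = {
            n: ("SCC" if truth.planted_role[n] == "SCC" else "NA")
            for n in pair.early.nodes
        }
        cfg = CascadeConfig(
            beta=0.4, gamma=0.4, n_pieces=200, rng_seed=0
        )
        res = simulate_ensemble(pair.early, roles, cfg)
        assert sum(res.page_w.values()) == pytest.approx(
            res.info_w.sum(), abs=1e-9
        )
        assert sum(res.page_a.values()) == pytest.approx(
            res.info_a.sum(), abs=1e-9
        )

    def test_impacted_within_reverse_closure(self, small_pair_truth):
        pair, _ = small_pair_truth
        net = pair.early
        roles = {n: "NA" for n in net.nodes}
        cfg = CascadeConfig(
            beta=0.6, gamma=0.5, n_pieces=50, rng_seed=4
        )
        res = simulate_ensemble(net, roles, cfg)
        for seed_page, imp in zip(res.seeds, res.impacted):
            closure = nx.ancestors(net.graph, seed_page) | {seed_page}
            assert imp <= closure
            assert seed_page in imp

    def test_concentrated_weights_single_seeder(self, chain_net):
        roles = {"a": "SCC", "b": "OUT", "c": "IN"}
        cfg = CascadeConfig(
            beta=0.5, gamma=0.5, n_pieces=100,
            initializer_weights={
                "SCC": 1e9, "OUT": 1e-9, "IN": 1e-9, "NA": 1e-9
            },
            rng_seed=0,
        )
        res = simulate_ensemble(chain_net, roles, cfg)
        assert set(res.seeds) == {"a"}
        assert res.page_w["b"] == res.page_w["c"] == 0.0

    def test_uniform_weights_multinomial(self, small_pair_truth):
        pair, _ = small_pair_truth
        net = pair.early
        pool = [n for n in net.nodes if net.polarity[n] != "g"]
        roles = {n: "NA" for n in net.nodes}
        cfg = CascadeConfig(
            beta=0.0, gamma=1.0, n_pieces=3000, rng_seed=10
        )
        res = simulate_ensemble(net, roles, cfg)
        counts = {n: 0 for n in pool}
        for s in res.seeds:
            counts[s] += 1
        observed = np.array(list(counts.values()))
        expected = np.full(len(pool), cfg.n_pieces / len(pool))
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.01

    def test_empty_pool_rejected(self):
        net = make_net({"x": ("g", 1)}, [])
        with pytest.raises(ValueError):
            simulate_ensemble(
                net, {"x": "NA"},
                CascadeConfig(beta=0.5, gamma=0.5, n_pieces=1),
            )

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            CascadeConfig(
                beta=0.5, gamma=0.5, n_pieces=1,
                initializer_weights={"SCC": 0.0, "IN": 1, "OUT": 1,
                                     "NA": 1},
            )


class TestComponentDistributions:
    def test_beta_zero_degenerate_samples(self, small_pair_truth):
        pair, truth = small_pair_truth
        net = pair.early
        roles = {
            n: (truth.planted_role[n]
                if truth.planted_role[n] in ("SCC", "IN", "OUT")
                else "NA")
            for n in net.nodes
        }
        fans = net.fan_count
        pols = net.polarity
        dists = component_influence_distributions(
            net, roles, beta=0.0, gamma=1.0,
            pieces_per_component=50, seed=0,
        )
        for comp, samples in dists.items():
            eligible_fans = {
                fans[n] for n in net.nodes
                if roles[n] == comp and pols[n] != "g"
            }
            assert set(samples["W"]) <= eligible_fans
            assert np.all(samples["A"] == 0)

    def test_single_page_component(self):
        net = make_net(
            {"s": ("r", 5), "t": ("g", 1)}, [("t", "s")]
        )
        roles = {"s": "SCC", "t": "NA"}
        dists = component_influence_distributions(
            net, roles, beta=0.0, gamma=1.0,
            pieces_per_component=20, seed=0,
            components=("SCC",),
        )
        assert np.all(dists["SCC"]["W"] == 5)

    def test_empty_component_skipped(self, chain_net):
        roles = {"a": "NA", "b": "NA", "c": "NA"}
        dists = component_influence_distributions(
            chain_net, roles, pieces_per_component=5, seed=0
        )
        assert dists == {}


class TestInitializerSweep:
    def test_axis_validation(self, chain_net):
        roles = {"a": "SCC", "b": "OUT", "c": "IN"}
        delta = {"a": 1, "b": 2, "c": 3}
        with pytest.raises(ValueError, match="distinct"):
            initializer_sweep(
                chain_net, roles, "SCC", "SCC", delta
            )
        with pytest.raises(ValueError, match="strictly positive"):
            initializer_sweep(
                chain_net, roles, "SCC", "OUT", delta, grid=[0.0, 1.0]
            )

    def test_shuffled_target_gives_near_zero_cc(self, small_pair_truth):
        pair, truth = small_pair_truth
        net = pair.early
        roles = {
            n: (truth.planted_role[n]
                if truth.planted_role[n] in ("SCC", "IN", "OUT")
                else "NA")
            for n in net.nodes
        }
        rng = np.random.default_rng(0)
        pool = [n for n in net.nodes if net.polarity[n] != "g"]
        shuffled = rng.permutation([net.fan_count[n] for n in pool])
        delta = {n: float(v) for n, v in zip(pool, shuffled)}
        rows = initializer_sweep(
            net, roles, "SCC", "OUT", delta,
            grid=[1.0], n_pieces=1500, stratum="all", seed=1,
        )
        for row in rows:
            assert abs(row["cc"]) < 0.15
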