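import networkx as nx
import numpy as np
import pandas as pd
import pytest

from bowtienet import (
    NodePartition,
    SnapshotNetwork,
    classify_expansion,
    compute_features,
    feature_matrix,
    label_expansion,
    rank_features,
    regress_variation,
)
from bowtienet.features import CATEGORICAL_FEATURES, NUMERIC_FEATURES


def make_net(node_spec, edges):
    g = nx.DiGraph()
    for n, (pol, f) in node_spec.items():
        g.add_node(n, polarity=pol, fans=f)
    g.add_edges_from(edges)
    return SnapshotNetwork(label="feb", graph=g)


def trivial_partition(net, label="C1"):
    return NodePartition(
        community={n: label for n in net.nodes}, origin="detected"
    )


@pytest.mark.parametrize(
    "early,late,expected",
    [(5, 7, 1), (5, 5, 0), (5, 3, 0), (0, 1, 1)],
)
def test_label_expansion(early, late, expected):
    assert label_expansion(early, late) == expected


class TestComputeFeatures:
    def test_hand_computed_strengths(self):
        # v is recommended by u (same polarity, w=6) and w (neutral,
        # w=15): k_in = 21, same-polarity share 6/21; v recommends only
        # the neutral page w: k_out = 15, same-polarity share 0
        net = make_net(
            {"u": ("r", 2), "v": ("r", 3), "w": ("g", 5)},
            [("u", "v"), ("w", "v"), ("v", "w")],
        )
        roles = {n: "NA" for n in net.nodes}
        table = compute_features(
            net, roles, roles, trivial_partition(net)
        )
        v = table.loc["v"]
        assert v["k_in"] == 21
        assert v["kps_in"] == pytest.approx(6 / 21)
        assert v["k_out"] == 15
        assert v["kps_out"] == 0.0
        assert "w" not in table.index  # neutral pages are not rows

    def test_isolated_page_degenerate(self):
        net = make_net({"u": ("r", 2)}, [])
        roles = {"u": "NA"}
        table = compute_features(
            net, roles, roles, trivial_partition(net)
        )
        u = table.loc["u"]
        assert u["k_in"] == u["k_out"] == 0
        assert u["kps_in"] == u["kcs_in"] == 0.0
        assert u["degenerate_in"] and u["degenerate_out"]

    def test_single_matching_recommender(self):
        net = make_net(
            {"u": ("r", 2), "v": ("r", 3)}, [("u", "v")]
        )
        roles = {n: "NA" for n in net.nodes}
        table = compute_features(
            net, roles, roles, trivial_partition(net)
        )
        v = table.loc["v"]
        assert v["kps_in"] == 1.0
        assert v["kcs_in"] == 1.0

    def test_worked_toy_hand_values(self, toy_pair):
        # page a (pro, 100 fans) is recommended by b (5000), c (8000)
        # and d (1000): k_in = 14000 of which 13000 comes from pro
        # pages; it recommends b (5000) and f (20000): k_out = 25000
        # with a 0.2 same-stance share
        import bowtienet as bn

        net = toy_pair.early
        part = bn.polarity_partition(net)
        roles = {n: "NA" for n in net.nodes}
        table = compute_features(net, roles, roles, part)
        a = table.loc["a"]
        assert a["k_in"] == 14000
        assert a["kps_in"] == pytest.approx(13000 / 14000)
        assert a["k_out"] == 25000
        assert a["kps_out"] == pytest.approx(0.2)
        # with polarity groups as communities the community share
        # coincides with the polarity share
        assert a["kcs_in"] == a["kps_in"]

    def test_strength_decomposition_invariant(self, small_pair_truth):
        # same-polarity strength plus other-polarity strength is the
        # weighted in-degree, exactly, for every page
        pair, _ = small_pair_truth
        net = pair.early
        roles = {n: "NA" for n in net.nodes}
        part = NodePartition(
            community=dict(net.polarity), origin="detected"
        )
        table = compute_features(net, roles, roles, part)
        g = net.graph
        pols = net.polarity
        for i in table.index:
            other = sum(
                g.edges[j, i]["weight"]
                for j, _ in g.in_edges(i)
                if pols[j] != pols[i]
            )
            same = table.loc[i, "kps_in"] * table.loc[i, "k_in"]
            assert same + other == pytest.approx(table.loc[i, "k_in"])

    def test_one_hot_round_trip(self, small_pair_truth):
        pair, truth = small_pair_truth
        net = pair.early
        roles = {
            n: (truth.planted_role[n]
                if truth.planted_role[n] in ("SCC", "IN", "OUT")
                else "NA")
            for n in net.nodes
        }
        part = NodePartition(
            community=dict(net.polarity), origin="detected"
        )
        table = compute_features(net, roles, roles, part)
        X, names = feature_matrix(table, include=["w_bt"])
        cats = [n.split("_", 2)[-1] for n in names]
        decoded = [cats[k] for k in X.argmax(axis=1)]
        assert decoded == list(table["w_bt"])


def synthetic_table(n, rng, informative=True):
    """Small feature table with a known linear signal in k_in."""
    table = pd.DataFrame(
        {
            "p": rng.choice(["r", "b"], size=n),
            "c": rng.choice(["C1", "C2", "C3"], size=n),
            "w_bt": rng.choice(["SCC", "IN", "OUT", "NA"], size=n),
            "a_bt": rng.choice(["SCC", "IN", "OUT", "NA"], size=n),
            "f": rng.integers(0, 500, size=n),
            "k_in": rng.uniform(0, 1000, size=n),
            "k_out": rng.uniform(0, 1000, size=n),
            "kps_in": rng.uniform(0, 1, size=n),
            "kps_out": rng.uniform(0, 1, size=n),
            "kcs_in": rng.uniform(0, 1, size=n),
            "kcs_out": rng.uniform(0, 1, size=n),
            "pagerank": rng.uniform(0, 0.01, size=n),
            "betweenness": rng.uniform(0, 0.01, size=n),
        }
    )
    delta = (
        3.0 * table["k_in"].to_numpy()
        if informative
        else rng.normal(size=n)
    )
    return table, delta


class TestClassification:
    def test_separable_features_perfect_accuracy(self, rng):
        table, _ = synthetic_table(200, rng)
        labels = (
            table["k_in"].to_numpy() > np.median(table["k_in"])
        ).astype(int)
        out = classify_expansion(table, labels, seed=0)
        assert out.metrics["accuracy"] > 0.95

    def test_null_labels_near_chance(self, rng):
        table, _ = synthetic_table(600, rng, informative=False)
        labels = rng.integers(0, 2, size=len(table))
        out = classify_expansion(table, labels, seed=0)
        assert abs(out.metrics["accuracy"] - 0.5) < 0.1
        assert abs(out.baseline["accuracy"] - 0.5) < 0.1

    def test_single_class_rejected(self, rng):
        table, _ = synthetic_table(50, rng)
        with pytest.raises(ValueError):
            classify_expansion(table, np.ones(50, dtype=int), seed=0)


class TestRegression:
    def test_noiseless_linear_recovery(self, rng):
        table, delta = synthetic_table(300, rng)
        for model in ("svr", "rfr"):
            out = regress_variation(
                table, delta, stratum="all", model=model, seed=0
            )
            assert out.metrics["r2"] > 0.9, model

    def test_constant_target_zero_mae(self, rng):
        table, _ = synthetic_table(60, rng)
        delta = np.full(60, 5.0)
        out = regress_variation(
            table, delta, stratum="expanding", model="svr", seed=0
        )
        assert out.metrics["mae"] == pytest.approx(0.0, abs=1e-6)
        assert out.baseline["mae"] == pytest.approx(0.0, abs=1e-9)

    def test_baseline_r2_nonpositive(self, rng):
        table, delta = synthetic_table(200, rng)
        out = regress_variation(
            table, delta, stratum="all", model="rfr", seed=0
        )
        assert out.baseline["r2"] <= 0.05

    def test_small_stratum_rejected(self, rng):
        table, delta = synthetic_table(30, rng)
        delta = -np.abs(delta)  # nothing expanding
        with pytest.raises(ValueError):
            regress_variation(
                table, delta, stratum="expanding", model="svr", seed=0
            )

    def test_seeded_reproducibility(self, rng):
        table, delta = synthetic_table(120, rng)
        delta = delta + rng.normal(scale=50, size=120)
        a = regress_variation(table, delta, model="rfr", seed=7)
        b = regress_variation(table, delta, model="rfr", seed=7)
        assert a.metrics == b.metrics


class TestRankFeatures:
    def test_feature_equal_to_target_cc_one(self, rng):
        table, _ = synthetic_table(100, rng)
        delta = table["f"].to_numpy(dtype=float)
        out = rank_features(
            table, delta, include_mi=False, include_sffs=False, seed=0
        )
        assert out.loc["f", "cc_all"] == pytest.approx(1.0)

    def test_independent_feature_near_zero_cc(self, rng):
        table, _ = synthetic_table(3000, rng, informative=False)
        delta = rng.normal(size=3000)
        out = rank_features(
            table, delta, include_mi=False, include_sffs=False, seed=0
        )
        assert abs(out.loc["k_out", "cc_all"]) < 0.05

    def test_zero_variance_flagged(self, rng):
        table, delta = synthetic_table(100, rng)
        table["betweenness"] = 0.0
        out = rank_features(
            table, delta, include_mi=False, include_sffs=False, seed=0
        )
        assert out.loc["betweenness", "cc_all"] == 0.0
        assert out.loc["betweenness", "zero_variance"]

    def test_mi_finds_informative_feature(self, rng):
        table, delta = synthetic_table(400, rng)
        out = rank_features(
            table, delta, n_runs=3, include_sffs=False, seed=0
        )
        mi = out["mi_all"].loc[list(NUMERIC_FEATURES)]
        assert mi.idxmax() == "k_in"

    def test_sffs_selects_signal(self, rng):
        table, delta = synthetic_table(150, rng)
        delta = np.abs(delta) + 1.0  # everything expanding
        out = rank_features(
            table, delta, n_runs=2, sffs_subset=3,
            include_mi=False, seed=0, sffs_cv_folds=3,
        )
        assert out.loc["k_in", "sffs_rfr"] == 2
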