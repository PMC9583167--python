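import networkx as nx
import numpy as np
import pytest

import _oracles as oracle
from leafnetmap.interaction_networks import (
    ClassifierConfig,
    InteractionNetwork,
    PairEffects,
    classify_pairs,
    estimate_pair_effects,
)
from leafnetmap.network_properties import (
    INDEX_NAMES,
    build_property_table,
    compute_indices,
    population_edge_weights,
    sample_specific_network,
)


class TestComputeIndices:
    def test_path_graph_hand_values(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c")], weight=1.0)
        idx = compute_indices(g)
        # per-node closeness: middle 1.0, ends 2/3; eccentricity: 1 and 2
        assert idx["C"] == pytest.approx(np.mean([1.0, 2 / 3, 2 / 3]), abs=1e-15)
        assert idx["E"] == pytest.approx(np.mean([1, 2, 2]), abs=1e-15)
        assert idx["Con"] == pytest.approx(4 / 3)
        # only the middle node lies between the single (end, end) pair
        assert idx["B"] == pytest.approx(1 / 3, abs=1e-15)

    def test_empty_graph(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        idx = compute_indices(g)
        assert idx["empty"] is True
        assert all(idx[k] == 0.0 for k in INDEX_NAMES)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        for k in range(30):
            g = oracle.random_graph(rng, directed=(k % 3 == 0))
            got = compute_indices(g)
            want = oracle.all_indices(g)
            for name in INDEX_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-9), (
                    f"{name} mismatch on graph {k}")


class TestSampleSpecific:
    def _net(self, table):
        pairs = [PairEffects(a, b, 0.3, 0.3, 1.0, 1.0)
                 for a, b in [("OTU1", "OTU2"), ("OTU2", "OTU3"),
                              ("OTU1", "OTU4")]]
        return classify_pairs(pairs, table)["mutualism"]

    def test_mean_identity(self, tiny_table):
        net = self._net(tiny_table)
        pop = population_edge_weights(net, tiny_table)
        acc = {e: 0.0 for e in pop}
        for s in tiny_table.sample_ids:
            single = sample_specific_network(net, tiny_table, s)
            for e in acc:
                acc[e] += single.graph.edges[e]["weight"]
        for e, total in acc.items():
            assert total / tiny_table.n_samples == pytest.approx(pop[e], abs=1e-12)

    def test_unknown_sample(self, tiny_table):
        with pytest.raises(KeyError):
            sample_specific_network(self._net(tiny_table), tiny_table, "nope")

    def test_topology_frozen(self, tiny_table):
        net = self._net(tiny_table)
        single = sample_specific_network(net, tiny_table, "s0")
        assert set(single.graph.edges()) == set(net.graph.edges())


class TestPropertyTable:
    def test_shapes_and_standardization(self, small_sim):
        _, _, table, design, _ = small_sim
        cfg = ClassifierConfig(rng_seed=3, n_subsamples=15)
        pairs = estimate_pair_effects(table, cfg)
        nets = classify_pairs(pairs, table, cfg, experiment=("SU", 2012))
        props = build_property_table({("SU", 2012): nets}, table, design)
        assert list(props.values.index) == table.sample_ids
        assert len(props.columns()) == 4 * len(INDEX_NAMES)
        std = props.standardized
        n_varying = 0
        for col in std.columns:
            v = std[col].dropna()
            if len(v) > 1 and v.std() > 0:
                n_varying += 1
                assert v.mean() == pytest.approx(0.0, abs=1e-9)
                assert v.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        # standardization must not have flattened the genuinely varying
        # columns (closeness depends on edge weights in every non-empty type)
        assert n_varying >= 3

    def test_empty_type_gives_nan(self, tiny_table, tiny_design):
        nets = classify_pairs([], tiny_table, experiment=("SU", 2012))
        props = build_property_table({("SU", 2012): nets}, tiny_table,
                                     tiny_design)
        assert props.values.isna().all().all()
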