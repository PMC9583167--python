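import itertools

import networkx as nx
import numpy as np
import pytest

from leafnetmap.interaction_networks import (
    ClassifierConfig,
    InteractionNetwork,
    PairEffects,
    assign_roles,
    check_ecological_hypotheses,
    classify_pair,
    classify_pairs,
    clr_transform,
    estimate_pair_effects,
)
from leafnetmap.io_formats import AbundanceTable


class TestClr:
    def test_rows_center_to_zero(self):
        x = np.array([[0.5, 0.3, 0.2], [0.1, 0.1, 0.8]])
        z = clr_transform(x)
        np.testing.assert_allclose(z.sum(axis=1), 0.0, atol=1e-12)

    def test_scale_invariance(self):
        x = np.array([[0.5, 0.3, 0.2]])
        np.testing.assert_allclose(clr_transform(x), clr_transform(10 * x),
                                   atol=1e-12)


def _pair(e_LS, e_SL):
    # OTU "L" has the higher mean abundance in `_ABUND`
    return PairEffects("L", "S", e_LS, e_SL, 0.9, 0.9)


_ABUND = {"L": 0.7, "S": 0.3}


class TestDecisionTable:
    # signs (e_{L->S}, e_{S->L}) -> (type, (source, target))
    EXPECTED = {
        (1, 1): ("mutualism", ("L", "S")),
        (-1, -1): ("antagonism", ("L", "S")),
        (-1, 0): ("aggression", ("L", "S")),
        (-1, 1): ("aggression", ("L", "S")),
        (0, -1): ("aggression", ("S", "L")),
        (1, 0): ("altruism", ("L", "S")),
        (1, -1): ("altruism", ("L", "S")),
        (0, 1): ("altruism", ("S", "L")),
        (0, 0): None,
    }

    @pytest.mark.parametrize("sL,sS", list(itertools.product((-1, 0, 1), repeat=2)))
    def test_exhaustive(self, sL, sS):
        p = _pair(0.2 * sL, 0.2 * sS)
        assert classify_pair(p, _ABUND) == self.EXPECTED[(sL, sS)]

    def test_zero_band(self):
        cfg = ClassifierConfig()
        eps = cfg.effect_zero_band
        p = _pair(eps * 0.9, -0.2)  # first effect inside the band -> 0
        assert classify_pair(p, _ABUND, cfg) == ("aggression", ("S", "L"))

    def test_equal_abundance_tie_is_lexicographic(self):
        p = PairEffects("B", "A", 0.2, -0.2, 0.9, 0.9)
        # tie: L = "A" (lexicographic); effect of A on B is e_ji = -0.2
        verdict = classify_pair(p, {"A": 0.5, "B": 0.5})
        assert verdict == ("aggression", ("A", "B"))


class TestClassifyPairs:
    def test_edges_mutually_exclusive(self, tiny_table):
        pairs = [
            PairEffects("OTU1", "OTU2", 0.3, 0.3, 1.0, 1.0),
            PairEffects("OTU1", "OTU3", -0.3, -0.3, 1.0, 1.0),
            PairEffects("OTU2", "OTU4", -0.3, 0.0, 1.0, 0.0),
            PairEffects("OTU3", "OTU4", 0.3, 0.0, 1.0, 0.0),
        ]
        nets = classify_pairs(pairs, tiny_table)
        assert set(nets) == {"mutualism", "antagonism", "aggression", "altruism"}
        seen = set()
        for net in nets.values():
            for u, v in net.graph.edges():
                key = frozenset((u, v))
                assert key not in seen
                seen.add(key)
        assert len(seen) == 4
        assert nets["aggression"].graph.is_directed()
        assert not nets["mutualism"].graph.is_directed()
        # every network carries the full node set with mean abundances
        for net in nets.values():
            assert set(net.graph.nodes()) == set(tiny_table.otu_ids)


class TestRoles:
    def test_aggression_roles(self, tiny_table):
        pairs = [
            PairEffects("OTU1", "OTU2", -0.3, 0.0, 1.0, 0.0),  # 1 -> 2
            PairEffects("OTU2", "OTU3", -0.3, 0.0, 1.0, 0.0),  # 2 -> 3
        ]
        nets = classify_pairs(pairs, tiny_table)
        net = assign_roles(nets["aggression"])
        assert net.roles["OTU1"] == "hawk"
        assert net.roles["OTU2"] == "hawk-dove"
        assert net.roles["OTU3"] == "dove"

    def test_mutualism_star_roles(self):
        g = nx.Graph()
        for o in "hub a b c d".split():
            g.add_node(o, mean_abundance=0.2)
        for o in "a b c d".split():
            g.add_edge("hub", o)
        net = assign_roles(InteractionNetwork(type="mutualism", graph=g))
        assert net.roles["hub"] == "primary_leader"
        assert all(net.roles[o] == "secondary_leader" for o in "abcd")

    def test_antagonism_roles(self):
        g = nx.Graph()
        g.add_node("big", mean_abundance=0.8)
        g.add_node("mid", mean_abundance=0.5)
        g.add_node("small", mean_abundance=0.1)
        g.add_edge("big", "mid")
        g.add_edge("mid", "small")
        net = assign_roles(InteractionNetwork(type="antagonism", graph=g))
        assert net.roles["big"] == "larger_antagonist"
        assert net.roles["mid"] == "mixed_antagonist"
        assert net.roles["small"] == "smaller_antagonist"


class TestEstimatePairEffects:
    def test_recovers_directed_effect_from_linear_mixture(self):
        # equilibrium fluctuations x = -A^{-1} r with independent lognormal
        # growth-rate noise: the ICA deconvolution must find the one strong
        # asymmetric interaction and not invent effects elsewhere
        rng = np.random.default_rng(42)
        n, m = 6, 500
        A = -np.eye(n)
        A[1, 0] = 0.45  # OTU0 promotes OTU1, no reciprocal effect
        R = np.exp(rng.normal(-0.08, 0.4, size=(m, n))) * rng.uniform(
            0.8, 1.5, size=n)
        X = -np.linalg.solve(A, R.T).T
        X = X / X.sum(axis=1, keepdims=True)
        table = AbundanceTable([f"s{i}" for i in range(m)],
                               [f"O{i}" for i in range(n)], X)
        cfg = ClassifierConfig(rng_seed=0, min_samples=10)
        pairs = estimate_pair_effects(table, cfg)
        found = {frozenset((p.otu_i, p.otu_j)): p for p in pairs}
        key = frozenset(("O0", "O1"))
        assert key in found
        p = found[key]
        e_01 = p.e_ij if p.otu_i == "O0" else p.e_ji  # effect of O0 on O1
        e_10 = p.e_ji if p.otu_i == "O0" else p.e_ij
        assert e_01 > 0.2
        assert abs(e_10) < abs(e_01) / 2
        # few false pairs among the 14 null pairs
        assert len(pairs) <= 4

    def test_supports_within_unit_interval(self, small_sim):
        *_, table, _, _ = (None, None) + small_sim[2:]
        cfg = ClassifierConfig(rng_seed=1, n_subsamples=10)
        pairs = estimate_pair_effects(small_sim[2], cfg)
        for p in pairs:
            assert 0.0 <= p.support_ij <= 1.0
            assert 0.0 <= p.support_ji <= 1.0


def _role_net(net_type, directed, roles, abundance):
    g = nx.DiGraph() if directed else nx.Graph()
    for node, r in roles.items():
        g.add_node(node, mean_abundance=abundance[node], role=r)
    net = InteractionNetwork(type=net_type, graph=g)
    net.roles = dict(roles)
    return net


class TestHypotheses:
    def test_equal_abundance_ratios_are_one(self):
        ab = dict.fromkeys("abcdefghij", 0.1)
        nets = {
            "mutualism": _role_net("mutualism", False, {
                "a": "primary_leader", "b": "secondary_leader",
                "c": "tertiary_leader", "d": "follower"}, ab),
            "aggression": _role_net("aggression", True, {
                "e": "hawk", "f": "hawk-dove", "g": "dove"}, ab),
            "altruism": _role_net("altruism", True, {
                "h": "altruist", "i": "altruist-egoist", "j": "egoist"}, ab),
        }
        checks = check_ecological_hypotheses(nets)
        assert checks
        for c in checks:
            assert c.ratio == pytest.approx(1.0)
            assert c.passed is True

    def test_secondary_primary_ratio(self):
        ab = {"a": 1.0, "b": 0.8}
        nets = {"mutualism": _role_net("mutualism", False, {
            "a": "primary_leader", "b": "secondary_leader"}, ab)}
        checks = {c.comparison: c for c in check_ecological_hypotheses(nets)}
        c = checks["secondary/primary"]
        assert c.ratio == pytest.approx(0.8)
        assert c.passed is True  # 0.8 > 0.618

    def test_empty_class_gives_nan(self):
        nets = {"mutualism": _role_net("mutualism", False,
                                       {"a": "primary_leader"}, {"a": 1.0})}
        checks = check_ecological_hypotheses(nets)
        assert all(c.passed is None for c in checks
                   if c.comparison != "secondary/primary" or np.isnan(c.ratio))
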