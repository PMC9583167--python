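import networkx as nx
import numpy as np
import pandas as pd
import pytest

from leafnetmap.hub_heritability import (
    anova_varcomp,
    detect_hubs,
    estimate_H2,
    h2_from_varcomp,
    heritable_hubs,
    reml_varcomp,
)
from leafnetmap.interaction_networks import InteractionNetwork


def _balanced(seed, k=50, r=2, s2g=0.2, s2e=0.8):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2g), k)
    y = np.repeat(g, r) + rng.normal(0, np.sqrt(s2e), k * r)
    groups = np.repeat(np.arange(k), r)
    return y, groups


class TestVarianceComponents:
    def test_reml_equals_anova_when_balanced(self):
        for seed in range(10):
            y, groups = _balanced(seed)
            h2_a = h2_from_varcomp(*anova_varcomp(y, groups))
            h2_r = h2_from_varcomp(*reml_varcomp(y, groups))
            assert h2_r == pytest.approx(h2_a, abs=1e-6)

    def test_degenerate_h2_one(self):
        # no within-group variance at all -> H2 = 1 exactly
        y = np.repeat([1.0, 2.0, 3.0], 2)
        groups = np.repeat([0, 1, 2], 2)
        for fn in (anova_varcomp, reml_varcomp):
            assert h2_from_varcomp(*fn(y, groups)) == 1.0

    def test_degenerate_h2_zero(self):
        # identical group means, all variance within -> H2 = 0 exactly
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        groups = np.repeat([0, 1, 2], 2)
        for fn in (anova_varcomp, reml_varcomp):
            assert h2_from_varcomp(*fn(y, groups)) == 0.0

    def test_anova_negative_truncates(self):
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        groups = np.repeat([0, 1, 2, 3], 2)
        s2g, _ = anova_varcomp(y, groups)
        assert s2g == 0.0

    def test_unbalanced_anova_matches_hand_calc(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        groups = np.array([0, 0, 0, 1, 1])
        s2g, s2e = anova_varcomp(y, groups)
        # hand: means 2 and 5, grand 3.2; SSB 3*1.44+2*3.24=10.8 (k-1=1)
        # SSW = 2 + 2 = 4, msw = 4/3; n0 = (5 - 13/5)/1 = 2.4
        msw = 4 / 3
        n0 = (5 - 13 / 5) / 1
        assert s2e == pytest.approx(msw)
        assert s2g == pytest.approx((10.8 - msw) / n0)

    def test_requires_replication(self):
        with pytest.raises(ValueError):
            anova_varcomp(np.array([1.0, 2.0]), np.array([0, 1]))

    def test_reml_consistency(self):
        # pooled over many balanced datasets the REML H2 is close to truth
        h2s = [h2_from_varcomp(*reml_varcomp(*_balanced(s, k=200)))
               for s in range(20)]
        assert np.mean(h2s) == pytest.approx(0.2, abs=0.05)


class TestEstimateH2:
    def test_per_otu_per_experiment(self, small_sim):
        _, _, table, design, _ = small_sim
        res = estimate_H2(table, design)
        assert set(res.table["otu"]) == set(table.otu_ids)
        assert set(res.table["experiment"]) == {"SU_2012"}
        assert ((res.table["H2"] >= 0) & (res.table["H2"] <= 1)).all()

    def test_anova_estimator_option(self, small_sim):
        _, _, table, design, _ = small_sim
        res = estimate_H2(table, design, estimator="anova")
        assert (res.table["estimator"] == "anova").all()

    def test_no_replication_raises(self, tiny_table):
        from leafnetmap.io_formats import DesignTable

        rows = [{"sample_id": f"s{i}", "accession_id": f"acc{i}",
                 "site": "SU", "year": 2012, "replicate": 1} for i in range(6)]
        design = DesignTable(frame=pd.DataFrame(rows))
        with pytest.raises(ValueError, match="replication"):
            estimate_H2(tiny_table, design)


def _star_networks():
    g = nx.Graph()
    nodes = ["hub"] + [f"leaf{i}" for i in range(5)]
    for u in nodes:
        g.add_node(u, mean_abundance=0.1)
    for i in range(5):
        g.add_edge("hub", f"leaf{i}")
    net = InteractionNetwork(type="mutualism", graph=g, experiment=("SU", 2012))
    return {("SU", 2012): {"mutualism": net}}


class TestHubs:
    def test_star_hub_detected(self):
        report = detect_hubs(_star_networks(), quantile=0.9)
        flagged = set(report.table.loc[report.table["is_hub"], "otu"])
        assert flagged == {"hub"}
        assert report.occurrence["hub"] == 1

    def test_heritable_hubs_join(self):
        report = detect_hubs(_star_networks(), quantile=0.9)
        h2 = pd.DataFrame([
            {"otu": "hub", "experiment": "SU_2012", "sigma2_G": 0.3,
             "sigma2_E": 0.7, "H2": 0.3, "estimator": "reml"},
            {"otu": "leaf0", "experiment": "SU_2012", "sigma2_G": 0.0,
             "sigma2_E": 1.0, "H2": 0.0, "estimator": "reml"},
        ])
        from leafnetmap.hub_heritability import HeritabilityResult

        out = heritable_hubs(report, HeritabilityResult(table=h2),
                             h2_threshold=0.1)
        assert list(out["otu"]) == ["hub"]
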