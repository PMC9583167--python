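import numpy as np
import pytest

from leafnetmap.synthetic_data import (
    ConfigurationError,
    PlantedPair,
    SimulationConfig,
    classify_planted_pair,
    default_planted_pairs,
    integrate_glv,
    simulate_community,
    simulate_fecundity,
    simulate_genotypes,
)


class TestConfig:
    def test_pair_rejects_self(self):
        with pytest.raises(ConfigurationError):
            PlantedPair(2, 2, 1, 1)

    def test_pair_rejects_zero_sign(self):
        with pytest.raises(ConfigurationError):
            PlantedPair(0, 1, 1, 0)

    def test_default_pairs_three_per_pattern(self):
        pairs = default_planted_pairs(20)
        assert len(pairs) == 12
        patterns = {}
        seen = set()
        for p in pairs:
            patterns.setdefault((p.sign_i_from_j, p.sign_j_from_i), 0)
            patterns[(p.sign_i_from_j, p.sign_j_from_i)] += 1
            assert p.i != p.j
            key = frozenset((p.i, p.j))
            assert key not in seen  # no pair planted twice
            seen.add(key)
        assert set(patterns.values()) == {3}
        assert len(patterns) == 4

    def test_default_pairs_disjoint_when_room(self):
        pairs = default_planted_pairs(30)
        nodes = [x for p in pairs for x in (p.i, p.j)]
        assert len(nodes) == len(set(nodes))


class TestGenotypes:
    def test_shapes_and_values(self, small_sim):
        cfg, gen, *_ = small_sim
        assert gen.dosages.shape == (cfg.n_accessions, cfg.n_snps)
        assert np.all(np.isin(gen.dosages, (0.0, 1.0, 2.0)))
        assert np.all(gen.maf > 0) and np.all(gen.maf <= 0.5)

    def test_deterministic(self):
        cfg = SimulationConfig(n_accessions=10, n_snps=20, rng_seed=5)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        c = simulate_genotypes(SimulationConfig(n_accessions=10, n_snps=20,
                                                rng_seed=6))
        assert not np.array_equal(a.dosages, c.dosages)

    def test_structure_present(self, small_sim):
        # two Balding-Nichols subpopulations leave a visible PC1 split
        _, gen, *_ = small_sim
        X = gen.imputed()
        X = (X - X.mean(axis=0))
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        pc1 = X @ vt[0]
        half = len(pc1) // 2
        # accessions are drawn subpopulation-blockwise
        assert abs(pc1[:half].mean() - pc1[half:].mean()) > pc1.std()


class TestGlv:
    def test_diagonal_equilibrium(self):
        # with A = -I the gLV equilibrium is x* = r
        r = np.array([0.5, 1.0, 1.5])
        x = integrate_glv(np.ones(3), r, -np.eye(3))
        np.testing.assert_allclose(x, r, rtol=1e-5)

    def test_interacting_equilibrium(self):
        A = np.array([[-1.0, 0.3], [-0.2, -1.0]])
        r = np.array([1.0, 0.8])
        expected = -np.linalg.solve(A, r)
        x = integrate_glv(np.ones(2), r, A)
        np.testing.assert_allclose(x, expected, rtol=1e-5)


class TestCommunity:
    def test_closure_and_shapes(self, small_sim):
        cfg, _, table, design, _ = small_sim
        n_expected = cfg.n_accessions * cfg.n_replicates
        assert table.n_samples == n_expected
        assert table.n_otus == cfg.n_bacteria + cfg.n_fungi
        np.testing.assert_allclose(table.values.sum(axis=1), 1.0, atol=1e-9)
        assert set(design.sample_ids) == set(table.sample_ids)

    def test_deterministic(self):
        cfg = SimulationConfig(n_accessions=8, n_replicates=2, sites=("SU",),
                               years=(2012,), n_snps=10, n_bacteria=4,
                               n_fungi=4, rng_seed=11)
        gen = simulate_genotypes(cfg)
        t1, _, _ = simulate_community(cfg, gen)
        t2, _, _ = simulate_community(cfg, gen)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_truth_matches_planting(self, small_sim):
        cfg, _, _, _, truth = small_sim
        assert len(truth.pair_classes) == len(truth.pair_signs) > 0
        valid = {"mutualism", "antagonism", "aggression", "altruism"}
        assert set(truth.pair_classes.values()) <= valid
        # planted magnitudes respect the configured range
        A = truth.interaction_matrix
        np.testing.assert_allclose(np.diag(A), -cfg.self_limitation)
        for (i, j), (s_ij, s_ji) in truth.pair_signs.items():
            assert cfg.magnitude_range[0] <= abs(A[i, j]) <= cfg.magnitude_range[1]
            assert np.sign(A[i, j]) == s_ij
            assert np.sign(A[j, i]) == s_ji


class TestClassifyPlantedPair:
    def test_table(self):
        # (effect of j on i, effect of i on j); i more abundant than j
        assert classify_planted_pair((1, 1), 0.6, 0.4) == "mutualism"
        assert classify_planted_pair((-1, -1), 0.6, 0.4) == "antagonism"
        # L = i; e_{L->S} is the effect of i on j = second sign
        assert classify_planted_pair((1, -1), 0.6, 0.4) == "aggression"
        assert classify_planted_pair((-1, 1), 0.6, 0.4) == "altruism"
        # abundance order flips the orientation, not the multiset
        assert classify_planted_pair((1, -1), 0.4, 0.6) == "altruism"
        assert classify_planted_pair((-1, 1), 0.4, 0.6) == "aggression"


class TestFecundity:
    def test_direct_snp_effect_visible(self, small_sim):
        cfg, gen, table, design, truth = small_sim
        import dataclasses

        from leafnetmap.synthetic_data import FecundityModel

        cfg2 = dataclasses.replace(
            cfg, fecundity=FecundityModel(direct_snps={0: 1.0},
                                          residual_sd=0.3))
        import pandas as pd

        props = pd.DataFrame(index=table.sample_ids)
        fec, truth2 = simulate_fecundity(cfg2, gen, props, design=design,
                                         truth=truth)
        assert set(fec.index) == set(table.sample_ids)
        acc_of = design.accession_of()
        acc_idx = {a: k for k, a in enumerate(gen.accession_ids)}
        g = np.array([gen.dosages[acc_idx[acc_of[s]], 0] for s in fec.index])
        r = np.corrcoef(g, fec.to_numpy())[0, 1]
        assert r > 0.5
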