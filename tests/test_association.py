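import numpy as np
import pandas as pd
import pytest

from leafnetmap.association import (
    AssociationResult,
    average_replicates,
    build_structure,
    candidate_windows,
    genomic_inflation,
    ld_r2,
    scan,
    select_model,
    significant_snps,
    snp_h2,
)


class TestInflation:
    def test_uniform_p_gives_lambda_one(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50_000)
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_inflated_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=10_000) ** 2  # stochastically smaller
        assert genomic_inflation(p) > 1.2


class TestScan:
    def test_naive_recovers_planted_effect(self, tiny_genotypes):
        sm = build_structure(tiny_genotypes, k=2)
        X = tiny_genotypes.imputed()
        rng = np.random.default_rng(1)
        y = 1.0 * X[:, 2] + rng.normal(0, 0.05, tiny_genotypes.n_accessions)
        phen = pd.DataFrame({"trait": y}, index=tiny_genotypes.accession_ids)
        res = scan(phen, tiny_genotypes, sm, model="naive", maf_min=0.0)["trait"]
        best = res.table.loc[res.table["p"].idxmin()]
        assert best["snp_id"] == "snp2"
        assert best["beta"] == pytest.approx(1.0, abs=0.1)

    def test_maf_filter(self, tiny_genotypes):
        sm = build_structure(tiny_genotypes, k=2)
        phen = pd.DataFrame({"t": np.arange(12.0)},
                            index=tiny_genotypes.accession_ids)
        res = scan(phen, tiny_genotypes, sm, model="naive", maf_min=0.45)["t"]
        kept = set(res.table["snp_id"])
        expected = {s for s, m in zip(tiny_genotypes.snp_ids,
                                      tiny_genotypes.maf) if m > 0.45}
        assert kept == expected

    def test_bad_model_rejected(self, tiny_genotypes):
        sm = build_structure(tiny_genotypes, k=2)
        phen = pd.DataFrame({"t": np.arange(12.0)},
                            index=tiny_genotypes.accession_ids)
        with pytest.raises(ValueError, match="model"):
            scan(phen, tiny_genotypes, sm, model="emmax")


class TestModelSelection:
    def _res(self, lam):
        return AssociationResult(trait="t", model="x",
                                 table=pd.DataFrame(), lambda_gc=lam)

    def test_closest_to_one_wins(self):
        out = select_model({"naive": self._res(1.5), "Q": self._res(1.2),
                            "QK": self._res(0.97)})
        assert out == "QK"

    def test_tie_prefers_complex(self):
        out = select_model({"naive": self._res(1.1), "QK": self._res(1.1)})
        assert out == "QK"

    def test_degenerate_lambda_never_wins(self):
        out = select_model({"naive": self._res(0.0), "Q": self._res(1.3)})
        assert out == "Q"


class TestSignificance:
    def _result(self):
        table = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(5)],
            "chrom": ["1"] * 5, "pos": range(5),
            "maf": [0.5, 0.3, 0.2, 0.1, 0.05],
            "beta": [1.0, 0.5, 0.2, 0.1, 0.05], "se": [0.1] * 5,
            "stat": [10.0, 5.0, 2.0, 1.0, 0.5],
            "p": [1e-6, 0.004, 0.2, 0.5, 0.9],
        })
        return AssociationResult(trait="t", model="QK", table=table,
                                 lambda_gc=1.0)

    def test_bonferroni(self):
        out = significant_snps(self._result(), var_y=1.0, alpha=0.05)
        assert list(out["snp_id"]) == ["s0", "s1"]  # p <= 0.01

    def test_bh(self):
        out = significant_snps(self._result(), var_y=1.0, method="bh",
                               alpha=0.05)
        assert set(out["snp_id"]) == {"s0", "s1"}

    def test_h2_column(self):
        out = significant_snps(self._result(), var_y=2.0)
        expected = 2 * 0.5 * 0.5 * 1.0**2 / 2.0
        assert out.loc[0, "h2"] == pytest.approx(expected)

    def test_snp_h2_clipping(self):
        h2 = snp_h2(np.array([100.0]), np.array([0.5]), 1.0)
        assert h2[0] < 1.0


class TestWindows:
    def test_ld_r2_identical_snps(self, tiny_genotypes):
        gen = tiny_genotypes
        gen.dosages[:, 1] = gen.dosages[:, 0]
        gen.dosages[np.isnan(gen.dosages)] = 0.0
        gen2 = type(gen)(gen.accession_ids, gen.snp_ids, gen.dosages,
                         gen.chrom, gen.pos)
        assert ld_r2(gen2, "snp0", "snp1") == pytest.approx(1.0)

    def test_window_members_and_merge(self, tiny_genotypes):
        gen = tiny_genotypes
        d = np.nan_to_num(gen.dosages)
        d[:, 1] = d[:, 0]          # snp1 (pos 5000) in LD with snp0 (pos 100)
        gen2 = type(gen)(gen.accession_ids, gen.snp_ids, d, gen.chrom, gen.pos)
        wins = candidate_windows(["snp0"], gen2, w=10_000, r2_min=0.8)
        assert len(wins) == 1
        assert set(wins[0].members) >= {"snp0", "snp1"}
        assert wins[0].start == 0 and wins[0].end == 10_100
        # two overlapping leads on the same chromosome merge into one window
        wins2 = candidate_windows(["snp0", "snp1"], gen2, w=10_000)
        assert len(wins2) == 1
        # leads on different chromosomes never merge
        wins3 = candidate_windows(["snp0", "snp4"], gen2, w=10_000)
        assert len(wins3) == 2

    def test_unknown_lead(self, tiny_genotypes):
        with pytest.raises(KeyError):
            candidate_windows(["nope"], tiny_genotypes)


class TestAverageReplicates:
    def test_means_per_accession(self, tiny_design):
        phen = pd.DataFrame({"t": [1.0, 3.0, 5.0, 7.0, 9.0, 11.0]},
                            index=[f"s{i}" for i in range(6)])
        out = average_replicates(phen, tiny_design)
        assert out.loc["acc0", "t"] == pytest.approx(2.0)
        assert out.loc["acc2", "t"] == pytest.approx(10.0)


class TestStructure:
    def test_qk_shapes_and_definiteness(self, small_sim):
        _, gen, *_ = small_sim
        sm = build_structure(gen, k=3)
        n = gen.n_accessions
        assert sm.Q.shape == (n, 3)
        assert sm.K.shape == (n, n)
        np.testing.assert_allclose(sm.K, sm.K.T, atol=1e-12)
        evals = np.linalg.eigvalsh(sm.K)
        assert evals.min() > -1e-9
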