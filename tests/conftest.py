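import numpy as np
import pytest

from leafnetmap.io_formats import AbundanceTable, DesignTable, GenotypeTable
from leafnetmap.synthetic_data import (
    SimulationConfig,
    simulate_community,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_sim():
    """One small end-to-end simulation shared across tests (read-only)."""
    cfg = SimulationConfig(
        n_accessions=40, n_replicates=2, sites=("SU",), years=(2012,),
        n_snps=60, n_bacteria=5, n_fungi=5, rng_seed=7,
    )
    gen = simulate_genotypes(cfg)
    table, design, truth = simulate_community(cfg, gen)
    return cfg, gen, table, design, truth


@pytest.fixture()
def tiny_table():
    values = np.array([
        [0.50, 0.20, 0.20, 0.10],
        [0.40, 0.30, 0.20, 0.10],
        [0.45, 0.25, 0.20, 0.10],
        [0.55, 0.15, 0.20, 0.10],
        [0.50, 0.25, 0.15, 0.10],
        [0.45, 0.20, 0.25, 0.10],
    ])
    return AbundanceTable(
        sample_ids=[f"s{i}" for i in range(6)],
        otu_ids=["OTU1", "OTU2", "OTU3", "OTU4"],
        values=values,
        kingdom=["bacteria", "bacteria", "fungi", "fungi"],
    )


@pytest.fixture()
def tiny_genotypes():
    rng = np.random.default_rng(3)
    dosages = rng.choice([0.0, 1.0, 2.0], size=(12, 8), p=[0.5, 0.3, 0.2])
    dosages[0, 0] = np.nan
    return GenotypeTable(
        accession_ids=[f"acc{i:02d}" for i in range(12)],
        snp_ids=[f"snp{i}" for i in range(8)],
        dosages=dosages,
        chrom=np.array(["1"] * 4 + ["2"] * 4, dtype=object),
        pos=np.array([100, 5_000, 30_000, 60_000, 100, 8_000, 9_000, 70_000]),
    )


@pytest.fixture()
def tiny_design():
    import pandas as pd

    rows = []
    for a in range(3):
        for r in (1, 2):
            rows.append({
                "sample_id": f"s{a * 2 + r - 1}", "accession_id": f"acc{a}",
                "site": "SU", "year": 2012, "replicate": r,
            })
    return DesignTable(frame=pd.DataFrame(rows))
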