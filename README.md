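# leafnetmap

Game-theoretic interaction networks, network-property heritability and
GWAS, and mediation path analysis for leaf-microbiome abundance data.

Given OTU abundance tables from replicated plantings of host accessions,
`leafnetmap`:

1. **Infers directed pairwise microbial interactions** from abundance
   covariation (centered log-ratio transform, skewness-contrast ICA
   deconvolution, bagged over subsamples) and classifies every
   interacting pair into one of four ecological network types —
   *mutualism*, *antagonism*, *aggression*, *altruism* — based on the
   signs of the two directed effects between the more-abundant (L) and
   less-abundant (S) partner.
2. **Assigns game-theoretic roles** within each network
   (leader/follower tiers, hawk/dove, altruist/egoist) and evaluates
   abundance-ratio hypotheses against the golden threshold (0.618) and
   the Fibonacci mark (0.382).
3. **Computes six network descriptors** per network — connectivity,
   closeness, betweenness, eccentricity, eigenvector centrality and
   PageRank — and turns them into *sample-specific* phenotypes with
   LIONESS-style leave-one-out edge weights (the mean over samples of
   single-sample weights equals the population weight exactly).
4. **Estimates broad-sense heritability** (H²) of hub abundances and
   network descriptors by one-way random-effects REML/ANOVA across
   accessions.
5. **Maps network descriptors and microbial hubs to the host genome**
   with naive, Q (structure covariates), K (kinship mixed model) and QK
   association scans, genomic-inflation diagnostics and candidate-window
   reporting.
6. **Learns a Bayesian network over lead SNPs** (BIC hill-climbing with
   restarts) and **decomposes SNP–fitness correlations** into direct and
   microbe-mediated path coefficients (`P_direct + P_indirect = r_gz`).

A gLV (generalized Lotka–Volterra) simulator with planted interactions,
abundance QTLs and a fecundity model provides ground truth for
end-to-end validation.

## Test

```sh
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Quickstart

```python
from leafnetmap.synthetic_data import (
    SimulationConfig, simulate_genotypes, simulate_community)
from leafnetmap.interaction_networks import (
    ClassifierConfig, estimate_pair_effects, classify_pairs, assign_roles)
from leafnetmap.network_properties import compute_indices

cfg = SimulationConfig(
    n_accessions=60, n_replicates=2, sites=("SU",), years=(2012,),
    n_snps=50, n_bacteria=5, n_fungi=5, rng_seed=4,
)
genotypes = simulate_genotypes(cfg)
table, design, truth = simulate_community(cfg, genotypes)

ccfg = ClassifierConfig(rng_seed=4)
pairs = estimate_pair_effects(table, ccfg)
networks = classify_pairs(pairs, table, ccfg)
for net_type, net in networks.items():
    net = assign_roles(net, ccfg)
    idx = compute_indices(net)
    print(f"{net_type:<10} edges={net.graph.number_of_edges():<2} "
          f"Con={idx['Con']:.3f} C={idx['C']:.3f} P={idx['P']:.3f}")
```

Output:

```
mutualism  edges=2  Con=0.400 C=0.400 P=0.100
antagonism edges=1  Con=0.200 C=0.200 P=0.100
aggression edges=3  Con=0.600 C=0.433 P=0.100
altruism   edges=2  Con=0.400 C=0.233 P=0.100
```

## Command line

The `leafnetmap` console script orchestrates the full analysis:

```sh
# simulate a dataset, or point the config at your own tables
leafnetmap simulate --out sim/ --seed 1
# full pipeline: simulate -> networks -> properties -> H2 -> GWAS ->
# Bayesian network -> path analysis
leafnetmap run-all --out results/ --seed 1
```

`run-all` writes per-experiment GraphML networks plus `roles.tsv`,
`hypothesis_report.tsv`, `properties.tsv`, `heritability.tsv`,
`hubs.tsv`, `lambda.tsv`, `significant.tsv` and a `manifest.json` with
content checksums. Re-running against the same output directory reuses
the simulated inputs (verified by checksum) and reproduces every result
table byte-for-byte; runs are fully determined by `--seed`.

Stages can also be run individually (`leafnetmap networks`,
`heritability`, `bn`, `path`) against existing tables; see
`leafnetmap --help` and the YAML config accepted by `--config`.

## Package layout

| module                 | contents                                               |
| ---------------------- | ------------------------------------------------------ |
| `io_formats`           | abundance/genotype/design/phenotype tables, VCF, GraphML |
| `synthetic_data`       | gLV simulator, planted pairs, genotypes, fecundity     |
| `interaction_networks` | ICA effect estimation, pair classification, roles, hypothesis checks |
| `network_properties`   | six indices, LIONESS sample-specific networks, property tables |
| `hub_heritability`     | hub detection, ANOVA/REML variance components, H²      |
| `association`          | structure/kinship, naive/Q/K/QK scans, inflation, windows |
| `qtl_bayes_net`        | BIC-scored DAG learning over lead SNPs                 |
| `path_analysis`        | direct/indirect path decomposition                     |
| `pipeline` / `cli`     | orchestration, manifest, console script                |

See `docs/methods.md` for the statistical methods and their rationale.
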