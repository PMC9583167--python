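# Methods

This document records the statistical models behind each module, the
design decisions in the interaction-effect estimator, and known
limitations.

## Synthetic test bed

Communities follow a generalized Lotka–Volterra (gLV) model near
equilibrium. With growth-rate vector `r` and interaction matrix `A`
(off-diagonal `a_ij` = effect of OTU *j* on OTU *i*, diagonal fixed at
`-self_limitation`, default −1), the deterministic equilibrium is
`x* = -A⁻¹ r`. Each sample draws its own growth rates:

- a per-OTU **lognormal environmental fluctuation** with log-sd
  `env_sd = 0.4` (mean-one, i.e. log-mean `-env_sd²/2`),
- additive **site/year offsets** (sd 0.15) shared within an experiment,
- per-accession genetic effects from planted **abundance QTLs**
  (additive SNP dosage scaled to a target h²),

after which multiplicative **lognormal measurement noise** (log-sd 0.1)
is applied and rows are closed to relative abundances.

`env_sd = 0.4` is deliberately large relative to the measurement noise:
the ICA-based estimator identifies directed effects from *non-Gaussian*
(skewed) abundance covariation, and the lognormal growth-rate
fluctuation is the skewed source it exploits. Much smaller values leave
too little identifiable signal (the mixture becomes near-Gaussian);
much larger values push samples far from the linearized regime. 0.4
gives equilibria that remain positive for the planted magnitude range
(|a_ij| ∈ [0.3, 0.5]) while the skewness-based unmixing stays well
conditioned.

Planted pairs cover all four sign patterns — (+,+), (−,−), (+,−),
(−,+) — in equal numbers; ground truth records the interaction matrix,
each pair's expected network type (via the same L/S decision table the
classifier uses, evaluated at the simulated mean abundances), the
equilibrium, QTLs, and the fecundity model (direct SNP effects plus
network-descriptor mediators).

## Interaction inference and classification

1. **clr transform.** Relative abundances are centered log-ratio
   transformed per sample (pseudo-count = half the smallest positive
   value). clr is invariant to per-sample rescaling, so compositional
   closure does not masquerade as interaction.
2. **Deconvolution.** For the linearized gLV model around equilibrium,
   abundance deviations mix independent, *skewed* (lognormal) growth
   fluctuations through `(-A)⁻¹`. FastICA with a **skewness contrast**
   (`g(u) = u²`) recovers the unmixing matrix up to scale and
   permutation; rows are aligned and signed by their dominant diagonal
   and normalized so that off-diagonal entries estimate signed directed
   effects. The skew contrast is essential: the default kurtosis-based
   contrasts are nearly blind to the lognormal sources at these noise
   levels.
3. **Bagging.** The deconvolution is repeated on `B = 100` random
   subsamples of 70% of samples. The point estimate is the element-wise
   mean; averaging over subsample-perturbed fits cancels both FastICA
   convergence noise and sampling noise (repeated full-data restarts do
   not, because deflation FastICA converges to near-identical solutions
   from any start). The **support** of an effect is the frequency with
   which its sign is consistent across runs (magnitudes below the zero
   band 0.05 count as sign zero).
4. **Detection.** An effect is detected when it is outside the zero
   band and either (a) its row-robust z-score (median/MAD per row)
   exceeds 2 with support ≥ 0.7, or (b) its support is ≥ 0.95.
   A sub-threshold reverse effect is **rescued** (support ≥ 0.5) when
   its partner direction was detected, so that bidirectional pairs are
   not truncated to unidirectional ones by one marginal direction.
5. **Classification.** For each retained pair let L be the
   more-abundant partner and S the less-abundant one (lexicographic
   tie-break, flagged). With effect signs taken as 0 inside the zero
   band, the decision table on (sign e_{L→S}, sign e_{S→L}) is:
   (+,+) mutualism; (−,−) antagonism; (−, 0/+) aggression with L the
   hawk; (0, −) aggression with S the hawk; (+, 0/−) altruism with L
   the altruist; (0, +) altruism with S the altruist; (0,0) no edge.
   The four networks share the full node set and have mutually
   exclusive edge sets.
6. **Roles and hypothesis checks.** Within each network, abundance
   tiers define roles (primary/secondary/tertiary leaders and
   followers; hawk/hawk-dove/dove; altruist/altruist-egoist/egoist;
   larger/smaller antagonist). Role-class mean-abundance ratios are
   compared against the golden threshold 0.618 (cooperation) and the
   Fibonacci mark 0.382 (altruism); an equal-abundance community gives
   every ratio exactly 1.

## Network descriptors

Six indices summarize each network (means over nodes): connectivity
(2|E|/|V|), closeness, betweenness (Brandes, normalized), hop
eccentricity, eigenvector centrality, and PageRank (damping 0.85).
Distances use 1/|w| on the symmetrized (max-|w|) graph; zero-weight
edges are dropped. Eigenvector centrality uses a dense symmetric
eigensolve rather than power iteration so results are deterministic to
machine precision on graphs with small spectral gaps.

**Sample-specific networks.** Population topology is frozen; only edge
weights vary by sample. With frozen-population-standardized clr scores
`z`, the population weight of edge (i, j) is `t = mean_s z_i(s) z_j(s)`
and the single-sample weight is the leave-one-out linear interpolation
`w_s = n·t − (n−1)·t₍₋s₎ = z_i(s)·z_j(s)`, so the sample mean of `w_s`
reproduces the population weight *exactly* (machine precision). The
per-sample index values of each network type are the quantitative
phenotypes passed to heritability estimation and GWAS.

## Heritability

Broad-sense heritability uses the one-way random-effects model
`y = mu + g_accession + e`. Variance components come from REML
(restricted likelihood profiled down to the log variance ratio,
handling unbalanced designs) or method-of-moments ANOVA; in balanced
designs the two coincide. Estimates are truncated to the parameter
space: a non-positive genetic component gives H² = 0, a zero residual
component with varying accession means gives H² = 1, and a fully
constant trait gives (0, 0) → H² = 0.

## Association scans

Population structure is summarized by the top-k left singular vectors
of the centered genotype matrix (Q) and VanRaden kinship (K). Four
models are available: `naive` (no correction), `Q` (fixed covariates),
`K` (mixed model via eigendecomposition of K, variance components by
REML, single-pass Frisch–Waugh Wald tests) and `QK` (both). Genomic
inflation λ is the median association χ² divided by 0.4549. Candidate
windows extend ± a basepair window around lead SNPs and absorb SNPs
with r² above a threshold, merging overlapping same-chromosome windows.

With two planted subpopulations at divergence (F_ST) 0.2, a
structure-confounded null trait inflates the naive scan to λ ≈ 20–25
while the QK scan stays calibrated (λ ≈ 1, empirical type-I error at
α = 0.05 ≈ 0.048).

## QTL Bayesian network

Lead SNPs are joined in a directed acyclic graph learned by BIC
hill-climbing (add/delete/reverse moves, cycle checks, random
restarts; the first restart starts from the empty graph). The Gaussian
BIC is decomposable: per node, a least-squares regression on its
parents contributes `−n/2·(log(2π·RSS/n)+1) − (|parents|+2)/2·log n`.
A discrete (multinomial) scorer is available for raw dosages. On
4-node problems the hill-climber attains the exhaustive 543-DAG
optimum in ≥ 90% of trials.

## Path analysis

For SNP g, mediator y (a network descriptor) and fitness z, the
single-mediator decomposition fixes the mediator-to-fitness path at
`r_yz`, giving `P_indirect = r_gy · r_yz` and
`P_direct = r_gz − P_indirect`, so `r_gz = P_direct + P_indirect`
holds as an exact identity (machine precision) for every non-degenerate
triple; constant inputs are rejected. Mediators are treated one at a
time by default; a joint multi-mediator variant (mediator paths from a
multiple regression of z on all mediators) is available behind a flag.

## Pipeline

`run-all` executes simulate → networks → properties → fecundity →
hubs/H² → GWAS → Bayesian network → path analysis. Every table carries
a header comment with the package version and seed; a `manifest.json`
records content checksums so re-runs reuse verified inputs and
reproduce result tables byte-for-byte. All stage seeds derive from the
single run seed and stay below 2³¹.

## Limitations

- The effect estimator assumes near-equilibrium linearized gLV dynamics
  with skewed (lognormal) growth fluctuations; with near-Gaussian noise
  or strongly non-linear dynamics, identifiability degrades and support
  values drop.
- Directed effects are identified up to the estimator's zero band
  (0.05); effects genuinely smaller than the band are classified as
  absent, which shifts weak bidirectional pairs toward unidirectional
  types (aggression/altruism).
- Pair classification depends on the L/S abundance ordering; partners
  with nearly equal abundance (lexicographic tie-break) can flip type
  between hawk- and dove-sided labels under resampling.
- The kinship mixed model treats each trait independently with a single
  genetic variance component; no leave-one-chromosome-out correction is
  applied, so a very large single-SNP effect is partially absorbed by K.
- The BN scorer assumes linear-Gaussian local models; the discrete
  scorer assumes multinomial nodes. Mixed continuous/discrete networks
  are not supported.
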