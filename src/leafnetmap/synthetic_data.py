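"""Ground-truth test bed: genotypes, a host-modulated gLV community, and a
fecundity trait with direct and network-mediated SNP effects.

The community follows generalized Lotka-Volterra dynamics

    dx_i/dt = x_i (r_i + sum_j a_ij x_j),

with strictly negative self-limitation a_ii and planted off-diagonal signs
encoding the four interaction types.  Every sample (accession x site x
year x replicate) gets its own growth-rate vector: a baseline per OTU,
additive site/year offsets, additive causal-SNP shifts, and multiplicative
lognormal environmental fluctuation (skewed, independent per OTU — the
property that makes the interaction matrix identifiable downstream).
Interaction QTLs scale selected a_ij by (1 + gamma * dosage).  Each sample
is integrated to near-equilibrium with fixed-step RK4, measurement noise is
applied multiplicatively (lognormal), and abundances are closed to relative
abundance.

All randomness flows from ``rng_seed``; identical configurations reproduce
bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AbundanceTable, DesignTable, GenotypeTable

logger = logging.getLogger(__name__)

SIGN_PATTERNS = {(1, 1), (-1, -1), (1, -1), (-1, 1)}


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PlantedPair:
    """One planted interaction: signs are (effect of j on i, effect of i on j)."""

    i: int
    j: int
    sign_i_from_j: int
    sign_j_from_i: int
    magnitude_i_from_j: float | None = None  # drawn from magnitude_range if None
    magnitude_j_from_i: float | None = None

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ConfigurationError("planted pair must join two distinct OTUs")
        if (self.sign_i_from_j, self.sign_j_from_i) not in SIGN_PATTERNS:
            raise ConfigurationError("sign pattern must be one of (+,+), (-,-), (+,-), (-,+)")


@dataclass
class AbundanceQtl:
    """A SNP shifting the growth rate of one OTU; ``h2`` is the target
    broad-sense heritability of that OTU's abundance (the additive shift per
    dosage is calibrated against the environmental growth-rate variance)."""

    snp: int
    otu: int
    h2: float


@dataclass
class InteractionQtl:
    """A SNP scaling one interaction coefficient a_ij by (1 + gamma * dosage)."""

    snp: int
    i: int
    j: int
    gamma: float


@dataclass
class FecundityModel:
    """z = sum beta_g * g + sum beta_y * y + eps.

    ``direct_snps`` maps SNP index -> beta; ``mediators`` maps a network
    property column name (e.g. ``mutualism.B``) -> beta on the standardized
    mediator; ``residual_sd`` is the noise standard deviation.
    """

    direct_snps: dict[int, float] = field(default_factory=dict)
    mediators: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 1.0


@dataclass
class SimulationConfig:
    """Study-design and model parameters for the synthetic test bed.

    Defaults mirror the field design the pipeline targets: 198 accessions,
    2 replicates, 4 sites x 2 years, two subpopulations.  OTU counts and
    SNP counts default to desk scale.
    """

    n_accessions: int = 198
    n_replicates: int = 2
    sites: tuple[str, ...] = ("SU", "SR", "NM", "NA")
    years: tuple[int, ...] = (2012, 2013)
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpopulations: int = 2
    divergence: float = 0.2
    n_bacteria: int = 20
    n_fungi: int = 20
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    magnitude_range: tuple[float, float] = (0.3, 0.5)
    self_limitation: float = 1.0
    growth_rate_range: tuple[float, float] = (0.8, 1.5)
    env_sd: float = 0.4            # lognormal sd of growth-rate fluctuation
    site_year_sd: float = 0.15     # additive site/year growth-rate offsets
    noise_sd: float = 0.1          # lognormal measurement noise
    abundance_qtls: list[AbundanceQtl] = field(default_factory=list)
    interaction_qtls: list[InteractionQtl] = field(default_factory=list)
    fecundity: FecundityModel = field(default_factory=FecundityModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 <= lo < hi <= 0.5):
            raise ConfigurationError("maf_range must be within [0, 0.5]")
        if self.self_limitation <= 0:
            raise ConfigurationError("self-limitation must be strictly positive "
                                     "(the gLV diagonal is its negative)")

    @property
    def n_otus(self) -> int:
        return self.n_bacteria + self.n_fungi

    def otu_ids(self) -> list[str]:
        width = len(str(self.n_otus))
        return [f"OTU{str(k + 1).zfill(width)}" for k in range(self.n_otus)]

    def kingdoms(self) -> list[str]:
        return ["bacteria"] * self.n_bacteria + ["fungi"] * self.n_fungi


def default_planted_pairs(
    n_otus: int, n_per_type: int = 3, rng: np.random.Generator | None = None
) -> list[PlantedPair]:
    """A standard planting: ``n_per_type`` pairs of each sign pattern laid
    out over distinct OTUs first, reusing OTUs only when needed."""
    patterns = (
        [(1, 1)] * n_per_type + [(-1, -1)] * n_per_type
        + [(1, -1)] * n_per_type + [(-1, 1)] * n_per_type
    )
    n_pairs = len(patterns)
    slots: list[tuple[int, int]] = []
    k = 0
    while len(slots) < n_pairs and k + 1 < n_otus:
        slots.append((k, k + 1))
        k += 2
    extra = 0
    while len(slots) < n_pairs:
        a = (2 * extra) % n_otus
        b = (2 * extra + 2) % n_otus
        if a != b:
            slots.append((a, b))
        extra += 1
    return [PlantedPair(i, j, s1, s2) for (i, j), (s1, s2) in zip(slots, patterns)]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the generator knows that inference has to rediscover."""

    interaction_matrix: np.ndarray
    pair_classes: dict[tuple[int, int], str]
    pair_signs: dict[tuple[int, int], tuple[int, int]]
    equilibrium: np.ndarray
    abundance_qtls: list[dict]
    interaction_qtls: list[dict]
    fecundity_direct: dict[str, float] = field(default_factory=dict)
    fecundity_mediators: dict[str, float] = field(default_factory=dict)
    fecundity_residual_sd: float = 0.0

    def to_json(self, path) -> None:
        payload = {
            "interaction_matrix": self.interaction_matrix.tolist(),
            "pair_classes": {f"{i},{j}": c for (i, j), c in self.pair_classes.items()},
            "pair_signs": {f"{i},{j}": list(s) for (i, j), s in self.pair_signs.items()},
            "equilibrium": self.equilibrium.tolist(),
            "abundance_qtls": self.abundance_qtls,
            "interaction_qtls": self.interaction_qtls,
            "fecundity_direct": self.fecundity_direct,
            "fecundity_mediators": self.fecundity_mediators,
            "fecundity_residual_sd": self.fecundity_residual_sd,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        parse = lambda k: tuple(int(x) for x in k.split(","))
        return cls(
            interaction_matrix=np.array(d["interaction_matrix"]),
            pair_classes={parse(k): v for k, v in d["pair_classes"].items()},
            pair_signs={parse(k): tuple(v) for k, v in d["pair_signs"].items()},
            equilibrium=np.array(d["equilibrium"]),
            abundance_qtls=d["abundance_qtls"],
            interaction_qtls=d["interaction_qtls"],
            fecundity_direct=d["fecundity_direct"],
            fecundity_mediators=d["fecundity_mediators"],
            fecundity_residual_sd=d["fecundity_residual_sd"],
        )


def classify_planted_pair(
    signs: tuple[int, int], mean_i: float, mean_j: float
) -> str:
    """Map a planted sign pattern onto the network type the classifier
    should find, given the partners' mean abundances.

    signs = (effect of j on i, effect of i on j).  L is the more abundant
    partner; the decision table mirrors the classifier's.
    """
    s_ij, s_ji = signs  # s_ij: effect of j on i
    if mean_i >= mean_j:
        e_LS, e_SL = s_ji, s_ij  # effect of L(=i) on S(=j), and back
    else:
        e_LS, e_SL = s_ij, s_ji
    if e_LS == 1 and e_SL == 1:
        return "mutualism"
    if e_LS == -1 and e_SL == -1:
        return "antagonism"
    if e_LS == -1:
        return "aggression"
    if e_LS == 1:
        return "altruism"
    if e_SL == -1:
        return "aggression"
    if e_SL == 1:
        return "altruism"
    return "none"


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeTable:
    """Balding-Nichols genotypes with subpopulation structure.

    Ancestral minor-allele frequencies are uniform on ``maf_range``; each
    subpopulation draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F)
    with divergence F; accessions are assigned to subpopulations in blocks.
    SNP columns whose realized MAF falls below the lower bound are redrawn
    (bounded rounds), then dropped if still failing.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 11]))
    n, m = cfg.n_accessions, cfg.n_snps
    subpop = np.repeat(np.arange(cfg.n_subpopulations),
                       int(np.ceil(n / cfg.n_subpopulations)))[:n]
    F = cfg.divergence
    lo, hi = cfg.maf_range

    def draw(m_draw: int) -> np.ndarray:
        p_anc = rng.uniform(lo, hi, m_draw)
        if cfg.n_subpopulations <= 1 or F <= 0:
            p_sub = np.tile(p_anc, (cfg.n_subpopulations or 1, 1))
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            p_sub = rng.beta(np.tile(a, (cfg.n_subpopulations, 1)),
                             np.tile(b, (cfg.n_subpopulations, 1)))
        return rng.binomial(2, p_sub[subpop, :], size=(n, m_draw)).astype(float)

    X = draw(m)
    for _ in range(50):
        freq = X.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        bad = maf < lo
        if not bad.any():
            break
        X[:, bad] = draw(int(bad.sum()))
    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= lo
    if not keep.all():
        logger.warning("dropping %d SNPs below the MAF bound after redraws",
                       int((~keep).sum()))
    X = X[:, keep]
    m_eff = X.shape[1]
    chroms = np.array([str(1 + (j * 5) // m_eff) for j in range(m_eff)], dtype=object)
    pos = np.zeros(m_eff, dtype=np.int64)
    counter: dict[str, int] = {}
    for j, c in enumerate(chroms):
        counter[c] = counter.get(c, 0) + 1
        pos[j] = counter[c] * 250
    ids = [f"snp_{chroms[j]}_{pos[j]}" for j in range(m_eff)]
    acc_ids = [f"acc{str(i + 1).zfill(3)}" for i in range(n)]
    table = GenotypeTable(acc_ids, ids, X, chroms, pos)
    table.subpopulation = subpop  # type: ignore[attr-defined]
    return table


# ---------------------------------------------------------------------------
# community
# ---------------------------------------------------------------------------


def _build_interaction_matrix(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw A and r until the interior fixed point is positive and stable.

    Returns (A, r0, x_star).  A[i, j] is the per-capita effect of OTU j on
    OTU i; the diagonal is -self_limitation.
    """
    n = cfg.n_otus
    pairs = cfg.planted_pairs or default_planted_pairs(n)
    lo, hi = cfg.magnitude_range
    last_bad: list[tuple[int, int]] = []
    for _ in range(100):
        A = -cfg.self_limitation * np.eye(n)
        for p in pairs:
            m1 = p.magnitude_i_from_j if p.magnitude_i_from_j is not None else rng.uniform(lo, hi)
            m2 = p.magnitude_j_from_i if p.magnitude_j_from_i is not None else rng.uniform(lo, hi)
            A[p.i, p.j] = p.sign_i_from_j * m1
            A[p.j, p.i] = p.sign_j_from_i * m2
        r0 = rng.uniform(*cfg.growth_rate_range, n)
        x_star = np.linalg.solve(-A, r0)
        J = x_star[:, None] * A
        stable = np.all(np.linalg.eigvals(J).real < 0)
        if np.all(x_star > 0) and stable:
            return A, r0, x_star
        bad_idx = np.where(x_star <= 0)[0]
        last_bad = [(p.i, p.j) for p in pairs
                    if p.i in bad_idx or p.j in bad_idx] or [(p.i, p.j) for p in pairs]
    raise ConfigurationError(
        "could not find a stable positive equilibrium; offending pairs: "
        f"{last_bad}"
    )


def integrate_glv(
    X0: np.ndarray,
    R: np.ndarray,
    A: np.ndarray,
    modulation: list[tuple[int, int, np.ndarray]] | None = None,
    dt: float | None = None,
    t_max: float = 200.0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Fixed-step RK4 integration of the gLV system for a batch of samples.

    ``X0``: samples x n initial abundances; ``R``: samples x n growth
    rates; ``modulation``: per-sample multiplicative tweaks of single
    entries, as (i, j, per-sample delta) with effective a_ij[s] =
    A[i, j] * (1 + delta[s]).  The step defaults to 0.2 divided by a
    Lipschitz-style bound.  Integration stops when max |dx/dt| < ``tol``
    or at ``t_max``.  Abundances are floored at zero (extinction boundary).
    """
    X = np.asarray(X0, dtype=float).copy()
    mods = modulation or []

    def field_(Xc: np.ndarray) -> np.ndarray:
        growth = R + Xc @ A.T
        for i, j, delta in mods:
            growth[:, i] += delta * A[i, j] * Xc[:, j]
        return Xc * growth

    if dt is None:
        bound = np.abs(R).max() + np.abs(A).sum(axis=1).max() * max(X.max(), 1.0)
        dt = 0.2 / max(bound, 1e-6)
    n_steps = int(np.ceil(t_max / dt))
    check_every = max(n_steps // 200, 1)
    for step in range(n_steps):
        k1 = field_(X)
        k2 = field_(np.maximum(X + 0.5 * dt * k1, 0.0))
        k3 = field_(np.maximum(X + 0.5 * dt * k2, 0.0))
        k4 = field_(np.maximum(X + dt * k3, 0.0))
        X = np.maximum(X + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        if step % check_every == 0 and np.abs(field_(X)).max() < tol:
            break
    return X


def simulate_community(
    cfg: SimulationConfig, genotypes: GenotypeTable
) -> tuple[AbundanceTable, DesignTable, GroundTruth]:
    """Simulate the replicated multi-site/multi-year community.

    For every (accession, site, year, replicate) the growth-rate vector is

        r = (r0 + site_year_offset + snp_shift) * exp(env_noise)

    with env_noise ~ N(-env_sd^2/2, env_sd^2) i.i.d. per OTU and sample
    (multiplicative lognormal, mean one).  Interaction QTLs scale their
    a_ij per accession.  Equilibria are integrated with RK4, measurement
    noise (lognormal, sd ``noise_sd``) is applied, and rows are closed to
    relative abundance.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 23]))
    A, r0, x_star = _build_interaction_matrix(cfg, rng)
    n_otus = cfg.n_otus
    pairs = cfg.planted_pairs or default_planted_pairs(n_otus)

    acc_ids = genotypes.accession_ids
    n_acc = len(acc_ids)
    dosages = genotypes.imputed()

    # per-OTU genetic shift on r from abundance QTLs, calibrated to the H2 target
    snp_shift = np.zeros((n_acc, n_otus))
    aqtl_records = []
    env_var_r = (r0 * cfg.env_sd) ** 2  # approx variance of r from env noise
    for q in cfg.abundance_qtls:
        d = dosages[:, q.snp]
        p = d.mean() / 2.0
        het = max(2 * p * (1 - p), 1e-6)
        beta = float(np.sqrt(q.h2 / max(1 - q.h2, 1e-6) * env_var_r[q.otu] / het))
        snp_shift[:, q.otu] += beta * d
        aqtl_records.append({"snp": genotypes.snp_ids[q.snp], "otu": int(q.otu),
                             "h2": q.h2, "beta": beta})

    iqtl_records = []
    modulation_spec = []
    for q in cfg.interaction_qtls:
        d = dosages[:, q.snp]
        modulation_spec.append((q.i, q.j, q.gamma, d))
        iqtl_records.append({"snp": genotypes.snp_ids[q.snp], "i": q.i, "j": q.j,
                             "gamma": q.gamma})

    # design rows
    design_rows = []
    for site in cfg.sites:
        for year in cfg.years:
            for ai, acc in enumerate(acc_ids):
                for rep in range(1, cfg.n_replicates + 1):
                    design_rows.append((f"{site}_{year}_{acc}_r{rep}", acc, site,
                                        int(year), rep, ai))
    n_samples = len(design_rows)

    site_year_offset = {
        (site, int(year)): rng.normal(0.0, cfg.site_year_sd, n_otus)
        for site in cfg.sites for year in cfg.years
    }

    R = np.empty((n_samples, n_otus))
    acc_index = np.empty(n_samples, dtype=int)
    for s, (_, acc, site, year, rep, ai) in enumerate(design_rows):
        acc_index[s] = ai
        base = r0 + site_year_offset[(site, year)] + snp_shift[ai]
        env = rng.normal(-cfg.env_sd**2 / 2.0, cfg.env_sd, n_otus)
        R[s] = np.maximum(base, 0.05) * np.exp(env)

    X0 = np.maximum(
        x_star[None, :] * np.exp(rng.uniform(-0.2, 0.2, (n_samples, n_otus))), 1e-6
    )
    modulation = [(i, j, gamma * d[acc_index]) for i, j, gamma, d in modulation_spec]
    X = integrate_glv(X0, R, A, modulation)

    noise = np.exp(rng.normal(0.0, cfg.noise_sd, X.shape))
    Xobs = X * noise
    totals = Xobs.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    P = Xobs / totals

    sample_ids = [row[0] for row in design_rows]
    table = AbundanceTable(sample_ids, cfg.otu_ids(), P, cfg.kingdoms())
    design = DesignTable(pd.DataFrame(
        [row[:5] for row in design_rows],
        columns=["sample_id", "accession_id", "site", "year", "replicate"],
    ))

    # label pair types by the realized mean relative abundance -- the same
    # quantity a classifier sees -- so hawk/dove and altruist/egoist
    # orientations are defined by who is actually more abundant in the data
    mean_x = P.mean(axis=0)
    pair_classes = {}
    pair_signs = {}
    for p in pairs:
        signs = (p.sign_i_from_j, p.sign_j_from_i)
        pair_signs[(p.i, p.j)] = signs
        pair_classes[(p.i, p.j)] = classify_planted_pair(signs, mean_x[p.i], mean_x[p.j])
    truth = GroundTruth(
        interaction_matrix=A, pair_classes=pair_classes, pair_signs=pair_signs,
        equilibrium=x_star, abundance_qtls=aqtl_records, interaction_qtls=iqtl_records,
    )
    return table, design, truth


# ---------------------------------------------------------------------------
# fecundity
# ---------------------------------------------------------------------------


def simulate_fecundity(
    cfg: SimulationConfig,
    genotypes: GenotypeTable,
    properties,
    design: DesignTable | None = None,
    truth: GroundTruth | None = None,
) -> tuple[pd.Series, GroundTruth]:
    """Fecundity per sample: direct SNP effects plus mediated network-
    property effects plus Gaussian noise.

    ``properties`` is a NetworkPropertyTable (standardized mediators used)
    or a DataFrame indexed by sample id.  Returns the phenotype and the
    ground truth updated with standardized effect sizes.
    """
    fm = cfg.fecundity
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 37]))
    med = properties.standardized if hasattr(properties, "standardized") else properties
    sample_ids = list(med.index)
    for m in fm.mediators:
        if m not in med.columns:
            raise ConfigurationError(f"mediator {m!r} absent from property table")
    if design is not None:
        acc_of = design.accession_of()
    else:
        acc_of = {s: s for s in sample_ids}
    acc_pos = {a: i for i, a in enumerate(genotypes.accession_ids)}
    dosages = genotypes.imputed()

    z = np.zeros(len(sample_ids))
    direct_record: dict[str, float] = {}
    for snp_idx, beta in fm.direct_snps.items():
        d = np.array([dosages[acc_pos[acc_of[s]], snp_idx] for s in sample_ids])
        z += beta * d
        direct_record[genotypes.snp_ids[snp_idx]] = float(beta)
    for mname, beta in fm.mediators.items():
        y = med[mname].to_numpy(dtype=float)
        z += beta * np.nan_to_num(y)
    z += rng.normal(0.0, fm.residual_sd, len(sample_ids))
    series = pd.Series(z, index=sample_ids, name="fecundity")

    if truth is None:
        truth = GroundTruth(
            interaction_matrix=np.zeros((0, 0)), pair_classes={}, pair_signs={},
            equilibrium=np.zeros(0), abundance_qtls=[], interaction_qtls=[],
        )
    truth.fecundity_direct = direct_record
    truth.fecundity_mediators = dict(fm.mediators)
    truth.fecundity_residual_sd = fm.residual_sd
    return series, truth
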