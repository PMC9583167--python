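"""Inference and game-theoretic classification of pairwise microbial
interactions from relative-abundance snapshots.

The community is modelled as a generalized Lotka-Volterra (gLV) system
near equilibrium: sample-to-sample variation in abundances reflects
environmental fluctuations of the per-taxon growth rates propagated through
the interaction matrix A (x* = -A^{-1} r).  Because the equilibrium map is
linear in the fluctuating growth rates, and those fluctuations are
independent and skewed, the signed, *directed* interaction coefficients are
identifiable from snapshot data by blind source separation: an ICA unmixing
row for the source driving taxon i is proportional to row i of A (up to a
constant offset induced by compositional closure, removed here by a robust
sparse gauge).  Plain covariance or regression methods only see the
symmetric part a_ij + a_ji and cannot distinguish one-sided exploitation
from no interaction, which is why the estimator works on the unmixing side.

Each retained pair is then classified into one of the four ecological
interaction types of behavioural-ecology game theory:

* mutualism  (+,+)  — both partners promote each other;
* antagonism (-,-)  — both partners inhibit each other;
* aggression        — the more abundant partner (hawk) suppresses the less
  abundant one (dove) and is not harmed in return;
* altruism          — one partner benefits the other at its own expense
  (altruist -> egoist).

Post-hoc hypothesis checks compare role-class abundance ratios against the
golden threshold 0.618 and the Fibonacci retracement mark 0.382.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import AbundanceTable

logger = logging.getLogger(__name__)

NETWORK_TYPES = ("mutualism", "antagonism", "aggression", "altruism")
DIRECTED_TYPES = ("aggression", "altruism")


# ---------------------------------------------------------------------------
# configuration and result types
# ---------------------------------------------------------------------------


@dataclass
class ClassifierConfig:
    """Settings for pair-effect estimation and classification.

    golden_threshold / fibonacci_threshold are the abundance-ratio constants
    of the ecological hypotheses; ``effect_zero_band`` is the band on
    standardized effects treated as "no effect".  Detection of a directed
    effect requires row-outlyingness (``outlier_z``) together with
    subsample-stability ``min_support``, or stability alone at
    ``strong_support``; once one direction of a pair is detected, the
    reverse direction is admitted at the weaker ``rescue_support``.
    """

    golden_threshold: float = 0.618
    fibonacci_threshold: float = 0.382
    effect_zero_band: float = 0.05
    min_support: float = 0.7
    strong_support: float = 0.95
    rescue_support: float = 0.5
    n_subsamples: int = 100
    subsample_fraction: float = 0.7
    outlier_z: float = 2.0
    min_prevalence: float = 0.2
    min_samples: int = 30
    hub_degree_sd: float = 1.0
    enforce_ratio_gates: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fibonacci_threshold < self.golden_threshold < 1.0):
            raise ValueError("need 0 < fibonacci_threshold < golden_threshold < 1")


@dataclass
class PairEffects:
    """Directed standardized effects for one unordered OTU pair.

    ``e_ij`` is the effect of ``otu_i`` on ``otu_j`` (sign: promote/inhibit,
    magnitude relative to self-limitation), ``e_ji`` the reverse;
    ``support_*`` are stability-selection frequencies in [0, 1].
    """

    otu_i: str
    otu_j: str
    e_ij: float
    e_ji: float
    support_ij: float
    support_ji: float

    def __post_init__(self) -> None:
        if self.otu_i == self.otu_j:
            raise ValueError("pair must join two distinct OTUs")
        if not (np.isfinite(self.e_ij) and np.isfinite(self.e_ji)):
            raise ValueError("effects must be finite")


@dataclass
class InteractionNetwork:
    """One typed interaction network over OTUs.

    ``graph`` is undirected for mutualism/antagonism (both effect values
    stored on the edge) and directed for aggression (hawk -> dove) and
    altruism (altruist -> egoist).  Node attributes: ``mean_abundance`` and,
    after :func:`assign_roles`, ``role``.
    """

    type: str
    graph: nx.Graph
    experiment: tuple[str, int] | None = None
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in NETWORK_TYPES:
            raise ValueError(f"unknown network type {self.type!r}")
        want_directed = self.type in DIRECTED_TYPES
        if self.graph.is_directed() != want_directed:
            raise ValueError(f"{self.type} network must be "
                             f"{'directed' if want_directed else 'undirected'}")


# ---------------------------------------------------------------------------
# clr transform
# ---------------------------------------------------------------------------


def clr_transform(values: np.ndarray, pseudo_count: float | None = None) -> np.ndarray:
    """Centered log-ratio transform with a pseudo-count of half the smallest
    nonzero relative abundance (standard compositional practice)."""
    values = np.asarray(values, dtype=float)
    if pseudo_count is None:
        nz = values[values > 0]
        pseudo_count = 0.5 * nz.min() if nz.size else 0.5
    logv = np.log(values + pseudo_count)
    return logv - logv.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# effect estimation (ICA deconvolution under stability selection)
# ---------------------------------------------------------------------------


def _preprocess(table: AbundanceTable, cfg: ClassifierConfig) -> tuple[np.ndarray, list[str]]:
    """Prevalence filter, constant-column and duplicate-column handling."""
    vals = table.values
    keep: list[int] = []
    n = table.n_samples
    for j, otu in enumerate(table.otu_ids):
        col = vals[:, j]
        prev = float((col > 0).mean())
        if prev < cfg.min_prevalence:
            logger.warning("dropping OTU %s: prevalence %.2f < %.2f",
                           otu, prev, cfg.min_prevalence)
            continue
        if np.all(col == col[0]):
            logger.warning("dropping constant OTU column %s", otu)
            continue
        keep.append(j)
    # perfectly collinear pairs: drop the lexicographically larger id
    dropped: set[int] = set()
    for ai in range(len(keep)):
        for bi in range(ai + 1, len(keep)):
            a, b = keep[ai], keep[bi]
            if a in dropped or b in dropped:
                continue
            ca, cb = vals[:, a], vals[:, b]
            r = np.corrcoef(ca, cb)[0, 1]
            if abs(r) > 1 - 1e-12:
                loser = max(a, b, key=lambda k: table.otu_ids[k])
                dropped.add(loser)
                logger.warning("dropping OTU %s: collinear with %s",
                               table.otu_ids[loser],
                               table.otu_ids[a if loser == b else b])
    keep = [j for j in keep if j not in dropped]
    return vals[:, keep], [table.otu_ids[j] for j in keep]


def _skew_contrast(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FastICA contrast g(u) = u^2 (with derivative 2u): maximizes skewness.

    The latent sources here are lognormal growth-rate fluctuations, whose
    dominant non-Gaussian signature is skewness; the symmetric kurtosis
    contrasts (logcosh, exp) are blind to it and mix skewed sources far
    more often.
    """
    return u**2, (2 * u).mean(axis=-1)


def _ica_unmix(Y: np.ndarray, seed: int) -> np.ndarray:
    """One FastICA fit; returns row-normalized unmixing matrix."""
    from sklearn.decomposition import FastICA

    n = Y.shape[1]
    ica = FastICA(n_components=n - 1, random_state=seed, max_iter=2000,
                  tol=1e-5, algorithm="deflation", fun=_skew_contrast)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica.fit(Y)
    W = ica.components_
    return W / np.linalg.norm(W, axis=1, keepdims=True)


def _deconvolve(Y: np.ndarray, seed: int) -> np.ndarray:
    """Estimate the interaction matrix (diagonal gauge -1) from centered
    relative abundances.

    Components are matched to taxa by their dominant loading (the gLV
    matrix is diagonally dominant, so each source's unmixing row peaks on
    its own taxon); the compositional-closure gauge freedom (+c per row) is
    removed by subtracting the off-diagonal median (sparse rows have median
    zero); rows are scaled so the self-effect is -1.  Unmatched taxa give
    NaN rows.
    """
    n = Y.shape[1]
    W = _ica_unmix(Y, seed)
    ri, ci = linear_sum_assignment(-np.abs(W))
    A = np.full((n, n), np.nan)
    for k, i in zip(ri, ci):
        row = W[k].copy()
        row -= np.median(np.delete(row, i))
        if row[i] != 0:
            A[i] = -row / row[i]
            A[i, i] = -1.0
    return A


def estimate_pair_effects(
    table: AbundanceTable,
    cfg: ClassifierConfig | None = None,
) -> list[PairEffects]:
    """Estimate signed directed effects for every OTU pair.

    The point estimate is the elementwise mean over ``n_subsamples``
    deconvolutions of random subsamples (bagging: averaging over
    subsample-perturbed ICA fits cancels both FastICA convergence noise and
    sampling noise; repeated full-data restarts do not, because deflation
    FastICA converges to near-identical solutions from any start).  Support
    is the sign-consistent detection frequency across the same runs.  An
    effect is retained when it exceeds the zero band and either (a) it is a
    robust outlier within its row (|z| > ``outlier_z`` on median/MAD scale —
    rows of a sparse interaction matrix are their own null) with support >=
    ``min_support``, or (b) its support alone reaches ``strong_support``.
    Because most interactions are reciprocal, a retained direction also
    unlocks its reverse at the weaker ``rescue_support`` (nulls rarely show
    even moderate evidence in both directions at once, so this raises
    recall at almost no false-pair cost).  Non-retained directions are
    reported as exact zeros; pairs with no retained direction are omitted.
    """
    cfg = cfg or ClassifierConfig()
    if table.n_samples < cfg.min_samples:
        raise ValueError(
            f"need at least {cfg.min_samples} samples, got {table.n_samples}"
        )
    if not table.is_normalized():
        table = table.normalize()
    vals, otus = _preprocess(table, cfg)
    n = len(otus)
    if n < 2:
        return []
    Y = vals - vals.mean(axis=0)
    rng = np.random.default_rng(cfg.rng_seed)

    runs = np.full((cfg.n_subsamples, n, n), np.nan)
    size = max(int(table.n_samples * cfg.subsample_fraction), n + 1)
    for b in range(cfg.n_subsamples):
        idx = rng.choice(table.n_samples, size, replace=False)
        runs[b] = _deconvolve(Y[idx], seed=int(rng.integers(2**31)))

    eps = cfg.effect_zero_band
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = np.nanmean(runs, axis=0)
        pos = np.nanmean(runs > eps, axis=0)
        neg = np.nanmean(runs < -eps, axis=0)
    support = np.maximum(pos, neg)
    point = np.where(np.isfinite(point), point, 0.0)

    z = np.zeros((n, n))
    for i in range(n):
        off = np.delete(point[i], i)
        med = np.median(off)
        mad = 1.4826 * np.median(np.abs(off - med)) + 1e-12
        z[i] = np.abs(point[i] - med) / mad
    nonzero = np.abs(point) > eps
    strict = nonzero & (
        ((z > cfg.outlier_z) & (support >= cfg.min_support))
        | (support >= cfg.strong_support)
    )
    rescue = nonzero & (support >= cfg.rescue_support)
    retained = strict | (rescue & strict.T)
    retained[np.arange(n), np.arange(n)] = False

    pairs: list[PairEffects] = []
    for a in range(n):
        for b in range(a + 1, n):
            # point[i, j] = effect of taxon j on taxon i
            e_ab = float(point[b, a]) if retained[b, a] else 0.0  # a -> b
            e_ba = float(point[a, b]) if retained[a, b] else 0.0  # b -> a
            if e_ab == 0.0 and e_ba == 0.0:
                continue
            pairs.append(
                PairEffects(
                    otu_i=otus[a], otu_j=otus[b],
                    e_ij=e_ab, e_ji=e_ba,
                    support_ij=float(support[b, a]),
                    support_ji=float(support[a, b]),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_pair(
    p: PairEffects,
    abundances: dict[str, float],
    cfg: ClassifierConfig | None = None,
) -> tuple[str, tuple[str, str]] | None:
    """Classify one retained pair into a network type.

    Let L be the partner with higher mean abundance and S the lower one
    (ties broken lexicographically, flagged).  With signs of the two
    directed effects taken as zero inside the ``effect_zero_band``, the
    decision table on (sign e_{L->S}, sign e_{S->L}) is:

    ========  ========  =======================================
    L -> S    S -> L    type (orientation)
    ========  ========  =======================================
    +         +         mutualism
    -         -         antagonism
    -         + or 0    aggression (hawk = L, dove = S)
    0         -         aggression (hawk = S, dove = L)
    +         - or 0    altruism (altruist = L, egoist = S)
    0         +         altruism (altruist = S, egoist = L)
    0         0         none
    ========  ========  =======================================

    Returns (type, (source, target)) where the orientation is hawk->dove or
    altruist->egoist for the directed types and the (L, S) order otherwise.
    """
    cfg = cfg or ClassifierConfig()
    a_i, a_j = abundances[p.otu_i], abundances[p.otu_j]
    if a_i == a_j:
        logger.warning("equal mean abundances for %s/%s; tie broken lexicographically",
                       p.otu_i, p.otu_j)
        L, S = sorted((p.otu_i, p.otu_j))
    else:
        L, S = (p.otu_i, p.otu_j) if a_i > a_j else (p.otu_j, p.otu_i)
    e_LS = p.e_ij if L == p.otu_i else p.e_ji  # effect of L on S
    e_SL = p.e_ji if L == p.otu_i else p.e_ij

    eps = cfg.effect_zero_band
    sL = 0 if abs(e_LS) < eps else (1 if e_LS > 0 else -1)
    sS = 0 if abs(e_SL) < eps else (1 if e_SL > 0 else -1)

    if sL == 1 and sS == 1:
        return "mutualism", (L, S)
    if sL == -1 and sS == -1:
        return "antagonism", (L, S)
    if sL == -1:  # sS in (0, 1): L suppresses S unharmed
        return "aggression", (L, S)
    if sL == 1:  # sS in (0, -1): L benefits S at its own expense
        return "altruism", (L, S)
    if sL == 0 and sS == -1:  # S suppresses L
        return "aggression", (S, L)
    if sL == 0 and sS == 1:  # S benefits L: benefit flows from the donor
        return "altruism", (S, L)
    return None


def classify_pairs(
    pairs: list[PairEffects],
    table: AbundanceTable,
    cfg: ClassifierConfig | None = None,
    experiment: tuple[str, int] | None = None,
) -> dict[str, InteractionNetwork]:
    """Assign every retained pair to exactly one of the four networks.

    All four networks share the full node set (with mean relative abundance
    as a node attribute); each pair contributes one edge to exactly one
    network, so the edge sets are mutually exclusive.
    """
    cfg = cfg or ClassifierConfig()
    means = dict(zip(table.otu_ids, table.values.mean(axis=0)))
    graphs: dict[str, nx.Graph] = {
        t: (nx.DiGraph() if t in DIRECTED_TYPES else nx.Graph()) for t in NETWORK_TYPES
    }
    for t, g in graphs.items():
        for otu, m in means.items():
            g.add_node(otu, mean_abundance=float(m))
    for p in pairs:
        verdict = classify_pair(p, means, cfg)
        if verdict is None:
            continue
        net_type, (src, dst) = verdict
        e_st = p.e_ij if src == p.otu_i else p.e_ji
        e_ts = p.e_ji if src == p.otu_i else p.e_ij
        s_st = p.support_ij if src == p.otu_i else p.support_ji
        s_ts = p.support_ji if src == p.otu_i else p.support_ij
        graphs[net_type].add_edge(src, dst, e_st=float(e_st), e_ts=float(e_ts),
                                  support_st=float(s_st), support_ts=float(s_ts))
    return {
        t: InteractionNetwork(type=t, graph=g, experiment=experiment)
        for t, g in graphs.items()
    }


# ---------------------------------------------------------------------------
# roles
# ---------------------------------------------------------------------------


def assign_roles(net: InteractionNetwork, cfg: ClassifierConfig | None = None) -> InteractionNetwork:
    """Label each node with its game-theoretic role.

    mutualism: primary leaders are nodes whose degree is much more than
    average (mean + ``hub_degree_sd`` standard deviations); secondary
    leaders are non-primaries adjacent to a primary; tertiary leaders reach
    every primary only through secondaries; followers touch tertiaries but
    no secondary; the rest are "other".

    aggression: hawk (out-edges only), dove (in-edges only), hawk-dove
    (both).  altruism: altruist / egoist / both, analogously.  antagonism:
    per-edge larger/smaller antagonist by mean abundance; the node label is
    "larger_antagonist" if the node is the larger partner on every edge,
    "smaller_antagonist" if always smaller, else "mixed_antagonist".
    """
    cfg = cfg or ClassifierConfig()
    g = net.graph
    roles: dict[str, str] = {}
    active = [u for u in g.nodes() if g.degree(u) > 0]
    if not active:
        net.roles = {}
        return net

    if net.type == "mutualism":
        degs = np.array([g.degree(u) for u in active], dtype=float)
        cutoff = degs.mean() + cfg.hub_degree_sd * degs.std()
        primary = {u for u in active if g.degree(u) > cutoff}
        secondary = {
            u for u in active
            if u not in primary and any(v in primary for v in g.neighbors(u))
        }
        tertiary = set()
        for u in active:
            if u in primary or u in secondary:
                continue
            ok = False
            for p in primary:
                if not nx.has_path(g, u, p):
                    continue
                # every shortest path to any primary passes through a secondary
                paths = nx.all_shortest_paths(g, u, p)
                if all(any(w in secondary for w in path[1:-1]) for path in paths):
                    ok = True
                    break
            if ok:
                tertiary.add(u)
        follower = {
            u for u in active
            if u not in primary | secondary | tertiary
            and any(v in tertiary for v in g.neighbors(u))
            and not any(v in secondary for v in g.neighbors(u))
        }
        for u in active:
            roles[u] = (
                "primary_leader" if u in primary
                else "secondary_leader" if u in secondary
                else "tertiary_leader" if u in tertiary
                else "follower" if u in follower
                else "other"
            )
    elif net.type in ("aggression", "altruism"):
        src_role, dst_role = (
            ("hawk", "dove") if net.type == "aggression" else ("altruist", "egoist")
        )
        for u in active:
            has_out = g.out_degree(u) > 0
            has_in = g.in_degree(u) > 0
            roles[u] = (
                f"{src_role}-{dst_role}" if has_out and has_in
                else src_role if has_out
                else dst_role
            )
    elif net.type == "antagonism":
        for u in active:
            larger = smaller = 0
            au = g.nodes[u].get("mean_abundance", 0.0)
            for v in g.neighbors(u):
                av = g.nodes[v].get("mean_abundance", 0.0)
                if au >= av:
                    larger += 1
                else:
                    smaller += 1
            roles[u] = (
                "larger_antagonist" if smaller == 0
                else "smaller_antagonist" if larger == 0
                else "mixed_antagonist"
            )
        for u, v in g.edges():
            au = g.nodes[u].get("mean_abundance", 0.0)
            av = g.nodes[v].get("mean_abundance", 0.0)
            big, small = (u, v) if au >= av else (v, u)
            g.edges[u, v]["larger_antagonist"] = big
            g.edges[u, v]["smaller_antagonist"] = small

    nx.set_node_attributes(g, roles, "role")
    net.roles = roles
    return net


# ---------------------------------------------------------------------------
# hypothesis checks
# ---------------------------------------------------------------------------


@dataclass
class HypothesisCheck:
    network_type: str
    comparison: str
    ratio: float
    threshold: float
    passed: bool | None


def _class_mean(net: InteractionNetwork, role_filter) -> float:
    vals = [
        net.graph.nodes[u].get("mean_abundance", np.nan)
        for u, r in net.roles.items()
        if role_filter(r)
    ]
    return float(np.mean(vals)) if vals else np.nan


def check_ecological_hypotheses(
    nets: dict[str, InteractionNetwork],
    cfg: ClassifierConfig | None = None,
) -> list[HypothesisCheck]:
    """Golden-threshold / Fibonacci-mark checks on role-class abundances.

    mutualism: secondary/primary, tertiary/secondary and follower/secondary
    mean-abundance ratios must exceed the golden threshold 0.618
    (cooperation between a larger and a smaller partner).  aggression:
    (hawk-dove)/hawk (upper tier) and dove/(hawk-dove) (lower tier) ratios
    are reported against 0.618 (exploitation happens below it).  altruism:
    egoist/altruist ratios at both tiers must exceed the Fibonacci mark
    0.382.  antagonism: smaller/larger antagonist ratio is reported
    (surrender-resistance).  Empty role classes give NaN ratios with
    ``passed=None``.
    """
    cfg = cfg or ClassifierConfig()
    checks: list[HypothesisCheck] = []

    def add(net_type: str, name: str, num: float, den: float, threshold: float,
            direction: str = "above") -> None:
        ratio = num / den if den and np.isfinite(den) and np.isfinite(num) else np.nan
        passed: bool | None
        if np.isnan(ratio):
            passed = None
        elif direction == "above":
            passed = bool(ratio > threshold)
        else:
            passed = bool(ratio < threshold)
        checks.append(HypothesisCheck(net_type, name, float(ratio), threshold, passed))

    mu = nets.get("mutualism")
    if mu is not None:
        pri = _class_mean(mu, lambda r: r == "primary_leader")
        sec = _class_mean(mu, lambda r: r == "secondary_leader")
        ter = _class_mean(mu, lambda r: r == "tertiary_leader")
        fol = _class_mean(mu, lambda r: r == "follower")
        add("mutualism", "secondary/primary", sec, pri, cfg.golden_threshold)
        add("mutualism", "tertiary/secondary", ter, sec, cfg.golden_threshold)
        add("mutualism", "follower/secondary", fol, sec, cfg.golden_threshold)

    ag = nets.get("aggression")
    if ag is not None:
        hawk = _class_mean(ag, lambda r: r == "hawk")
        hd = _class_mean(ag, lambda r: r == "hawk-dove")
        dove = _class_mean(ag, lambda r: r == "dove")
        add("aggression", "hawkdove/hawk", hd, hawk, cfg.golden_threshold)
        add("aggression", "dove/hawkdove", dove, hd, cfg.golden_threshold)

    al = nets.get("altruism")
    if al is not None:
        altru = _class_mean(al, lambda r: r == "altruist")
        both = _class_mean(al, lambda r: r == "altruist-egoist")
        ego = _class_mean(al, lambda r: r == "egoist")
        add("altruism", "altruistegoist/altruist", both, altru, cfg.fibonacci_threshold)
        add("altruism", "egoist/altruistegoist", ego, both, cfg.fibonacci_threshold)

    an = nets.get("antagonism")
    if an is not None:
        small_vals, large_vals = [], []
        for u, v, attrs in an.graph.edges(data=True):
            big = attrs.get("larger_antagonist")
            if big is None:
                continue
            small = v if big == u else u
            large_vals.append(an.graph.nodes[big]["mean_abundance"])
            small_vals.append(an.graph.nodes[small]["mean_abundance"])
        num = float(np.mean(small_vals)) if small_vals else np.nan
        den = float(np.mean(large_vals)) if large_vals else np.nan
        add("antagonism", "smaller/larger", num, den, cfg.golden_threshold)

    return checks
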