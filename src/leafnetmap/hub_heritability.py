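"""Hub detection and broad-sense heritability of OTU abundances.

Hub OTUs are nodes that pass joint quantile cutoffs on degree AND closeness
centrality within each (experiment, network type).  Broad-sense
heritability H2 of each OTU's (clr-transformed) abundance is estimated from
the replicated design with a one-way random-effects model

    y_{accession, rep} = mu + u_accession + eps,
    u ~ (0, sigma2_G),  eps ~ (0, sigma2_E),

fitted by REML (profile likelihood in the variance ratio, valid for
unbalanced data).  The closed-form ANOVA method-of-moments estimator
sigma2_G = (MS_between - MS_within) / r_bar serves as the balanced-case
oracle and agrees with REML to numerical precision when the design is
balanced.  H2 = sigma2_G / (sigma2_G + sigma2_E), clipped to [0, 1];
heritability is computed within a year and site (experiment group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io_formats import AbundanceTable, DesignTable
from .interaction_networks import InteractionNetwork, clr_transform

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------


@dataclass
class HubReport:
    """Per-(experiment, network type, OTU) hub flags and the cutoffs used."""

    table: pd.DataFrame          # experiment, network_type, otu, degree, closeness, is_hub
    cutoffs: pd.DataFrame        # experiment, network_type, degree_cutoff, closeness_cutoff
    occurrence: pd.Series        # per-OTU count of experiments where it is a hub in any network


def _closeness(graph) -> dict[str, float]:
    import networkx as nx

    und = graph.to_undirected() if graph.is_directed() else graph
    out = {}
    for u in und.nodes():
        dist = nx.single_source_shortest_path_length(und, u)
        others = {v: d for v, d in dist.items() if v != u}
        out[u] = len(others) / sum(others.values()) if others else 0.0
    return out


def detect_hubs(
    networks: dict[tuple[str, int], dict[str, InteractionNetwork]],
    quantile: float = 0.90,
) -> HubReport:
    """Flag hub OTUs: degree AND closeness both at or above the q-th
    quantile within each (experiment, network type).

    Returns per-network flags plus a cross-experiment occurrence count (the
    number of experiments in which an OTU is a hub in at least one network
    type).
    """
    rows = []
    cut_rows = []
    for exp_key, nets in networks.items():
        exp = f"{exp_key[0]}_{exp_key[1]}"
        for t, net in nets.items():
            g = net.graph
            active = [u for u in g.nodes() if g.degree(u) > 0]
            if len(active) < 2:
                continue
            deg = {u: g.degree(u) for u in active}
            clo = _closeness(g.subgraph(active))
            dcut = float(np.quantile(list(deg.values()), quantile))
            ccut = float(np.quantile(list(clo.values()), quantile))
            cut_rows.append({"experiment": exp, "network_type": t,
                             "degree_cutoff": dcut, "closeness_cutoff": ccut})
            for u in active:
                rows.append({
                    "experiment": exp, "network_type": t, "otu": u,
                    "degree": deg[u], "closeness": clo[u],
                    "is_hub": bool(deg[u] >= dcut and clo[u] >= ccut),
                })
    table = pd.DataFrame(rows, columns=["experiment", "network_type", "otu",
                                        "degree", "closeness", "is_hub"])
    cutoffs = pd.DataFrame(cut_rows, columns=["experiment", "network_type",
                                              "degree_cutoff", "closeness_cutoff"])
    if len(table):
        hub_any = table[table["is_hub"]].groupby(["otu", "experiment"]).size().reset_index()
        occurrence = hub_any.groupby("otu").size()
    else:
        occurrence = pd.Series(dtype=int)
    occurrence.name = "n_experiments"
    return HubReport(table=table, cutoffs=cutoffs, occurrence=occurrence)


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


@dataclass
class HeritabilityResult:
    """Variance components and H2 per (OTU, experiment group)."""

    table: pd.DataFrame  # otu, experiment, sigma2_G, sigma2_E, H2, estimator


def anova_varcomp(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA method-of-moments variance components.

    sigma2_G = (MS_between - MS_within) / r_bar with r_bar the effective
    replicate number n_0 = (N - sum n_i^2 / N) / (k - 1); exact for balanced
    designs.  Negative estimates truncate to zero.
    """
    labels, inv = np.unique(groups, return_inverse=True)
    k = len(labels)
    N = len(y)
    if k < 2 or N <= k:
        raise ValueError("H2 unidentifiable: need >= 2 groups with replication")
    gmeans = np.bincount(inv, weights=y) / np.bincount(inv)
    ssb = float(np.sum(np.bincount(inv) * (gmeans - y.mean()) ** 2))
    ssw = float(np.sum((y - gmeans[inv]) ** 2))
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n_i = np.bincount(inv)
    n0 = (N - np.sum(n_i**2) / N) / (k - 1)
    s2g = max((msb - msw) / n0, 0.0)
    return s2g, msw


def reml_varcomp(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """REML variance components for the one-way random-effects model.

    Profiles the residual variance out of the restricted likelihood and
    optimizes over the log variance ratio theta = sigma2_G / sigma2_E;
    handles unbalanced group sizes.
    """
    labels, inv = np.unique(groups, return_inverse=True)
    k = len(labels)
    N = len(y)
    if k < 2 or N <= k:
        raise ValueError("H2 unidentifiable: need >= 2 groups with replication")
    n_i = np.bincount(inv).astype(float)
    sums = np.bincount(inv, weights=y)
    gmeans = sums / n_i
    ssw = float(np.sum((y - gmeans[inv]) ** 2))
    if ssw == 0.0:
        if np.ptp(gmeans) == 0.0:
            # fully constant trait: both components are zero (rounding in
            # var() would otherwise turn an H2 of 0 into 1)
            return 0.0, 0.0
        # replicates agree exactly: the ratio is at the +inf boundary
        return float(np.var(gmeans, ddof=1)), 0.0

    def neg_restricted_loglik(log_theta: float) -> float:
        th = np.exp(log_theta)
        d = 1.0 + th * n_i
        # GLS mean: mu = sum(w_i * ybar_i)/sum(w_i), w_i = n_i/d_i
        w = n_i / d
        mu = float(np.sum(w * (sums / n_i)) / np.sum(w))
        resid = y - mu
        rg = np.bincount(inv, weights=resid)
        # quadratic form resid' V^{-1} resid with V = I + th Z Z'
        quad = float(np.sum(resid**2) - th * np.sum(rg**2 / d))
        logdet = float(np.sum(np.log(d)))
        log_xvx = float(np.log(np.sum(w)))
        s2e = quad / (N - 1)
        return 0.5 * ((N - 1) * np.log(s2e) + logdet + log_xvx)

    res = minimize_scalar(neg_restricted_loglik, bounds=(-12.0, 12.0),
                          method="bounded", options={"xatol": 1e-10})
    th = float(np.exp(res.x))
    # recompute profiled residual variance at the optimum
    d = 1.0 + th * n_i
    w = n_i / d
    mu = float(np.sum(w * (sums / n_i)) / np.sum(w))
    resid = y - mu
    rg = np.bincount(inv, weights=resid)
    s2e = float((np.sum(resid**2) - th * np.sum(rg**2 / d)) / (N - 1))
    s2g = th * s2e
    # boundary handling: if the ratio collapsed to the lower bound, call it 0
    if th < 1e-5:
        s2g = 0.0
        s2e = float(np.sum((y - y.mean()) ** 2) / (N - 1))
    return s2g, s2e


def h2_from_varcomp(s2g: float, s2e: float) -> float:
    if s2g <= 0:
        return 0.0
    if s2e <= 0:
        return 1.0
    return float(np.clip(s2g / (s2g + s2e), 0.0, 1.0))


def estimate_H2(
    table: AbundanceTable,
    design: DesignTable,
    transform: str = "clr",
    estimator: str = "reml",
) -> HeritabilityResult:
    """Broad-sense heritability of each OTU within each (site, year) group.

    ``transform``: ``clr`` (default; relative abundances violate the
    homoscedastic model) or ``raw``.  ``estimator``: ``reml`` or ``anova``.
    Raises if no experiment group has accession replication.
    """
    if transform == "clr":
        Y = clr_transform(table.values)
    elif transform == "raw":
        Y = table.values
    else:
        raise ValueError(f"unknown transform {transform!r}")
    est_fn = {"reml": reml_varcomp, "anova": anova_varcomp}[estimator]
    acc_of = design.accession_of()
    rows = []
    any_replication = False
    sample_pos = {s: i for i, s in enumerate(table.sample_ids)}
    for site, year in design.experiments():
        samples = [s for s in design.samples_in(site, year) if s in sample_pos]
        if not samples:
            continue
        groups = np.array([acc_of[s] for s in samples])
        _, counts = np.unique(groups, return_counts=True)
        if len(counts) < 2 or counts.max() < 2:
            logger.warning("experiment (%s, %s): no replication; skipped", site, year)
            continue
        any_replication = True
        idx = [sample_pos[s] for s in samples]
        for j, otu in enumerate(table.otu_ids):
            y = Y[idx, j]
            if np.allclose(y, y[0]):
                s2g, s2e = 0.0, 0.0
                h2 = 0.0
            else:
                s2g, s2e = est_fn(y, groups)
                h2 = h2_from_varcomp(s2g, s2e)
            rows.append({"otu": otu, "experiment": f"{site}_{year}",
                         "sigma2_G": s2g, "sigma2_E": s2e, "H2": h2,
                         "estimator": estimator})
    if not any_replication:
        raise ValueError("H2 unidentifiable: no experiment group has replication")
    return HeritabilityResult(table=pd.DataFrame(rows))


def heritable_hubs(
    hubs: HubReport,
    h2: HeritabilityResult,
    h2_threshold: float = 0.10,
) -> pd.DataFrame:
    """Hub OTUs whose abundance is heritable (H2 above threshold, default
    0.10) in the experiment where they are hubs."""
    hub_rows = hubs.table[hubs.table["is_hub"]][["experiment", "otu"]].drop_duplicates()
    merged = hub_rows.merge(h2.table, on=["experiment", "otu"], how="left")
    return merged[merged["H2"] > h2_threshold].reset_index(drop=True)
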