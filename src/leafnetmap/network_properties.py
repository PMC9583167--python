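"""Sample-specific networks and their emergent-property indices.

Each inferred interaction network is reduced, per sample, to six indices
that serve as quantitative phenotypes for association mapping:

* ``Con`` — connectivity, the mean degree 2|E|/|V|;
* ``C``   — mean closeness centrality (inverse-weight distances);
* ``B``   — mean normalized shortest-path betweenness;
* ``E``   — mean eccentricity in hops within each connected component;
* ``G``   — mean leading-eigenvector centrality (L2-normalized);
* ``P``   — mean PageRank (damping 0.85; per-node scores sum to one).

Single-sample networks keep the population topology fixed and perturb only
the edge weights, using the linear leave-one-out interpolation
w_s = n*w_all - (n-1)*w_(-s) on a per-sample co-variation statistic.  With
the statistic used here (mean product of population-standardized clr
abundances) the interpolation is exact: the single-sample weight reduces to
the sample's own cross product and the sample mean of the single-sample
weights equals the population weight identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import AbundanceTable, DesignTable
from .interaction_networks import (
    NETWORK_TYPES,
    InteractionNetwork,
    clr_transform,
)

logger = logging.getLogger(__name__)

INDEX_NAMES = ("Con", "C", "B", "E", "G", "P")


# ---------------------------------------------------------------------------
# single-sample extraction
# ---------------------------------------------------------------------------


def _edge_stat_matrix(table: AbundanceTable) -> tuple[np.ndarray, list[str]]:
    """Population-standardized clr values (samples x OTUs).

    Standardization (center/scale) is frozen at the population level so the
    per-edge statistic t(i,j) = mean_s z_i(s) z_j(s) is a plain average over
    samples, which makes the leave-one-out interpolation below exact.
    Constant OTUs get all-zero z columns (their edges carry weight 0).
    """
    Z = clr_transform(table.values)
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    return (Z - mu) / sd, list(table.otu_ids)


def sample_specific_network(
    nets: dict[str, InteractionNetwork] | InteractionNetwork,
    table: AbundanceTable,
    sample_id: str,
) -> dict[str, InteractionNetwork] | InteractionNetwork:
    """Extract the single-sample network(s) for ``sample_id``.

    Topology and interaction type are frozen to the population network; only
    edge weights vary.  The population weight of edge (i, j) is
    t = mean_s z_i z_j on frozen-standardized clr abundances, and the
    single-sample weight is the leave-one-out linear interpolation
    w_s = n*t_all - (n-1)*t_(-s), which simplifies to z_i(s) * z_j(s).
    The signed weight is stored as ``weight``; downstream indices use its
    magnitude.
    """
    single = isinstance(nets, InteractionNetwork)
    netmap = {"_": nets} if single else nets
    if sample_id not in table.sample_ids:
        raise KeyError(f"sample {sample_id!r} not in abundance table")
    Z, otus = _edge_stat_matrix(table)
    s = table.sample_ids.index(sample_id)
    col = {o: k for k, o in enumerate(otus)}
    out: dict[str, InteractionNetwork] = {}
    for key, net in netmap.items():
        g = net.graph.copy()
        for u, v in g.edges():
            w = float(Z[s, col[u]] * Z[s, col[v]])
            g.edges[u, v]["weight"] = w
        out[key] = InteractionNetwork(type=net.type, graph=g, experiment=net.experiment)
    return out["_"] if single else out


def population_edge_weights(net: InteractionNetwork, table: AbundanceTable) -> dict:
    """Population-level edge statistic t(i,j) (the mean over samples of the
    single-sample weights)."""
    Z, otus = _edge_stat_matrix(table)
    col = {o: k for k, o in enumerate(otus)}
    return {
        (u, v): float((Z[:, col[u]] * Z[:, col[v]]).mean())
        for u, v in net.graph.edges()
    }


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------


def _distance_graph(g: nx.Graph) -> nx.Graph:
    """Undirected view with 1/|weight| edge lengths (strong interaction =
    short ecological distance).  Zero-weight edges get infinite length and
    are dropped from shortest-path computations."""
    und = nx.Graph()
    und.add_nodes_from(g.nodes())
    for u, v, attrs in g.edges(data=True):
        w = abs(attrs.get("weight", 1.0))
        if w <= 0:
            continue
        if und.has_edge(u, v):  # two directed arcs between the same pair
            w = max(w, und.edges[u, v]["weight"])
        und.add_edge(u, v, weight=w, length=1.0 / w)
    return und


def compute_indices(net: InteractionNetwork | nx.Graph) -> dict[str, float]:
    """Compute the six network indices on one (weighted) network.

    Directed networks are symmetrized for the distance-based indices
    (closeness, betweenness, eccentricity); PageRank keeps native direction.
    Empty or edgeless graphs return all-zero indices with ``empty=True``.
    """
    g = net.graph if isinstance(net, InteractionNetwork) else net
    n = g.number_of_nodes()
    result = dict.fromkeys(INDEX_NAMES, 0.0)
    result["empty"] = False
    if n == 0 or g.number_of_edges() == 0:
        result["empty"] = True
        return result

    und = _distance_graph(g)
    result["Con"] = 2.0 * g.number_of_edges() / n

    # closeness: reachable_others / sum of inverse-weight distances
    closeness = []
    ecc = []
    for u in und.nodes():
        dist = nx.single_source_dijkstra_path_length(und, u, weight="length")
        others = {v: d for v, d in dist.items() if v != u}
        closeness.append(len(others) / sum(others.values()) if others else 0.0)
        hop = nx.single_source_shortest_path_length(und, u)
        ecc.append(max(hop.values()))
    result["C"] = float(np.mean(closeness))
    result["E"] = float(np.mean(ecc))

    btw = nx.betweenness_centrality(und, weight="length", normalized=True)
    result["B"] = float(np.mean(list(btw.values())))

    # leading eigenvector centrality on the undirected weighted graph; a
    # dense symmetric solve is deterministic and avoids the accuracy limits
    # of power iteration when the spectral gap is small
    W = nx.to_numpy_array(und, nodelist=list(und.nodes()), weight="weight")
    _, evecs = np.linalg.eigh(W)
    vec = np.abs(evecs[:, -1])
    norm = np.linalg.norm(vec)
    result["G"] = float((vec / norm).mean()) if norm > 0 else 0.0

    pr_graph = g if g.is_directed() else und
    # PageRank needs non-negative weights
    prg = pr_graph.copy()
    for u, v in prg.edges():
        prg.edges[u, v]["absw"] = abs(prg.edges[u, v].get("weight", 1.0))
    pr = nx.pagerank(prg, alpha=0.85, tol=1e-12, max_iter=1000, weight="absw")
    result["P"] = float(np.mean(list(pr.values())))
    return result


# ---------------------------------------------------------------------------
# property table
# ---------------------------------------------------------------------------


@dataclass
class NetworkPropertyTable:
    """Samples x (network type, index) phenotype matrix.

    ``values`` holds raw index values; ``standardized`` the per-experiment
    z-scored version used for mapping.  Column names are ``type.index``
    (e.g. ``mutualism.Con``).
    """

    values: pd.DataFrame
    standardized: pd.DataFrame
    experiment_of: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def columns(self) -> list[str]:
        return list(self.values.columns)


def build_property_table(
    networks: dict[tuple[str, int], dict[str, InteractionNetwork]],
    table: AbundanceTable,
    design: DesignTable,
) -> NetworkPropertyTable:
    """Per-sample six-index phenotypes for every network type.

    ``networks`` maps experiment keys (site, year) to the four population
    networks inferred on that experiment.  Samples whose experiment has no
    retained edges in a given network type get NaN for that type's columns
    (flagged, excluded downstream).  Columns are standardized within each
    experiment; raw values are retained alongside.
    """
    cols = [f"{t}.{ix}" for t in NETWORK_TYPES for ix in INDEX_NAMES]
    rows: dict[str, dict[str, float]] = {}
    exp_of: dict[str, str] = {}
    for (site, year), nets in networks.items():
        samples = design.samples_in(site, year)
        samples = [s for s in samples if s in set(table.sample_ids)]
        if not samples:
            continue
        sub = table.subset_samples(samples)
        Z, otus = _edge_stat_matrix(sub)
        col_of = {o: k for k, o in enumerate(otus)}
        for t in NETWORK_TYPES:
            net = nets.get(t)
            if net is None:
                continue
            edges = list(net.graph.edges())
            if not edges:
                for s in samples:
                    row = rows.setdefault(s, {})
                    for ix in INDEX_NAMES:
                        row[f"{t}.{ix}"] = np.nan
                logger.warning("experiment (%s, %s): %s network empty; NaN phenotypes",
                               site, year, t)
                continue
            base = net.graph
            for si, s in enumerate(samples):
                g = base.copy()
                for u, v in edges:
                    g.edges[u, v]["weight"] = float(Z[si, col_of[u]] * Z[si, col_of[v]])
                idx = compute_indices(InteractionNetwork(type=t, graph=g,
                                                         experiment=(site, year)))
                row = rows.setdefault(s, {})
                for ix in INDEX_NAMES:
                    row[f"{t}.{ix}"] = idx[ix]
        for s in samples:
            exp_of[s] = f"{site}_{year}"
    values = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)
    values.index.name = "sample_id"
    exp = pd.Series(exp_of, name="experiment").reindex(values.index)

    std = values.copy()
    for _, idx in std.groupby(exp).groups.items():
        block = std.loc[idx]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        # treat numerically constant columns (sd at rounding-noise level) as
        # constant, otherwise the z-scores amplify 1-ulp jitter into garbage
        constant = sd <= 1e-9 * mu.abs().clip(lower=1.0)
        if constant.any():
            # expected for topology-only indices: single-sample networks
            # share the frozen population topology
            logger.info("constant phenotype columns within an experiment: %s",
                           list(block.columns[constant]))
        sd = sd.where(~constant, 1.0)
        z = (block - mu) / sd
        z.loc[:, list(constant.index[constant])] = 0.0
        std.loc[idx] = z
    return NetworkPropertyTable(values=values, standardized=std, experiment_of=exp)
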