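"""Bayesian network structure learning over significant SNPs.

Greedy hill-climbing over add/delete/reverse moves maximizing the BIC
score, with a tabu list of recently visited structures and random restarts.
Dosages are scored as Gaussian by default (they are ordinal 0/1/2; the
Gaussian BIC is the pragmatic default and is checkable against exhaustive
enumeration on small node sets) or as 3-level discrete variables.  Edge
direction inside a Markov equivalence class is not identifiable from
observational data; downstream consumers should rely on the skeleton.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SnpDag:
    """A scored DAG over SNP nodes."""

    nodes: list[str]
    edges: set[tuple[str, str]]
    score: float
    hub_flags: dict[str, bool] = field(default_factory=dict)

    def adjacency(self) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.nodes)}
        A = np.zeros((len(self.nodes), len(self.nodes)), dtype=bool)
        for u, v in self.edges:
            A[idx[u], idx[v]] = True
        return A

    def skeleton(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.edges}

    def is_acyclic(self) -> bool:
        return _is_dag(self.adjacency())

    def degrees(self) -> dict[str, int]:
        deg = dict.fromkeys(self.nodes, 0)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg


def _is_dag(A: np.ndarray) -> bool:
    """Topological-sort acyclicity check on a boolean adjacency matrix."""
    A = A.copy()
    n = A.shape[0]
    indeg = A.sum(axis=0)
    stack = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for v in np.where(A[u])[0]:
            A[u, v] = False
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    return seen == n


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


class _GaussianBic:
    """Decomposable Gaussian BIC: local score of node i with parent set P
    is -n/2 (log(2 pi rss/n) + 1) - (|P| + 2)/2 log n."""

    def __init__(self, X: np.ndarray):
        self.X = X - X.mean(axis=0)
        self.n = X.shape[0]
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, i: int, parents: tuple[int, ...]) -> float:
        key = (i, parents)
        if key in self._cache:
            return self._cache[key]
        y = self.X[:, i]
        if parents:
            Z = self.X[:, list(parents)]
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            rss = float(np.sum((y - Z @ coef) ** 2))
        else:
            rss = float(np.sum(y**2))
        rss = max(rss, 1e-12)
        n = self.n
        ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
        val = ll - 0.5 * (len(parents) + 2) * np.log(n)
        self._cache[key] = val
        return val


class _DiscreteBic:
    """Decomposable BIC for 3-level discrete dosages."""

    def __init__(self, X: np.ndarray, levels: int = 3):
        self.X = X.astype(int)
        self.n, _ = X.shape
        self.levels = levels
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, i: int, parents: tuple[int, ...]) -> float:
        key = (i, parents)
        if key in self._cache:
            return self._cache[key]
        y = self.X[:, i]
        if parents:
            base = self.levels ** np.arange(len(parents))
            config = self.X[:, list(parents)] @ base
        else:
            config = np.zeros(self.n, dtype=int)
        ll = 0.0
        for c in np.unique(config):
            sel = y[config == c]
            counts = np.bincount(sel, minlength=self.levels).astype(float)
            nz = counts[counts > 0]
            ll += float(np.sum(nz * np.log(nz / sel.size)))
        n_params = (self.levels - 1) * self.levels ** len(parents)
        val = ll - 0.5 * n_params * np.log(self.n)
        self._cache[key] = val
        return val


def score_dag(
    X: np.ndarray, edges: set[tuple[int, int]], scorer: str = "bic_gaussian"
) -> float:
    """Independent re-scoring of a structure (sum of local scores)."""
    sc = _GaussianBic(X) if scorer == "bic_gaussian" else _DiscreteBic(X)
    n_nodes = X.shape[1]
    parents: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for u, v in edges:
        parents[v].append(u)
    return float(sum(sc.local(i, tuple(sorted(parents[i]))) for i in range(n_nodes)))


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------


def _hill_climb(sc, n_nodes: int, rng: np.random.Generator, tabu_len: int = 10,
                max_iter: int = 2000, init_edges: set | None = None):
    parents: dict[int, set[int]] = {i: set() for i in range(n_nodes)}
    A = np.zeros((n_nodes, n_nodes), dtype=bool)
    if init_edges:
        for u, v in init_edges:
            parents[v].add(u)
            A[u, v] = True
    local = [sc.local(i, tuple(sorted(parents[i]))) for i in range(n_nodes)]
    total = float(sum(local))
    tabu: list[frozenset] = [frozenset((u, v) for u, v in zip(*np.where(A)))]

    def creates_cycle(u: int, v: int) -> bool:
        Anew = A.copy()
        Anew[u, v] = True
        return not _is_dag(Anew)

    for _ in range(max_iter):
        best_move = None
        best_gain = 1e-10
        pairs = [(u, v) for u in range(n_nodes) for v in range(n_nodes) if u != v]
        rng.shuffle(pairs)
        for u, v in pairs:
            if A[u, v]:
                # delete
                newp = tuple(sorted(parents[v] - {u}))
                gain = sc.local(v, newp) - local[v]
                if gain > best_gain:
                    cand = ("del", u, v, gain)
                    if _allowed(A, cand, tabu):
                        best_move, best_gain = cand, gain
                # reverse
                if not creates_cycle_after_reverse(A, u, v):
                    gain = (
                        sc.local(v, tuple(sorted(parents[v] - {u})))
                        - local[v]
                        + sc.local(u, tuple(sorted(parents[u] | {v})))
                        - local[u]
                    )
                    if gain > best_gain:
                        cand = ("rev", u, v, gain)
                        if _allowed(A, cand, tabu):
                            best_move, best_gain = cand, gain
            elif not A[v, u] and not creates_cycle(u, v):
                gain = sc.local(v, tuple(sorted(parents[v] | {u}))) - local[v]
                if gain > best_gain:
                    cand = ("add", u, v, gain)
                    if _allowed(A, cand, tabu):
                        best_move, best_gain = cand, gain
        if best_move is None:
            break
        op, u, v, _ = best_move
        if op == "add":
            parents[v].add(u)
            A[u, v] = True
        elif op == "del":
            parents[v].discard(u)
            A[u, v] = False
        else:
            parents[v].discard(u)
            parents[u].add(v)
            A[u, v] = False
            A[v, u] = True
            local[u] = sc.local(u, tuple(sorted(parents[u])))
        local[v] = sc.local(v, tuple(sorted(parents[v])))
        if op == "rev":
            local[u] = sc.local(u, tuple(sorted(parents[u])))
        new_total = float(sum(local))
        assert new_total >= total - 1e-9, "BIC must not decrease on an accepted move"
        total = new_total
        tabu.append(frozenset((a, b) for a, b in zip(*np.where(A))))
        if len(tabu) > tabu_len:
            tabu.pop(0)
    edges = {(int(u), int(v)) for u, v in zip(*np.where(A))}
    return edges, total


def creates_cycle_after_reverse(A: np.ndarray, u: int, v: int) -> bool:
    Anew = A.copy()
    Anew[u, v] = False
    Anew[v, u] = True
    return not _is_dag(Anew)


def _allowed(A: np.ndarray, move, tabu) -> bool:
    op, u, v, _ = move
    Anew = A.copy()
    if op == "add":
        Anew[u, v] = True
    elif op == "del":
        Anew[u, v] = False
    else:
        Anew[u, v] = False
        Anew[v, u] = True
    state = frozenset((a, b) for a, b in zip(*np.where(Anew)))
    return state not in tabu


def learn_dag(
    gen_or_frame,
    scorer: str = "bic_gaussian",
    restarts: int = 20,
    rng_seed: int = 0,
    snp_ids: list[str] | None = None,
) -> SnpDag:
    """Learn a DAG over SNP dosages by restarted tabu hill-climbing on BIC.

    ``gen_or_frame``: a GenotypeTable (all SNPs used), a DataFrame
    (columns = SNPs) or an array with ``snp_ids``.  The first restart
    starts from the empty graph; later restarts from random sparse DAGs.
    Deterministic given ``rng_seed``.  Returns the best-scoring structure;
    with fewer than 2 SNPs an empty DAG is returned with a warning.
    """
    if isinstance(gen_or_frame, pd.DataFrame):
        names = list(gen_or_frame.columns)
        X = gen_or_frame.to_numpy(dtype=float)
    elif hasattr(gen_or_frame, "dosages"):
        names = list(gen_or_frame.snp_ids)
        X = gen_or_frame.imputed()
    else:
        X = np.asarray(gen_or_frame, dtype=float)
        names = snp_ids or [f"snp{i}" for i in range(X.shape[1])]
    n_nodes = X.shape[1]
    if n_nodes < 2:
        logger.warning("fewer than 2 SNPs; returning empty DAG")
        return SnpDag(nodes=names, edges=set(), score=float("nan"))

    sc = _GaussianBic(X) if scorer == "bic_gaussian" else _DiscreteBic(X)
    rng = np.random.default_rng(rng_seed)
    best_edges: set | None = None
    best_score = -np.inf
    for r in range(max(restarts, 1)):
        if r == 0:
            init: set[tuple[int, int]] = set()
        else:
            init = set()
            for u, v in combinations(rng.permutation(n_nodes).tolist(), 2):
                if rng.random() < 1.5 / n_nodes:
                    init.add((int(u), int(v)))  # ordered pairs of a permutation: acyclic
        edges, total = _hill_climb(sc, n_nodes, rng, init_edges=init)
        if total > best_score:
            best_score, best_edges = total, edges
    named = {(names[u], names[v]) for u, v in best_edges}
    dag = SnpDag(nodes=names, edges=named, score=float(best_score))
    if not dag.is_acyclic():  # pragma: no cover - defensive
        raise RuntimeError("hill climber produced a cyclic structure")
    return dag


def hub_qtls(
    dag: SnpDag,
    quantile: float = 0.90,
    min_degree: int = 2,
    traits_of: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Hub QTLs: nodes with total degree at or above the q-th degree
    quantile (and at least ``min_degree``).  If ``traits_of`` maps SNP ->
    set of traits it is significant for, SNPs with more than one trait are
    flagged pleiotropic."""
    deg = dag.degrees()
    if not deg or not dag.edges:
        return pd.DataFrame(columns=["snp_id", "degree", "is_hub", "pleiotropic"])
    cutoff = float(np.quantile(list(deg.values()), quantile))
    rows = []
    for snp, d in deg.items():
        is_hub = d >= max(cutoff, min_degree)
        pleio = bool(traits_of and len(traits_of.get(snp, ())) > 1)
        rows.append({"snp_id": snp, "degree": d, "is_hub": bool(is_hub),
                     "pleiotropic": pleio})
    dag.hub_flags = {r["snp_id"]: r["is_hub"] for r in rows}
    return pd.DataFrame(rows)
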