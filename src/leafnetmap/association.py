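"""Association mapping of network-property phenotypes with nested models.

Three models are fitted per trait: ``naive`` (per-SNP simple regression),
``Q`` (structure covariates = top genotype principal components) and ``QK``
(EMMAX-style mixed model: variance components for the VanRaden kinship are
estimated once per trait under the null by REML on the kinship
eigendecomposition, then each SNP gets a generalized least squares Wald
test at the fixed variance ratio).  Model choice follows the genomic
inflation factor: the model whose lambda is closest to 1 wins, ties going
to the more complex model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .io_formats import DesignTable, GenotypeTable

logger = logging.getLogger(__name__)

MODELS = ("naive", "Q", "QK")
MEDIAN_CHI2_1 = 0.4549364231195724  # median of chi-square with 1 df


# ---------------------------------------------------------------------------
# structure model
# ---------------------------------------------------------------------------


@dataclass
class StructureModel:
    """Population structure covariates Q and VanRaden kinship K."""

    Q: np.ndarray            # accessions x k, orthonormal columns
    K: np.ndarray            # accessions x accessions, PSD
    accession_ids: list[str]
    k: int

    def __post_init__(self) -> None:
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("kinship matrix must be positive semidefinite")


def _standardized_dosages(gen: GenotypeTable) -> np.ndarray:
    X = gen.imputed()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def build_structure(gen: GenotypeTable, k: int = 3) -> StructureModel:
    """PCA structure covariates + VanRaden genomic relationship matrix.

    Q holds the top-k left singular vectors of the standardized (mean-
    imputed) dosage matrix; K = Z Z' / m on the same standardized dosages.
    """
    n = gen.n_accessions
    if n < 2:
        raise ValueError("need at least 2 accessions")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of accessions {n}")
    Z = _standardized_dosages(gen)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    Q = U[:, :k]
    K = Z @ Z.T / gen.n_snps
    return StructureModel(Q=Q, K=K, accession_ids=list(gen.accession_ids), k=k)


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """Per-SNP association statistics for one trait and model."""

    trait: str
    model: str
    table: pd.DataFrame          # snp_id, chrom, pos, maf, beta, se, stat, p
    lambda_gc: float
    n_skipped: int = 0
    var_components: tuple[float, float] | None = None  # (sigma2_g, sigma2_e), QK only


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Median-chi-square genomic inflation factor (NaN with no tests)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return float("nan")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / MEDIAN_CHI2_1)


def average_replicates(
    phenotypes: pd.DataFrame, design: DesignTable
) -> pd.DataFrame:
    """Average per-sample phenotypes to one value per accession (genotype
    is the experimental unit)."""
    acc = pd.Series(design.accession_of())
    df = phenotypes.copy()
    df["__acc"] = acc.reindex(df.index)
    out = df.groupby("__acc").mean()
    out.index.name = "accession_id"
    return out


def _wald_scan(yr: np.ndarray, Gr: np.ndarray, Xr: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP Wald tests of (possibly rotated/whitened) genotype columns,
    with covariates projected out (Frisch-Waugh).  Returns beta, se, t, p,
    and a mask of skipped (constant) SNPs."""
    n = len(yr)
    # project covariates out of y and G
    Qc, _ = np.linalg.qr(Xr)
    yp = yr - Qc @ (Qc.T @ yr)
    Gp = Gr - Qc @ (Qc.T @ Gr)
    dof = n - Xr.shape[1] - 1
    gss = (Gp**2).sum(axis=0)
    skip = gss < 1e-12
    gss_safe = np.where(skip, 1.0, gss)
    beta = (Gp * yp[:, None]).sum(axis=0) / gss_safe
    rss = (yp**2).sum() - beta**2 * gss_safe
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 / gss_safe, 1e-300))
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, tstat, p, skip


def _reml_kinship(y: np.ndarray, X: np.ndarray, evals: np.ndarray, evecs: np.ndarray):
    """Null-model REML for y = X b + g + e, g ~ N(0, s2g K), on the
    eigendecomposition of K.  Returns (s2g, s2e, delta = s2e/s2g)."""
    yr = evecs.T @ y
    Xr = evecs.T @ X
    n, q = Xr.shape

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        d = evals + delta
        w = 1.0 / d
        XtWX = Xr.T @ (Xr * w[:, None])
        XtWy = Xr.T @ (yr * w)
        try:
            b = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return 1e30
        r = yr - Xr @ b
        quad = float(np.sum(r**2 * w))
        s2 = max(quad / (n - q), np.finfo(float).tiny)
        _, ld_x = np.linalg.slogdet(XtWX)
        return 0.5 * ((n - q) * np.log(s2) + np.sum(np.log(d)) + ld_x)

    res = minimize_scalar(neg_reml, bounds=(-10.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    delta = float(np.exp(res.x))
    d = evals + delta
    w = 1.0 / d
    XtWX = Xr.T @ (Xr * w[:, None])
    XtWy = Xr.T @ (yr * w)
    b = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ b
    s2g = float(np.sum(r**2 * w) / (len(yr) - X.shape[1]))
    s2e = s2g * delta
    return s2g, s2e, delta


def scan(
    phenotypes: pd.DataFrame,
    gen: GenotypeTable,
    sm: StructureModel,
    model: str = "QK",
    design: DesignTable | None = None,
    maf_min: float = 0.05,
) -> dict[str, AssociationResult]:
    """Scan every SNP against every phenotype column.

    ``phenotypes`` is indexed by sample id (if ``design`` given; replicates
    are averaged per accession) or directly by accession id.  SNPs at
    MAF <= ``maf_min`` are excluded before testing; constant SNPs are
    skipped and counted.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if design is not None:
        phenotypes = average_replicates(phenotypes, design)
    acc_index = [a for a in sm.accession_ids if a in phenotypes.index]
    if len(acc_index) < 10:
        raise ValueError("too few accessions with phenotypes")
    rows = [sm.accession_ids.index(a) for a in acc_index]

    keep = gen.maf > maf_min
    X = gen.imputed()[np.ix_(rows, np.where(keep)[0])]
    snp_ids = [s for s, k in zip(gen.snp_ids, keep) if k]
    chrom = gen.chrom[keep]
    pos = gen.pos[keep]
    maf = gen.maf[keep]
    n = len(acc_index)
    intercept = np.ones((n, 1))
    if model == "naive":
        covar = intercept
    else:
        covar = np.hstack([intercept, sm.Q[rows]])

    results: dict[str, AssociationResult] = {}
    evals = evecs = None
    if model == "QK":
        K = sm.K[np.ix_(rows, rows)]
        evals, evecs = np.linalg.eigh(K)
        evals = np.maximum(evals, 0.0)

    for trait in phenotypes.columns:
        y = phenotypes.loc[acc_index, trait].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        yv, Xv, Cv = y[ok], X[ok], covar[ok]
        varcomp = None
        if model == "QK":
            ev, U = (evals, evecs) if ok.all() else np.linalg.eigh(
                sm.K[np.ix_(list(np.array(rows)[ok]), list(np.array(rows)[ok]))]
            )
            ev = np.maximum(ev, 0.0)
            s2g, s2e, delta = _reml_kinship(yv, Cv, ev, U)
            varcomp = (s2g, s2e)
            w = 1.0 / np.sqrt(ev + delta)
            yr = (U.T @ yv) * w
            Gr = (U.T @ Xv) * w[:, None]
            Xr = (U.T @ Cv) * w[:, None]
        else:
            yr, Gr, Xr = yv, Xv, Cv
        beta, se, tstat, p, skip = _wald_scan(yr, Gr, Xr)
        if skip.any():
            logger.info("trait %s: skipped %d constant SNPs", trait, int(skip.sum()))
        tbl = pd.DataFrame({
            "snp_id": snp_ids, "chrom": chrom, "pos": pos, "maf": maf,
            "beta": beta, "se": se, "stat": tstat, "p": p,
        })
        tbl = tbl[~skip].reset_index(drop=True)
        results[trait] = AssociationResult(
            trait=trait, model=model, table=tbl,
            lambda_gc=genomic_inflation(tbl["p"].to_numpy()),
            n_skipped=int(skip.sum()), var_components=varcomp,
        )
    return results


def select_model(results_per_model: dict[str, AssociationResult]) -> str:
    """Pick the model with lambda closest to 1 (argmin |log lambda|), ties
    broken toward the more complex model (QK > Q > naive)."""
    complexity = {m: i for i, m in enumerate(MODELS)}
    best = None
    for m, res in results_per_model.items():
        lam = res.lambda_gc
        # a degenerate lambda (0, nan) is infinitely far from 1
        dist = abs(np.log(lam)) if np.isfinite(lam) and lam > 0 else np.inf
        key = (dist, -complexity[m])
        if best is None or key < best[0]:
            best = (key, m)
    if best is None:
        raise ValueError("no model results supplied")
    return best[1]


# ---------------------------------------------------------------------------
# significance, PVE, windows
# ---------------------------------------------------------------------------


def snp_h2(beta: np.ndarray, maf: np.ndarray, var_y: float) -> np.ndarray:
    """Per-SNP phenotypic variance explained: 2 p (1-p) beta^2 / var(y)."""
    h2 = 2.0 * maf * (1.0 - maf) * beta**2 / var_y
    return np.clip(h2, 0.0, 1.0 - np.finfo(float).eps)


def significant_snps(
    res: AssociationResult,
    var_y: float,
    method: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Threshold the scan (Bonferroni default, BH optional) and report
    per-SNP variance explained for the survivors."""
    tbl = res.table
    m = len(tbl)
    if m == 0:
        return tbl.assign(h2=[])
    p = tbl["p"].to_numpy()
    if method == "bonferroni":
        sig = p <= alpha / m
    elif method == "bh":
        order = np.argsort(p)
        ranked = p[order] <= alpha * (np.arange(1, m + 1) / m)
        cutoff_rank = np.max(np.where(ranked)[0]) if ranked.any() else -1
        sig = np.zeros(m, bool)
        if cutoff_rank >= 0:
            sig[order[: cutoff_rank + 1]] = True
    else:
        raise ValueError(f"unknown method {method!r}")
    out = tbl[sig].copy().reset_index(drop=True)
    out["h2"] = snp_h2(out["beta"].to_numpy(), out["maf"].to_numpy(), var_y)
    return out


@dataclass
class CandidateWindow:
    """LD-defined candidate interval around one lead SNP."""

    lead_snp: str
    chrom: str
    start: int
    end: int
    members: list[str] = field(default_factory=list)
    r2: dict[str, float] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)


def ld_r2(gen: GenotypeTable, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of dosages (composite LD)."""
    X = gen.imputed()
    ia, ib = gen.snp_ids.index(snp_a), gen.snp_ids.index(snp_b)
    a, b = X[:, ia], X[:, ib]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def candidate_windows(
    snps: list[str],
    gen: GenotypeTable,
    w: int = 10_000,
    r2_min: float = 0.8,
    annotations: pd.DataFrame | None = None,
) -> list[CandidateWindow]:
    """Closed +-w bp windows around each lead SNP; same-chromosome member
    SNPs with r^2 > ``r2_min`` are retained; overlapping windows merge.

    ``annotations``: optional BED-like frame (chrom, start, end, name);
    genes overlapping a window are listed.
    """
    if gen.pos is None or gen.chrom is None:
        raise ValueError("SNP positions required for candidate windows")
    X = gen.imputed()
    pos_of = {s: i for i, s in enumerate(gen.snp_ids)}
    wins: list[CandidateWindow] = []
    for lead in snps:
        if lead not in pos_of:
            raise KeyError(f"unknown SNP {lead!r}")
        i = pos_of[lead]
        c, p = str(gen.chrom[i]), int(gen.pos[i])
        lo, hi = max(p - w, 0), p + w
        members, r2map = [], {}
        in_win = np.where((gen.chrom.astype(str) == c) & (gen.pos >= lo) & (gen.pos <= hi))[0]
        a = X[:, i]
        for j in in_win:
            b = X[:, j]
            if a.std() == 0 or b.std() == 0:
                continue
            r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
            if r2 > r2_min:
                members.append(gen.snp_ids[j])
                r2map[gen.snp_ids[j]] = r2
        wins.append(CandidateWindow(lead, c, lo, hi, members, r2map))
    # merge overlapping windows on the same chromosome
    wins.sort(key=lambda cw: (cw.chrom, cw.start))
    merged: list[CandidateWindow] = []
    for cw in wins:
        if merged and merged[-1].chrom == cw.chrom and cw.start <= merged[-1].end:
            last = merged[-1]
            last.end = max(last.end, cw.end)
            last.members = sorted(set(last.members) | set(cw.members))
            last.r2.update(cw.r2)
        else:
            merged.append(cw)
    if annotations is not None:
        for cw in merged:
            hits = annotations[
                (annotations["chrom"].astype(str) == cw.chrom)
                & (annotations["end"] >= cw.start)
                & (annotations["start"] <= cw.end)
            ]
            cw.genes = list(hits["name"])
    return merged
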