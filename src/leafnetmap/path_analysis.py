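"""Correlation-based path analysis: decompose a SNP's association with
fecundity into a direct path and an indirect path mediated by a microbial
network property.

For genotype g, mediator y (a network-property trait) and fecundity z the
single-mediator decomposition is

    r_gz = P_direct + P_indirect,   P_indirect = P_(z<-y) * r_gy,
    with the mediator path fixed at P_(z<-y) = r_yz,

so P_direct = r_gz - r_yz * r_gy holds as an exact identity.  Mediators are
treated one at a time; a joint multi-mediator variant (P_(z<-y) from a
multiple regression of z on all mediators) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PathDecomposition", "decompose", "decompose_all"]


@dataclass
class PathDecomposition:
    """Direct/indirect path coefficients for one (SNP, mediator) pair."""

    snp_id: str
    mediator_id: str
    r_gy: float
    r_yz: float
    r_gz: float
    p_direct: float
    p_indirect: float

    @property
    def direct_sign(self) -> str:
        return "promote" if self.p_direct >= 0 else "inhibit"

    @property
    def indirect_sign(self) -> str:
        return "promote" if self.p_indirect >= 0 else "inhibit"


def _pearson(a: np.ndarray, b: np.ndarray, what: str) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError(f"correlation undefined: {what} is constant")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def decompose(
    g: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    snp_id: str = "g",
    mediator_id: str = "y",
) -> PathDecomposition:
    """Decompose corr(g, z) into direct and y-mediated components.

    Uses pairwise-complete observations; raises if any vector is constant
    after removing incomplete rows.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(g) == len(y) == len(z)):
        raise ValueError("g, y, z must have equal lengths")
    ok = ~(np.isnan(g) | np.isnan(y) | np.isnan(z))
    g, y, z = g[ok], y[ok], z[ok]
    if len(g) < 3:
        raise ValueError("need at least 3 complete observations")
    r_gy = _pearson(g, y, "genotype/mediator")
    r_yz = _pearson(y, z, "mediator/fecundity")
    r_gz = _pearson(g, z, "genotype/fecundity")
    p_indirect = r_yz * r_gy
    p_direct = r_gz - p_indirect
    return PathDecomposition(snp_id, mediator_id, r_gy, r_yz, r_gz, p_direct, p_indirect)


def decompose_all(
    genotypes: pd.DataFrame,
    properties: pd.DataFrame,
    fecundity: pd.Series,
    joint: bool = False,
    report_threshold: float = 0.05,
) -> pd.DataFrame:
    """One decomposition per (SNP, mediator) pair.

    ``genotypes``: accessions x significant SNPs dosage frame;
    ``properties``: accessions x mediator traits; ``fecundity``: per-accession
    phenotype.  All three are aligned on their shared accession index.  With
    ``joint=True`` the mediator path is the partial regression coefficient of
    each (standardized) mediator in a joint linear model of z on all
    mediators instead of the marginal correlation.

    Returns a tidy frame with one row per (snp, mediator) and a ``flagged``
    column marking |P_indirect| > ``report_threshold``.
    """
    shared = genotypes.index.intersection(properties.index).intersection(fecundity.index)
    if len(shared) == 0:
        raise ValueError("no overlapping accessions between genotypes, properties and fecundity")
    G = genotypes.loc[shared]
    Y = properties.loc[shared]
    z = fecundity.loc[shared].to_numpy(dtype=float)

    mediator_path: dict[str, float] = {}
    if joint:
        Ystd = (Y - Y.mean()) / Y.std(ddof=0)
        zstd = (z - z.mean()) / z.std()
        X = Ystd.to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, zstd, rcond=None)
        mediator_path = dict(zip(Y.columns, coef))

    rows = []
    for snp in G.columns:
        gvec = G[snp].to_numpy(dtype=float)
        for med in Y.columns:
            d = decompose(gvec, Y[med].to_numpy(dtype=float), z, snp, med)
            if joint:
                p_zy = mediator_path[med]
                d.p_indirect = p_zy * d.r_gy
                d.p_direct = d.r_gz - d.p_indirect
            rows.append(
                {
                    "snp_id": d.snp_id,
                    "mediator_id": d.mediator_id,
                    "r_gy": d.r_gy,
                    "r_yz": d.r_yz,
                    "r_gz": d.r_gz,
                    "p_direct": d.p_direct,
                    "p_indirect": d.p_indirect,
                    "direct_sign": d.direct_sign,
                    "indirect_sign": d.indirect_sign,
                    "flagged": abs(d.p_indirect) > report_threshold,
                }
            )
    return pd.DataFrame(rows)
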