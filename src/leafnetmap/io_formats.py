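"""Readers, writers and validated in-memory containers.

All downstream modules operate on the domain types defined here:
:class:`AbundanceTable` (samples x OTUs relative abundances),
:class:`GenotypeTable` (accessions x SNPs additive dosages) and
:class:`DesignTable` (sample -> accession / site / year / replicate).
Files are plain TSV/CSV (plus VCF for genotypes and GraphML for networks);
orientation of matrix files is normalized on read so that the canonical
in-memory layout is always samples x OTUs and accessions x SNPs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINGDOMS = ("bacteria", "fungi")


class ParseError(ValueError):
    """A cell or line could not be interpreted."""


class FormatError(ValueError):
    """The file violates the structural contract (duplicates, truncation)."""


class ValidationError(ValueError):
    """The parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Relative abundances of OTUs across samples.

    ``values[s, o]`` is the abundance of OTU ``otu_ids[o]`` in sample
    ``sample_ids[s]``.  ``kingdom`` labels each OTU as ``bacteria`` or
    ``fungi``; ``taxonomy`` is an optional lineage string per OTU.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray
    kingdom: list[str] = field(default_factory=list)
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not self.kingdom:
            self.kingdom = ["bacteria"] * len(self.otu_ids)
        self.validate()

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU ids")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("non-finite abundance values")
        if np.any(self.values < 0):
            raise ValidationError("negative abundance values")
        if len(self.kingdom) != len(self.otu_ids):
            raise ValidationError("kingdom labels do not match OTU count")
        bad = set(self.kingdom) - set(KINGDOMS)
        if bad:
            raise ValidationError(f"unknown kingdom labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def normalize(self) -> "AbundanceTable":
        """Return a copy whose rows sum to one (samples with zero total stay zero)."""
        totals = self.values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(totals > 0, self.values / totals, 0.0)
        return AbundanceTable(
            list(self.sample_ids), list(self.otu_ids), vals,
            list(self.kingdom), None if self.taxonomy is None else list(self.taxonomy),
        )

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return bool(np.all(np.abs(self.values.sum(axis=1) - 1.0) <= tol))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)

    def subset_otus(self, otus: Sequence[str]) -> "AbundanceTable":
        idx = [self.otu_ids.index(o) for o in otus]
        return AbundanceTable(
            list(self.sample_ids), [self.otu_ids[i] for i in idx],
            self.values[:, idx], [self.kingdom[i] for i in idx],
            None if self.taxonomy is None else [self.taxonomy[i] for i in idx],
        )

    def subset_samples(self, samples: Sequence[str]) -> "AbundanceTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return AbundanceTable(
            list(samples), list(self.otu_ids), self.values[idx],
            list(self.kingdom), None if self.taxonomy is None else list(self.taxonomy),
        )


@dataclass
class GenotypeTable:
    """Additive dosages (count of the minor allele) per accession and SNP.

    Missing calls are stored as NaN.  ``maf`` is recomputed from the
    non-missing dosages and SNPs are polarized so the dosage counts the
    minor allele.
    """

    accession_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = len(self.accession_ids), len(self.snp_ids)
        if self.dosages.shape != (n, m):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} != {n} accessions x {m} SNPs"
            )
        if len(set(self.accession_ids)) != n:
            raise FormatError("duplicate accession ids")
        if len(set(self.snp_ids)) != m:
            raise FormatError("duplicate SNP ids")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValidationError("dosages must be 0/1/2 or missing")
        if self.chrom is None:
            self.chrom = np.array(["0"] * m, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.pos is None:
            self.pos = np.arange(1, m + 1, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if np.any(self.pos < 0):
            raise ValidationError("negative SNP positions")
        self._polarize()
        self.maf = self.compute_maf()

    def _polarize(self) -> None:
        """Flip SNPs so dosage counts the minor allele."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        flip = freq > 0.5
        if np.any(flip):
            self.dosages[:, flip] = 2.0 - self.dosages[:, flip]

    def compute_maf(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def imputed(self) -> np.ndarray:
        """Dosages with per-SNP mean imputation (used only inside
        kinship/association computations; never written back)."""
        X = self.dosages.copy()
        mask = np.isnan(X)
        if mask.any():
            with np.errstate(invalid="ignore"):
                means = np.nanmean(X, axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            X[mask] = np.broadcast_to(means, X.shape)[mask]
        return X

    def subset_snps(self, snps: Sequence[str]) -> "GenotypeTable":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in snps]
        return GenotypeTable(
            list(self.accession_ids), list(snps), self.dosages[:, idx].copy(),
            self.chrom[idx].copy(), self.pos[idx].copy(),
        )


@dataclass
class DesignTable:
    """Experimental design: one row per sample."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "accession_id", "site", "year", "replicate")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        self.frame = self.frame.copy()
        self.frame["year"] = self.frame["year"].astype(int)
        self.frame["replicate"] = self.frame["replicate"].astype(int)
        if self.frame["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in design table")
        combo = self.frame[["accession_id", "site", "year", "replicate"]]
        if combo.duplicated().any():
            raise FormatError("duplicate (accession, site, year, replicate) combinations")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def experiments(self) -> list[tuple[str, int]]:
        """Distinct (site, year) experiment keys in order of appearance."""
        seen = self.frame[["site", "year"]].drop_duplicates()
        return [(str(s), int(y)) for s, y in seen.itertuples(index=False)]

    def samples_in(self, site: str, year: int) -> list[str]:
        f = self.frame
        sel = f[(f["site"] == site) & (f["year"] == int(year))]
        return list(sel["sample_id"])

    def accession_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["accession_id"]))


# ---------------------------------------------------------------------------
# abundance IO
# ---------------------------------------------------------------------------


def _read_tsv_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray, dict]:
    """Read a TSV matrix with a header row and an id column, rejecting
    truncated rows.  Leading '#key<TAB>...' comment lines are collected."""
    path = Path(path)
    meta: dict[str, list[str]] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                meta[parts[0].strip()] = [p.strip() for p in parts[1:]]
                continue
            rows.append(line.split("\t"))
    if len(rows) < 2:
        raise FormatError(f"{path}: need a header and at least one data row")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(
                f"{path}: row {i + 1} has {len(r)} fields, expected {width} "
                "(truncated or malformed file)"
            )
    header = rows[0]
    col_ids = [h.strip() for h in header[1:]]
    row_ids = [r[0].strip() for r in rows[1:]]
    body = np.empty((len(row_ids), len(col_ids)))
    for i, r in enumerate(rows[1:]):
        for j, cell in enumerate(r[1:]):
            try:
                body[i, j] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric cell at data row {i + 1}, column "
                    f"{col_ids[j]!r}: {cell!r}"
                ) from exc
    return row_ids, col_ids, body, meta


def read_abundance_table(
    path: str | Path,
    format: str = "auto",
    kingdom: dict[str, str] | None = None,
) -> AbundanceTable:
    """Read an OTU abundance TSV and return a normalized AbundanceTable.

    ``format`` is one of ``tsv_samples_by_otus``, ``tsv_otus_by_samples`` or
    ``auto`` (orientation inferred from the corner header label).  Counts are
    converted to relative abundances per sample.  Kingdom labels are taken
    from a ``#kingdom`` comment line (aligned with the OTU ids), from the
    ``kingdom`` argument, or default to ``bacteria``.
    """
    row_ids, col_ids, body, meta = _read_tsv_matrix(path)
    corner = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            corner = line.split("\t")[0].strip().lower()
            break
    if format == "auto":
        if corner in ("otu_id", "otu", "taxon", "taxon_id"):
            format = "tsv_otus_by_samples"
        else:
            format = "tsv_samples_by_otus"
    if format == "tsv_otus_by_samples":
        sample_ids, otu_ids, values = col_ids, row_ids, body.T.copy()
    elif format == "tsv_samples_by_otus":
        sample_ids, otu_ids, values = row_ids, col_ids, body
    else:
        raise ValueError(f"unknown abundance format {format!r}")
    labels = None
    if "kingdom" in meta and len(meta["kingdom"]) == len(otu_ids):
        labels = meta["kingdom"]
    elif kingdom is not None:
        labels = [kingdom.get(o, "bacteria") for o in otu_ids]
    table = AbundanceTable(sample_ids, otu_ids, values, labels or [])
    return table.normalize()


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#kingdom\t" + "\t".join(table.kingdom) + "\n")
        fh.write("sample_id\t" + "\t".join(table.otu_ids) + "\n")
        for sid, row in zip(table.sample_ids, table.values):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


@dataclass
class SelectionReport:
    """Report from top-OTU selection: retained mass fraction per kingdom."""

    n_kept: dict[str, int]
    retained_fraction: dict[str, float]


def select_top_otus(
    table: AbundanceTable,
    n_bacteria: int = 200,
    n_fungi: int = 200,
    renormalize: bool = True,
) -> tuple[AbundanceTable, SelectionReport]:
    """Keep the top-n most abundant OTUs per kingdom (mean relative
    abundance across samples; ties broken by lexicographic OTU id).

    Returns the reduced table and a report with the cumulative abundance
    fraction retained per kingdom.  With ``renormalize`` (default) rows are
    re-closed to sum to one, matching relative-abundance semantics.
    """
    want = {"bacteria": n_bacteria, "fungi": n_fungi}
    means = table.values.mean(axis=0)
    keep: list[str] = []
    n_kept: dict[str, int] = {}
    retained: dict[str, float] = {}
    for kd in KINGDOMS:
        members = [(o, means[i]) for i, o in enumerate(table.otu_ids) if table.kingdom[i] == kd]
        if not members:
            continue
        n = want[kd]
        if n > len(members):
            logger.warning(
                "requested %d %s OTUs but only %d available; keeping all",
                n, kd, len(members),
            )
            n = len(members)
        ranked = sorted(members, key=lambda t: (-t[1], t[0]))
        chosen = ranked[:n]
        keep.extend(o for o, _ in chosen)
        total = sum(m for _, m in members)
        n_kept[kd] = n
        retained[kd] = float(sum(m for _, m in chosen) / total) if total > 0 else float("nan")
    keep = [o for o in table.otu_ids if o in set(keep)]  # original order
    out = table.subset_otus(keep)
    if renormalize:
        out = out.normalize()
    return out, SelectionReport(n_kept, retained)


# ---------------------------------------------------------------------------
# genotype IO
# ---------------------------------------------------------------------------

_SNPID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+)$")


def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeTable:
    """Read genotypes from a VCF or a dosage TSV.

    VCF records that are not biallelic SNPs are skipped (counted, logged).
    The dosage TSV is accessions x SNPs, coded 0/1/2 with NA for missing;
    SNP ids of the form ``chrom:pos`` carry coordinates.
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    accessions = list(vcf.samples)
    if len(set(accessions)) != len(accessions):
        raise FormatError("duplicate accession ids in VCF header")
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    cols: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        g = rec.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = np.nan
        cols.append(g)
        snp_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM))
        positions.append(int(rec.POS))
    if skipped:
        logger.warning("skipped %d non-biallelic/non-SNP VCF records", skipped)
    if not cols:
        raise FormatError(f"{path}: no biallelic SNPs found")
    dosages = np.column_stack(cols)
    table = GenotypeTable(accessions, snp_ids, dosages, np.array(chroms, dtype=object),
                          np.array(positions))
    table.n_skipped_records = skipped  # type: ignore[attr-defined]
    return table


def _read_dosage_tsv(path: Path) -> GenotypeTable:
    row_ids, col_ids, body, _ = _read_tsv_matrix_allow_na(path)
    chroms, positions = [], []
    for sid in col_ids:
        m = _SNPID_RE.match(sid)
        if m:
            chroms.append(m.group("chrom"))
            positions.append(int(m.group("pos")))
        else:
            chroms, positions = [], []
            break
    if not col_ids:
        raise FormatError(f"{path}: no SNP columns")
    return GenotypeTable(
        row_ids, col_ids, body,
        np.array(chroms, dtype=object) if chroms else None,
        np.array(positions) if positions else None,
    )


def _read_tsv_matrix_allow_na(path: Path):
    """Like _read_tsv_matrix but 'NA'/'' parse to NaN."""
    row_ids, col_ids, body, meta = None, None, None, {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                meta[parts[0].strip()] = [p.strip() for p in parts[1:]]
                continue
            rows.append(line.split("\t"))
    if len(rows) < 2:
        raise FormatError(f"{path}: need a header and at least one data row")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(f"{path}: row {i + 1} has {len(r)} fields, expected {width}")
    col_ids = [h.strip() for h in rows[0][1:]]
    row_ids = [r[0].strip() for r in rows[1:]]
    body = np.empty((len(row_ids), len(col_ids)))
    for i, r in enumerate(rows[1:]):
        for j, cell in enumerate(r[1:]):
            cell = cell.strip()
            if cell in ("NA", "NaN", "nan", ""):
                body[i, j] = np.nan
            else:
                try:
                    body[i, j] = float(cell)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: non-numeric cell at data row {i + 1}, "
                        f"column {col_ids[j]!r}: {cell!r}"
                    ) from exc
    return row_ids, col_ids, body, meta


def write_genotypes(gen: GenotypeTable, path: str | Path, format: str = "dosage_tsv") -> None:
    path = Path(path)
    if format == "dosage_tsv":
        with open(path, "w") as fh:
            fh.write("accession_id\t" + "\t".join(gen.snp_ids) + "\n")
            for aid, row in zip(gen.accession_ids, gen.dosages):
                cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
                fh.write(aid + "\t" + "\t".join(cells) + "\n")
    elif format == "vcf":
        _write_vcf(gen, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_vcf(gen: GenotypeTable, path: Path) -> None:
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(gen.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gen.accession_ids) + "\n")
        order = np.lexsort((gen.pos, gen.chrom.astype(str)))
        for j in order:
            gts = "\t".join(
                "./." if np.isnan(v) else gt_of[v] for v in gen.dosages[:, j]
            )
            fh.write(f"{gen.chrom[j]}\t{gen.pos[j]}\t{gen.snp_ids[j]}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# design / phenotype IO
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> DesignTable:
    frame = pd.read_csv(path, dtype={"sample_id": str, "accession_id": str, "site": str})
    return DesignTable(frame)


def write_design(design: DesignTable, path: str | Path) -> None:
    design.frame.to_csv(path, index=False)


def read_phenotype(path: str | Path) -> pd.Series:
    """Read a two-column TSV (id, value) into a Series indexed by id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns")
    return pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str))


def write_phenotype(values: pd.Series, path: str | Path, name: str = "fecundity") -> None:
    with open(path, "w") as fh:
        fh.write(f"sample_id\t{name}\n")
        for k, v in values.items():
            fh.write(f"{k}\t{repr(float(v))}\n")


# ---------------------------------------------------------------------------
# network IO
# ---------------------------------------------------------------------------


def write_network(net, path: str | Path, format: str = "graphml") -> None:
    """Serialize an :class:`~leafnetmap.interaction_networks.InteractionNetwork`.

    ``graphml`` keeps every node/edge attribute through networkx; the
    ``edge_tsv`` format is one edge per row (source, target, type, e_st,
    e_ts, support_st, support_ts) with node ids/attributes in ``#node``
    comment lines so empty networks round-trip.
    """
    import networkx as nx

    path = Path(path)
    g = net.graph.copy()
    g.graph["type"] = net.type
    if net.experiment is not None:
        g.graph["site"] = str(net.experiment[0])
        g.graph["year"] = int(net.experiment[1])
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write(f"#network_type\t{net.type}\n")
            if net.experiment is not None:
                fh.write(f"#experiment\t{net.experiment[0]}\t{net.experiment[1]}\n")
            for node, attrs in g.nodes(data=True):
                fh.write(
                    "#node\t%s\t%s\t%s\n"
                    % (node, repr(float(attrs.get("mean_abundance", 0.0))),
                       attrs.get("role", ""))
                )
            fh.write("source\ttarget\ttype\te_st\te_ts\tsupport_st\tsupport_ts\n")
            for u, v, attrs in g.edges(data=True):
                fh.write(
                    "\t".join(
                        [str(u), str(v), net.type,
                         repr(float(attrs.get("e_st", 0.0))),
                         repr(float(attrs.get("e_ts", 0.0))),
                         repr(float(attrs.get("support_st", 0.0))),
                         repr(float(attrs.get("support_ts", 0.0)))]
                    ) + "\n"
                )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml"):
    import networkx as nx

    from .interaction_networks import InteractionNetwork

    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        # GraphML node ids are strings already; restore attribute types
        net_type = g.graph.pop("type")
        site = g.graph.pop("site", None)
        year = g.graph.pop("year", None)
        experiment = (site, int(year)) if site is not None else None
        return InteractionNetwork(type=net_type, graph=g, experiment=experiment)
    if format == "edge_tsv":
        directed = None
        net_type = None
        experiment = None
        nodes: list[tuple[str, dict]] = []
        edges: list[tuple[str, str, dict]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#network_type"):
                    net_type = line.split("\t")[1]
                elif line.startswith("#experiment"):
                    _, site, year = line.split("\t")
                    experiment = (site, int(year))
                elif line.startswith("#node"):
                    parts = line.split("\t")
                    attrs = {"mean_abundance": float(parts[2])}
                    if len(parts) > 3 and parts[3]:
                        attrs["role"] = parts[3]
                    nodes.append((parts[1], attrs))
                elif line.startswith("source\t"):
                    continue
                else:
                    s, t, _typ, e_st, e_ts, s_st, s_ts = line.split("\t")
                    edges.append(
                        (s, t, {"e_st": float(e_st), "e_ts": float(e_ts),
                                "support_st": float(s_st), "support_ts": float(s_ts)})
                    )
        if net_type is None:
            raise FormatError(f"{path}: missing #network_type line")
        from .interaction_networks import InteractionNetwork, DIRECTED_TYPES

        g = nx.DiGraph() if net_type in DIRECTED_TYPES else nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return InteractionNetwork(type=net_type, graph=g, experiment=experiment)
    raise ValueError(f"unknown network format {format!r}")
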