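"""End-to-end orchestration: simulate -> networks -> properties -> hubs/H2
-> gwas -> bn -> path, with provenance manifests and deterministic seeding.

One global seed derives per-stage seeds by stable hashing of the stage
name, so each stage is reproducible independently of execution order.  A
manifest records the sha256 of every input and output per stage; reruns
with unchanged config and inputs are skipped unless forced, and checksum
mismatches on intermediates halt the run naming the file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    AbundanceTable,
    DesignTable,
    GenotypeTable,
    read_abundance_table,
    read_design,
    read_genotypes,
    read_phenotype,
    write_abundance_table,
    write_design,
    write_genotypes,
    write_network,
    write_phenotype,
)
from .interaction_networks import (
    ClassifierConfig,
    assign_roles,
    check_ecological_hypotheses,
    classify_pairs,
    estimate_pair_effects,
)
from .network_properties import build_property_table
from .hub_heritability import detect_hubs, estimate_H2, heritable_hubs
from .association import (
    build_structure,
    average_replicates,
    scan,
    select_model,
    significant_snps,
    candidate_windows,
)
from .qtl_bayes_net import hub_qtls, learn_dag
from .path_analysis import decompose_all
from .synthetic_data import (
    AbundanceQtl,
    FecundityModel,
    InteractionQtl,
    SimulationConfig,
    simulate_community,
    simulate_fecundity,
    simulate_genotypes,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "networks", "properties", "hubs", "heritability",
          "gwas", "bn", "path")

# Desk-scale defaults for the simulate stage of a full pipeline run: small
# enough for a complete run-all on one CPU in minutes, with planted abundance
# QTLs and a fecundity model so every downstream stage has signal to find.
# Used only when no ``simulation`` block is configured; a user-provided block
# replaces it entirely (its QTL indices assume these SNP/OTU counts).
DEFAULT_SIMULATION: dict = {
    "n_accessions": 100,
    "n_replicates": 2,
    "sites": ("SU", "SR"),
    "years": (2012,),
    "n_snps": 300,
    "n_bacteria": 8,
    "n_fungi": 8,
    "abundance_qtls": [
        {"snp": 17, "otu": 0, "h2": 0.40},
        {"snp": 101, "otu": 3, "h2": 0.35},
        {"snp": 223, "otu": 9, "h2": 0.35},
    ],
    "fecundity": {
        "direct_snps": {17: 0.5, 259: 0.4},
        "mediators": {"mutualism.Con": 0.4, "antagonism.P": -0.3},
        "residual_sd": 1.0,
    },
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path: Path, seed: int, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# leafnetmap v{__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str
    rng_seed: int = 1
    abundance: str | None = None       # input paths; None => simulate stage
    genotypes: str | None = None
    design: str | None = None
    fecundity: str | None = None
    simulation: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    n_top_bacteria: int | None = None  # optional top-OTU pre-selection
    n_top_fungi: int | None = None
    gwas_model: str = "auto"
    gwas_maf_min: float = 0.05
    gwas_alpha: float = 0.05
    gwas_method: str = "bonferroni"
    structure_k: int = 3
    hub_quantile: float = 0.90
    bn_restarts: int = 10
    bn_max_nodes: int = 30
    window_bp: int = 10_000
    r2_min: float = 0.8

    KNOWN_KEYS = None  # filled after definition

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "out_dir" not in d:
            raise ValueError("configuration requires out_dir")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def simulation_config(self) -> SimulationConfig:
        d = dict(self.simulation) if self.simulation else dict(DEFAULT_SIMULATION)
        aq = [AbundanceQtl(**q) for q in d.pop("abundance_qtls", [])]
        iq = [InteractionQtl(**q) for q in d.pop("interaction_qtls", [])]
        fm = FecundityModel(**{
            **d.pop("fecundity", {}),
        }) if "fecundity" in d or True else FecundityModel()
        fm.direct_snps = {int(k): float(v) for k, v in fm.direct_snps.items()}
        cfg = SimulationConfig(rng_seed=stage_seed(self.rng_seed, "simulate"),
                               abundance_qtls=aq, interaction_qtls=iq,
                               fecundity=fm, **d)
        return cfg

    def classifier_config(self, seed: int) -> ClassifierConfig:
        return ClassifierConfig(rng_seed=seed, **self.classifier)


class PipelineHalt(RuntimeError):
    pass


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data: dict = {"version": __version__, "stages": {}}
        if self.path.exists():
            try:
                self.data = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                pass

    def stage_up_to_date(self, stage: str, config_key: str, inputs: dict[str, str]) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None or rec.get("config") != config_key or rec.get("inputs") != inputs:
            return False
        for f, digest in rec.get("outputs", {}).items():
            p = Path(f)
            if not p.exists():
                return False
            if _sha256(p) != digest:
                raise PipelineHalt(
                    f"stage {stage}: checksum mismatch on intermediate file {f}"
                )
        return True

    def record(self, stage: str, config_key: str, inputs: dict[str, str],
               outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "config": config_key,
            "inputs": inputs,
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_all(cfg: PipelineConfig, force: bool = False) -> Path:
    """Run every stage in dependency order; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    config_key = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()

    # ---- stage: simulate (or load inputs) -------------------------------
    paths = {
        "abundance": out / "abundance.tsv",
        "design": out / "design.csv",
        "genotypes": out / "genotypes.tsv",
        "fecundity": out / "fecundity.tsv",
        "truth": out / "truth.json",
    }
    simulate_needed = cfg.abundance is None
    if simulate_needed:
        stage = "simulate"
        if force or not manifest.stage_up_to_date(stage, config_key, {}):
            logger.info("stage simulate: generating synthetic dataset")
            sim_cfg = cfg.simulation_config()
            gen = simulate_genotypes(sim_cfg)
            table, design, truth = simulate_community(sim_cfg, gen)
            write_abundance_table(table, paths["abundance"])
            write_design(design, paths["design"])
            write_genotypes(gen, paths["genotypes"])
            truth.to_json(paths["truth"])
            # fecundity needs properties; deferred below if mediators requested,
            # otherwise direct-only fecundity can be written now.  We always
            # defer to keep a single code path.
            manifest.record(stage, config_key, {}, [
                paths["abundance"], paths["design"], paths["genotypes"], paths["truth"],
            ])
        else:
            logger.info("stage simulate: up to date")
        table = read_abundance_table(paths["abundance"])
        design = read_design(paths["design"])
        gen = read_genotypes(paths["genotypes"], format="dosage_tsv")
    else:
        table = read_abundance_table(cfg.abundance)
        design = read_design(cfg.design)
        gen = read_genotypes(cfg.genotypes)

    # ---- stage: networks ------------------------------------------------
    stage = "networks"
    seed = stage_seed(cfg.rng_seed, stage)
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    networks: dict[tuple[str, int], dict] = {}
    roles_rows = []
    hypo_rows = []
    for site, year in design.experiments():
        samples = [s for s in design.samples_in(site, year) if s in set(table.sample_ids)]
        if len(samples) < 10:
            continue
        sub = table.subset_samples(samples)
        ccfg = cfg.classifier_config(seed)
        pairs = estimate_pair_effects(sub, ccfg)
        nets = classify_pairs(pairs, sub, ccfg, experiment=(site, year))
        for t, net in nets.items():
            assign_roles(net, ccfg)
            write_network(net, net_dir / f"{site}_{year}_{t}.graphml")
            for node, role in net.roles.items():
                roles_rows.append({"experiment": f"{site}_{year}", "network_type": t,
                                   "otu": node, "role": role})
        for chk in check_ecological_hypotheses(nets, ccfg):
            hypo_rows.append({"experiment": f"{site}_{year}",
                              "network_type": chk.network_type,
                              "comparison": chk.comparison, "ratio": chk.ratio,
                              "threshold": chk.threshold, "passed": chk.passed})
        networks[(site, year)] = nets
        logger.info("experiment %s_%s: edges per type %s", site, year,
                    {t: n.graph.number_of_edges() for t, n in nets.items()})
    write_tsv(pd.DataFrame(roles_rows), out / "roles.tsv", cfg.rng_seed)
    write_tsv(pd.DataFrame(hypo_rows), out / "hypothesis_report.tsv", cfg.rng_seed)

    # ---- stage: properties ---------------------------------------------
    props = build_property_table(networks, table, design)
    prop_df = props.standardized.copy()
    write_tsv(props.values, out / "properties_raw.tsv", cfg.rng_seed, index=True)
    write_tsv(prop_df, out / "properties.tsv", cfg.rng_seed, index=True)

    # ---- fecundity (simulated case: needs properties) -------------------
    if simulate_needed:
        sim_cfg = cfg.simulation_config()
        fec, _ = simulate_fecundity(sim_cfg, gen, props, design)
        write_phenotype(fec, paths["fecundity"])
    else:
        fec = read_phenotype(cfg.fecundity)

    # ---- stage: hubs + heritability -------------------------------------
    hubs = detect_hubs(networks, quantile=cfg.hub_quantile)
    write_tsv(hubs.table, out / "hubs.tsv", cfg.rng_seed)
    write_tsv(hubs.occurrence.reset_index(), out / "hub_occurrence.tsv", cfg.rng_seed)
    h2 = estimate_H2(table, design)
    write_tsv(h2.table, out / "heritability.tsv", cfg.rng_seed)
    write_tsv(heritable_hubs(hubs, h2), out / "heritable_hubs.tsv", cfg.rng_seed)

    # ---- stage: gwas -----------------------------------------------------
    sm = build_structure(gen, k=cfg.structure_k)
    lam_rows = []
    sig_frames = []
    traits_of: dict[str, set[str]] = {}
    pheno_acc = average_replicates(prop_df.dropna(axis=1, how="all"), design)
    pheno_acc = pheno_acc.dropna(axis=1, how="any")
    pheno_acc = pheno_acc.loc[:, pheno_acc.std(ddof=0) > 0]  # constant traits untestable
    models = ("naive", "Q", "QK") if cfg.gwas_model == "auto" else (cfg.gwas_model,)
    per_model = {m: scan(pheno_acc, gen, sm, model=m, maf_min=cfg.gwas_maf_min)
                 for m in models}
    for trait in pheno_acc.columns:
        by_model = {m: per_model[m][trait] for m in models}
        for m, res in by_model.items():
            lam_rows.append({"trait": trait, "model": m, "lambda": res.lambda_gc})
        chosen = select_model(by_model) if len(by_model) > 1 else models[0]
        res = by_model[chosen]
        var_y = float(np.var(pheno_acc[trait].to_numpy(dtype=float)))
        sig = significant_snps(res, var_y, method=cfg.gwas_method, alpha=cfg.gwas_alpha)
        if len(sig):
            sig.insert(0, "trait", trait)
            sig.insert(1, "model", chosen)
            sig_frames.append(sig)
            for s in sig["snp_id"]:
                traits_of.setdefault(s, set()).add(trait)
    sig_all = (pd.concat(sig_frames, ignore_index=True) if sig_frames
               else pd.DataFrame(columns=["trait", "model", "snp_id", "chrom", "pos",
                                          "maf", "beta", "se", "stat", "p", "h2"]))
    write_tsv(pd.DataFrame(lam_rows), out / "lambda.tsv", cfg.rng_seed)
    write_tsv(sig_all, out / "significant.tsv", cfg.rng_seed)
    lead_snps = list(dict.fromkeys(sig_all["snp_id"])) if len(sig_all) else []
    windows = candidate_windows(lead_snps, gen, w=cfg.window_bp, r2_min=cfg.r2_min) \
        if lead_snps else []
    win_df = pd.DataFrame([
        {"lead_snp": w.lead_snp, "chrom": w.chrom, "start": w.start, "end": w.end,
         "n_members": len(w.members)} for w in windows
    ])
    write_tsv(win_df, out / "windows.tsv", cfg.rng_seed)
    logger.info("gwas: %d SNPs significant across %d traits",
                len(lead_snps), len(pheno_acc.columns))

    # ---- stage: bn -------------------------------------------------------
    stage_bn_seed = stage_seed(cfg.rng_seed, "bn")
    if len(lead_snps) >= 2:
        top = (sig_all.sort_values("p").drop_duplicates("snp_id")
               .head(cfg.bn_max_nodes)["snp_id"].tolist())
        dag = learn_dag(gen.subset_snps(top), restarts=cfg.bn_restarts,
                        rng_seed=stage_bn_seed)
        hub_df = hub_qtls(dag, quantile=cfg.hub_quantile, traits_of=traits_of)
        edges_df = pd.DataFrame(sorted(dag.edges), columns=["source", "target"])
    else:
        hub_df = pd.DataFrame(columns=["snp_id", "degree", "is_hub", "pleiotropic"])
        edges_df = pd.DataFrame(columns=["source", "target"])
    write_tsv(edges_df, out / "qtl_dag_edges.tsv", cfg.rng_seed)
    write_tsv(hub_df, out / "hub_qtls.tsv", cfg.rng_seed)

    # ---- stage: path -----------------------------------------------------
    fec_acc = average_replicates(fec.to_frame("fecundity"), design)["fecundity"]
    if lead_snps:
        gsub = gen.subset_snps(lead_snps)
        gframe = pd.DataFrame(gsub.imputed(), index=gsub.accession_ids,
                              columns=gsub.snp_ids)
        path_df = decompose_all(gframe, pheno_acc, fec_acc)
    else:
        path_df = pd.DataFrame(columns=["snp_id", "mediator_id", "r_gy", "r_yz",
                                        "r_gz", "p_direct", "p_indirect",
                                        "direct_sign", "indirect_sign", "flagged"])
    write_tsv(path_df, out / "paths.tsv", cfg.rng_seed)

    manifest.record("run_all", config_key, {}, [
        out / "roles.tsv", out / "hypothesis_report.tsv", out / "properties.tsv",
        out / "hubs.tsv", out / "heritability.tsv", out / "lambda.tsv",
        out / "significant.tsv", out / "paths.tsv",
    ])
    return out
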