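"""End-to-end pipeline: simulate -> QC -> responses -> scans -> cascade ->
annotation -> GWAS overlap, with a structured config and a run manifest.

Every stage writes fixed-schema TSVs into the output directory; the
manifest records the verbatim config, the seed, input checksums, and
per-stage row counts. With a fixed seed the whole result directory is
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .containers import (
    AR_EXPRESSED,
    AR_NULL,
    DHT,
    DUAL,
    ENZ,
    VEH,
    GenotypeMatrix,
)
from .annotation import annotate_snps
from .eqtl import PgxEqtlResults, ScanParams, enumerate_cis_pairs, run_scan
from .expression import ExpressionFilterParams, build_responses, classify_ar_status, filter_low_count_genes
from .filters import SignalSet, apply_cascade, audit_table, direction_concordance
from .genotype_qc import QcThresholds, filter_genotypes
from .gwas import circos_locus_table, enrichment_test, group_loci, match_gwas
from .simulate import AR_GENE, PlantedEffect, SimulationConfig, simulate_study

log = logging.getLogger(__name__)

SCAN_CONDITIONS = (DHT, ENZ, DUAL)


@dataclass
class GwasOptions:
    r2_min: float = 0.8
    proxy_window: int = 500_000
    locus_gap: int = 1_000_000
    hit_threshold: float = 0.005
    strict_hits: bool = False


@dataclass
class PipelineConfig:
    """All stage parameters plus input paths / simulate-mode options."""

    seed: int = 0
    simulate: bool = True
    auto_effects: dict[str, int] = field(default_factory=dict)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    expression: ExpressionFilterParams = field(default_factory=ExpressionFilterParams)
    scan: ScanParams = field(default_factory=ScanParams)
    gwas: GwasOptions = field(default_factory=GwasOptions)
    hwe_per_subset: bool = True  # QC within each cell subset, not the full panel
    inputs: dict[str, str] = field(default_factory=dict)  # paths when simulate=False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["effect_table"] = [dataclasses.asdict(e) for e in self.sim.effect_table]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.get("sim", {}))
        effects = [PlantedEffect(**e) for e in sim.pop("effect_table", [])]
        for key in ("maf_range", "nb_mean_range", "library_size_range"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        return cls(
            seed=d.get("seed", 0),
            simulate=d.get("simulate", True),
            auto_effects=dict(d.get("auto_effects", {})),
            sim=SimulationConfig(effect_table=effects, **sim),
            qc=QcThresholds(**d.get("qc", {})),
            expression=ExpressionFilterParams(**d.get("expression", {})),
            scan=ScanParams(**d.get("scan", {})),
            gwas=GwasOptions(**d.get("gwas", {})),
            hwe_per_subset=d.get("hwe_per_subset", True),
            inputs=dict(d.get("inputs", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    """In-memory view of one full run (the TSVs mirror these tables)."""

    config: PipelineConfig
    ar_status: pd.DataFrame
    qc_reports: dict[str, pd.DataFrame]
    scans: dict[tuple[str, str], PgxEqtlResults]  # (cell_set, condition)
    cascades: dict[str, SignalSet]  # condition -> filtered signal set
    annotation: pd.DataFrame
    gwas_matches: pd.DataFrame
    loci: pd.DataFrame
    enrichment: pd.DataFrame
    manifest: dict


def _load_inputs(config: PipelineConfig):
    paths = config.inputs
    try:
        genotypes = (
            pio.read_vcf(paths["vcf"]) if "vcf" in paths else pio.read_dosage_tsv(paths["dosage"])
        )
        counts = {
            cond: pio.read_counts(paths[f"counts_{cond.lower()}"], cond)
            for cond in (VEH, DHT, ENZ, DUAL)
        }
        peaks = pio.read_bed(paths["peaks"])
        chromhmm = pio.read_chromhmm(paths["chromhmm"])
        gwas = pio.read_gwas(
            paths["gwas"],
            hit_threshold=config.gwas.hit_threshold,
            strict=config.gwas.strict_hits,
        )
        gene_models = pio.read_gene_models(paths["gene_models"])
    except KeyError as exc:
        raise StageError("load", f"missing input path {exc}") from exc
    return genotypes, gene_models, counts, peaks, chromhmm, gwas


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    outdir = Path(outdir) if outdir is not None else None
    manifest: dict = {"config": config.to_dict(), "seed": config.seed, "stages": {}}

    # -- acquire data --------------------------------------------------------
    if config.simulate:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        study = simulate_study(sim_cfg, auto_effects=config.auto_effects or None)
        config = dataclasses.replace(config, sim=study.config)
        manifest["config"] = config.to_dict()
        genotypes = study.genotypes
        gene_models = study.gene_models
        counts = study.counts
        peaks, chromhmm, gwas = study.peaks, study.chromhmm, study.gwas
        gwas.hit_threshold = config.gwas.hit_threshold
        gwas.strict = config.gwas.strict_hits
        truth = study.truth_table()
    else:
        genotypes, gene_models, counts, peaks, chromhmm, gwas = _load_inputs(config)
        truth = pd.DataFrame()
        manifest["input_checksums"] = {
            k: pio.sha256_of(v) for k, v in sorted(config.inputs.items())
        }

    if DUAL not in counts:
        raise StageError("reversibility", "dual-treatment counts are required")

    # -- AR status -----------------------------------------------------------
    if AR_GENE not in counts[VEH].gene_ids:
        raise StageError("ar_status", f"receptor gene {AR_GENE!r} absent from counts")
    ar_status = classify_ar_status(
        {cond: cm.counts.loc[AR_GENE] for cond, cm in counts.items()}, config.expression
    )
    cell_sets = {
        AR_EXPRESSED: ar_status.loc[ar_status["label"] == AR_EXPRESSED, "cell_id"].tolist(),
        AR_NULL: ar_status.loc[ar_status["label"] == AR_NULL, "cell_id"].tolist(),
    }
    for name, cells in cell_sets.items():
        if not cells:
            raise StageError("ar_status", f"no cells classified {name}")

    # -- genotype QC per cell subset ----------------------------------------
    qc_reports: dict[str, pd.DataFrame] = {}
    qc_genotypes: dict[str, GenotypeMatrix] = {}
    for name, cells in cell_sets.items():
        subset = cells if config.hwe_per_subset else genotypes.cell_ids
        filtered, report = filter_genotypes(genotypes, config.qc, subset)
        qc_reports[name] = report
        qc_genotypes[name] = filtered
    manifest["stages"]["qc"] = {
        name: int(rep["kept"].sum()) for name, rep in qc_reports.items()
    }

    # -- responses -----------------------------------------------------------
    retained_genes, gene_report = filter_low_count_genes(counts, config.expression)
    retained_genes = [g for g in retained_genes if g != AR_GENE]
    if not retained_genes:
        raise StageError("respond", "no genes survive the low-count filter")
    responses = build_responses(counts, config.expression, gene_subset=retained_genes)
    manifest["stages"]["respond"] = {"genes_retained": len(retained_genes)}

    # -- scans: 2 cell sets x 3 conditions ----------------------------------
    gene_by_id = {g.gene_id: g for g in gene_models}
    scan_models = [gene_by_id[g] for g in retained_genes if g in gene_by_id]
    scans: dict[tuple[str, str], PgxEqtlResults] = {}
    pairs_by_set: dict[str, pd.DataFrame] = {}
    for name in (AR_EXPRESSED, AR_NULL):
        pairs = enumerate_cis_pairs(scan_models, qc_genotypes[name].snp_meta, config.scan)
        pairs_by_set[name] = pairs
        for cond in SCAN_CONDITIONS:
            resp = responses[cond].subset_cells(cell_sets[name])
            scans[(name, cond)] = run_scan(
                resp, qc_genotypes[name], pairs, config.scan, cell_set=name
            )
    manifest["stages"]["scan"] = {
        f"{name}:{cond}": {
            "tested": scans[(name, cond)].n_tested,
            "significant": scans[(name, cond)].n_significant,
            "lambda": round(scans[(name, cond)].lambda_gc(), 4)
            if scans[(name, cond)].n_tested
            else None,
        }
        for (name, cond) in scans
    }

    # -- filter cascade per drug condition ----------------------------------
    cascades: dict[str, SignalSet] = {}
    for cond in (DHT, ENZ):
        cascades[cond] = apply_cascade(
            scans[(AR_EXPRESSED, cond)],
            scans[(AR_NULL, cond)],
            scans[(AR_EXPRESSED, DUAL)],
            peaks,
            qc_genotypes[AR_EXPRESSED],
            config.scan.p_threshold,
        )
    manifest["stages"]["cascade"] = {
        cond: {"significant": len(s.table), "survivors": len(s.survivors())}
        for cond, s in cascades.items()
    }
    shared, same_dir = direction_concordance(cascades[DHT], cascades[ENZ])
    manifest["stages"]["cascade"]["dht_enz_shared"] = shared
    manifest["stages"]["cascade"]["dht_enz_same_direction"] = same_dir

    # -- annotation of survivors --------------------------------------------
    survivor_pairs = pd.concat(
        [s.survivors()[["snp_id", "gene_id"]] for s in cascades.values()],
        ignore_index=True,
    ).drop_duplicates()
    annotation = annotate_snps(
        genotypes.snp_meta, survivor_pairs, gene_by_id, chromhmm
    )
    manifest["stages"]["annotate"] = {"pairs": len(annotation)}

    # -- GWAS overlap + enrichment ------------------------------------------
    survivor_snps = sorted(set(survivor_pairs["snp_id"]))
    matches = match_gwas(
        survivor_snps, gwas, genotypes, config.gwas.r2_min, config.gwas.proxy_window
    )
    matched_snps = set(matches["eqtl_snp"])
    sig_rows = []
    for cond, s in cascades.items():
        surv = s.survivors()
        surv = surv.loc[surv["snp_id"].isin(matched_snps)]
        for rec in surv.itertuples():
            meta = genotypes.snp_meta.loc[rec.snp_id]
            sig_rows.append(
                {
                    "snp_id": rec.snp_id,
                    "chrom": meta["chrom"],
                    "pos": int(meta["pos"]),
                    "gene_id": rec.gene_id,
                    "p_value": rec.p_value,
                    "in_peak": bool(rec.in_peak),
                    "condition": cond,
                }
            )
    matched_signals = pd.DataFrame(
        sig_rows,
        columns=["snp_id", "chrom", "pos", "gene_id", "p_value", "in_peak", "condition"],
    )
    loci = group_loci(matched_signals, config.gwas.locus_gap)

    # enrichment universe: SNPs that entered the scan after QC
    universe = qc_genotypes[AR_EXPRESSED].snp_ids
    survivor_snp_set = set(survivor_snps)
    eqtl_flags = np.array([s in survivor_snp_set for s in universe])
    hits = gwas.hits()
    enr_rows = []
    for study in sorted(set(gwas.table["study"])):
        hit_ids = set(hits.loc[hits["study"] == study, "snp_id"])
        gwas_flags = np.array([s in hit_ids for s in universe])
        enr = enrichment_test(eqtl_flags, gwas_flags)
        enr_rows.append(
            {
                "study": study,
                "a": enr.a,
                "b": enr.b,
                "c": enr.c,
                "d": enr.d,
                "odds_ratio": enr.odds_ratio,
                "p_value": enr.p_value,
                "defined": enr.defined,
            }
        )
    enrichment = pd.DataFrame(
        enr_rows,
        columns=["study", "a", "b", "c", "d", "odds_ratio", "p_value", "defined"],
    )
    manifest["stages"]["gwas"] = {
        "matches": len(matches),
        "loci": len(loci),
        "enrichment_or": [
            None if not r["defined"] else round(r["odds_ratio"], 4) for r in enr_rows
        ],
    }

    result = PipelineResult(
        config=config,
        ar_status=ar_status,
        qc_reports=qc_reports,
        scans=scans,
        cascades=cascades,
        annotation=annotation,
        gwas_matches=matches,
        loci=loci,
        enrichment=enrichment,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, truth, genotypes, peaks, chromhmm, gwas, counts, outdir)
    return result


def _write_outputs(result, truth, genotypes, peaks, chromhmm, gwas, counts, outdir: Path):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    if cfg.simulate:
        simdir = outdir / "simulated_inputs"
        pio.write_vcf(genotypes, simdir / "genotypes.vcf")
        pio.write_dosage_tsv(genotypes, simdir / "genotypes_dosage.tsv")
        for cond, cm in counts.items():
            pio.write_counts(cm, simdir / f"counts_{cond}.tsv")
        pio.write_bed(peaks, simdir / "peaks.bed")
        pio.write_chromhmm(chromhmm, simdir / "chromhmm.tsv")
        pio.write_gwas(gwas, simdir / "gwas.tsv")
        pio.write_table(truth, simdir / "planted_truth.tsv", "planted_truth")
    pio.write_table(result.ar_status, outdir / "ar_status.tsv", "ar_status")
    for name, rep in result.qc_reports.items():
        pio.write_table(rep, outdir / f"qc_report_{name}.tsv", "qc_report")
    for (name, cond), res in result.scans.items():
        pio.write_table(res.signals, outdir / f"scan_{name}_{cond}.tsv", "scan")
        pio.write_table(
            res.miami_table(genotypes.snp_meta), outdir / f"miami_{name}_{cond}.tsv", "miami"
        )
    for cond, s in result.cascades.items():
        pio.write_table(audit_table(s), outdir / f"cascade_{cond}.tsv", "cascade_audit")
    pio.write_table(result.annotation, outdir / "annotation.tsv", "annotation")
    pio.write_table(result.gwas_matches, outdir / "gwas_matches.tsv", "gwas_matches")
    pio.write_table(result.loci, outdir / "loci.tsv", "loci")
    pio.write_table(circos_locus_table(result.loci), outdir / "circos_loci.tsv", "circos")
    pio.write_table(result.enrichment, outdir / "enrichment.tsv", "enrichment")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
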