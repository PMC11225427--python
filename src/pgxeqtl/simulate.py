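"""Synthetic study generator with planted, recoverable ground truth.

Emulates the full experimental design the pipeline expects: a 30-cell
panel (15 receptor-expressing, 15 receptor-null), four treatment
conditions (vehicle, agonist, antagonist, dual), LD-blocked genotypes in
Hardy-Weinberg equilibrium, negative-binomial RNA-seq counts with planted
genotype x treatment interaction effects, ChIP-seq peaks covering effect
SNPs, multi-tissue chromatin-state calls, and GWAS hits placed on planted
SNPs or their LD proxies. Every downstream stage therefore has a known
truth table to recover.

Haplotype LD scheme: within a block all SNPs share the block's minor
allele frequency; each haplotype copies the previous SNP's allele with
probability sqrt(ld_decay) and otherwise draws fresh, giving adjacent
r^2 ~= ld_decay and r^2 ~= ld_decay**distance within the block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    DHT,
    DUAL,
    ENZ,
    VEH,
    ChromHmmTable,
    CountMatrix,
    GeneModel,
    GenotypeMatrix,
    GwasTable,
    PeakSet,
)
from .annotation import (
    ENHANCER_CAT,
    REPRESSED_CAT,
    STATE_VOCABULARY,
    TRANSCR_CAT,
    TSS_CAT,
    collapse_state,
)
from .gwas import ld_r2

AR_GENE = "AR"

EFFECT_CONDITIONS = ("DHT", "ENZ", "BOTH_NONREVERSIBLE", "AR_INDEPENDENT")

# condition label -> (count conditions carrying the shift, AR-expressed only?)
_EFFECT_SCOPE = {
    "DHT": ((DHT,), True),
    "ENZ": ((ENZ,), True),
    "BOTH_NONREVERSIBLE": ((DHT, ENZ, DUAL), True),
    "AR_INDEPENDENT": ((DHT, ENZ), False),
}


@dataclass(frozen=True)
class PlantedEffect:
    """One genotype-dependent drug-response effect written into the counts.

    ``condition`` names the effect class, not just the count condition:
    DHT/ENZ effects appear only in receptor-expressing cells and vanish
    under dual treatment (reversible); BOTH_NONREVERSIBLE persists under
    dual treatment; AR_INDEPENDENT appears in receptor-null cells too
    (but stays reversible, so only the null-control filter catches it).
    ``beta`` is the per-minor-allele log2 fold-change shift.
    """

    snp_id: str
    gene_id: str
    condition: str
    beta: float = 2.0
    direction: int = 1

    def __post_init__(self) -> None:
        if self.condition not in EFFECT_CONDITIONS:
            raise ValueError(f"unknown effect condition {self.condition!r}")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class SimulationConfig:
    n_cells_ar_pos: int = 15
    n_cells_ar_null: int = 15
    n_snps: int = 60
    n_genes: int = 40
    maf_range: tuple[float, float] = (0.2, 0.5)
    ld_block_size: int = 5
    ld_decay: float = 0.8
    nb_mean_range: tuple[float, float] = (64.0, 4096.0)
    nb_dispersion: float = 0.05
    library_size_range: tuple[float, float] | None = None  # None: genes keep nb_mean scale
    effect_table: list[PlantedEffect] = field(default_factory=list)
    peak_fraction: float = 0.3
    missing_rate: float = 0.002  # array-grade call rate (~99.8%)
    snp_spacing: int = 20_000
    n_chromosomes: int = 2
    n_tissues: int = 5
    tissue_dominance: float = 0.8
    gwas_background_hit_rate: float = 0.01
    gwas_proxy_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells_ar_pos, self.n_cells_ar_null, self.n_snps, self.n_genes) <= 0:
            raise ValueError("panel dimensions must be positive")
        if not 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.ld_decay <= 1.0:
            raise ValueError("ld_decay must lie in [0, 1]")
        if self.n_chromosomes < 2:
            raise ValueError("at least two synthetic autosomes required")

    @property
    def cell_ids(self) -> list[str]:
        pos = [f"LCL_P{i + 1:02d}" for i in range(self.n_cells_ar_pos)]
        null = [f"LCL_N{i + 1:02d}" for i in range(self.n_cells_ar_null)]
        return pos + null

    @property
    def ar_pos_cells(self) -> list[str]:
        return self.cell_ids[: self.n_cells_ar_pos]

    @property
    def ar_null_cells(self) -> list[str]:
        return self.cell_ids[self.n_cells_ar_pos:]


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """LD-blocked HWE genotypes with missingness on >=2 synthetic autosomes."""
    rng = _rng(config, 1)
    cells = config.cell_ids
    n_hap = 2 * len(cells)
    copy_p = float(np.sqrt(config.ld_decay))

    haps = np.empty((n_hap, config.n_snps), dtype=np.int8)
    block_of = np.arange(config.n_snps) // config.ld_block_size
    block_maf = rng.uniform(*config.maf_range, size=block_of.max() + 1)
    for j in range(config.n_snps):
        maf = block_maf[block_of[j]]
        fresh = rng.random(n_hap) < maf
        if j > 0 and block_of[j] == block_of[j - 1]:
            copy = rng.random(n_hap) < copy_p
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
        else:
            haps[:, j] = fresh
    dosage = (haps[0::2] + haps[1::2]).astype(float)

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    snp_ids = [f"rs{j + 1:06d}" for j in range(config.n_snps)]
    per_chrom = int(np.ceil(config.n_snps / config.n_chromosomes))
    chroms = [f"chr{1 + j // per_chrom}" for j in range(config.n_snps)]
    pos = [1_000_000 + (j % per_chrom) * config.snp_spacing for j in range(config.n_snps)]
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": "A", "alt": "G"}, index=snp_ids
    )
    return GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=cells, columns=snp_ids), snp_meta=meta
    )


def make_gene_models(config: SimulationConfig, genotypes: GenotypeMatrix) -> list[GeneModel]:
    """Gene models interleaved with the SNPs so cis windows are populated."""
    rng = _rng(config, 2)
    meta = genotypes.snp_meta
    genes: list[GeneModel] = []
    chrom_list = sorted(meta["chrom"].unique())
    per_chrom = int(np.ceil(config.n_genes / len(chrom_list)))
    g = 0
    for chrom in chrom_list:
        span_lo = int(meta.loc[meta["chrom"] == chrom, "pos"].min())
        span_hi = int(meta.loc[meta["chrom"] == chrom, "pos"].max())
        n_here = min(per_chrom, config.n_genes - g)
        starts = np.linspace(span_lo, max(span_hi - 30_000, span_lo + 1), n_here).astype(int)
        for s in starts:
            g += 1
            length = int(rng.integers(5_000, 30_000))
            tx_start, tx_end = int(s), int(s) + length
            strand = "+" if rng.random() < 0.5 else "-"
            # three exons with UTRs at the transcript ends
            e1 = (tx_start, tx_start + length // 6)
            e2 = (tx_start + length // 3, tx_start + length // 2)
            e3 = (tx_end - length // 6, tx_end)
            utr_len = max(length // 20, 1)
            if strand == "+":
                utr5 = [(tx_start, tx_start + utr_len)]
                utr3 = [(tx_end - utr_len, tx_end)]
            else:
                utr5 = [(tx_end - utr_len, tx_end)]
                utr3 = [(tx_start, tx_start + utr_len)]
            genes.append(
                GeneModel(
                    gene_id=f"GENE{g:05d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=[e1, e2, e3],
                    utr5=utr5,
                    utr3=utr3,
                )
            )
        if g >= config.n_genes:
            break
    return genes


def plant_effects(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    genes: list[GeneModel],
    n_per_class: dict[str, int],
    beta: float = 2.0,
    min_maf: float = 0.3,
    cis_window: int = 200_000,
) -> list[PlantedEffect]:
    """Choose valid cis SNP-gene pairs for the requested effect-class mix.

    SNPs are drawn from distinct LD blocks with empirical MAF >= ``min_maf``
    so planted effects are testable and mutually independent; each pairs
    with a gene whose body lies within the cis window of the SNP.
    """
    rng = _rng(config, 3)
    meta = genotypes.snp_meta
    mafs = genotypes.dosage.apply(
        lambda col: np.nanmean(col) / 2.0 if np.isfinite(col).any() else np.nan
    )
    mafs = np.minimum(mafs, 1.0 - mafs)
    eligible = [s for s in genotypes.snp_ids if mafs[s] >= min_maf]
    rng.shuffle(eligible)
    by_gene_chrom: dict[str, list[GeneModel]] = {}
    for gm in genes:
        by_gene_chrom.setdefault(gm.chrom, []).append(gm)
    effects: list[PlantedEffect] = []
    used_blocks: set[int] = set()
    used_genes: set[str] = set()
    block_size = config.ld_block_size
    snp_index = {s: i for i, s in enumerate(genotypes.snp_ids)}
    queue = [(cls, i) for cls in EFFECT_CONDITIONS for i in range(n_per_class.get(cls, 0))]
    for cls, _ in queue:
        chosen = None
        for snp in eligible:
            blk = snp_index[snp] // block_size
            if blk in used_blocks:
                continue
            pos = int(meta.loc[snp, "pos"])
            cands = [
                gm for gm in by_gene_chrom.get(str(meta.loc[snp, "chrom"]), [])
                if gm.gene_id not in used_genes
                and gm.tx_start - cis_window <= pos <= gm.tx_end + cis_window
            ]
            if cands:
                chosen = (snp, cands[int(rng.integers(len(cands)))], blk)
                break
        if chosen is None:
            raise ValueError(f"no eligible cis SNP-gene pair left for class {cls}")
        snp, gm, blk = chosen
        used_blocks.add(blk)
        used_genes.add(gm.gene_id)
        eligible.remove(snp)
        effects.append(
            PlantedEffect(
                snp_id=snp,
                gene_id=gm.gene_id,
                condition=cls,
                beta=beta,
                direction=1 if rng.random() < 0.5 else -1,
            )
        )
    return effects


def _effect_shift_matrix(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    gene_ids: list[str],
    condition: str,
) -> np.ndarray:
    """log2-mean shift (genes x cells) contributed by the planted effects."""
    cells = config.cell_ids
    shift = np.zeros((len(gene_ids), len(cells)))
    if condition == VEH or not config.effect_table:
        return shift
    gene_row = {g: i for i, g in enumerate(gene_ids)}
    ar_pos = np.array([c in set(config.ar_pos_cells) for c in cells])
    for eff in config.effect_table:
        conds, pos_only = _EFFECT_SCOPE[eff.condition]
        if condition not in conds:
            continue
        if eff.gene_id not in gene_row:
            raise ValueError(f"planted effect references unknown gene {eff.gene_id!r}")
        if eff.snp_id not in genotypes.dosage.columns:
            raise ValueError(f"planted effect references unknown SNP {eff.snp_id!r}")
        d = genotypes.dosage[eff.snp_id].to_numpy(dtype=float)
        d = np.where(np.isnan(d), np.nanmean(d), d)  # truth uses mean-imputed dosage
        cell_mask = ar_pos if pos_only else np.ones(len(cells), dtype=bool)
        shift[gene_row[eff.gene_id]] += eff.beta * eff.direction * d * cell_mask
    return shift


def simulate_counts(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> dict[str, CountMatrix]:
    """Negative-binomial counts for all four conditions, truth written in.

    Counts are NB with variance mu + mu^2 * dispersion. Planted effects
    shift the log2 mean of their gene in the applicable condition(s) and
    cells by beta x dosage; the vehicle condition never carries an effect.
    The receptor gene ``AR`` is an ordinary extra row generated >=5 for
    receptor-expressing cells in at least one drug condition and <5 in all
    conditions for receptor-null cells.
    """
    rng = _rng(config, 4)
    gene_models_ids = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    gene_ids = gene_models_ids + [AR_GENE]
    cells = config.cell_ids
    base = np.exp(
        rng.uniform(np.log(config.nb_mean_range[0]), np.log(config.nb_mean_range[1]),
                    size=config.n_genes)
    )
    disp = config.nb_dispersion
    nb_n = 1.0 / disp  # scipy/numpy NB "successes" parameter

    ar_pos_mask = np.array([c in set(config.ar_pos_cells) for c in cells])
    out: dict[str, CountMatrix] = {}
    for condition in (VEH, DHT, ENZ, DUAL):
        shift = _effect_shift_matrix(config, genotypes, gene_models_ids, condition)
        mu = base[:, None] * np.power(2.0, shift)
        if config.library_size_range is not None:
            target = rng.uniform(*config.library_size_range, size=len(cells))
            mu = mu * (target / mu.sum(axis=0))
        else:
            mu = mu * rng.uniform(0.75, 1.25, size=len(cells))
        counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
        # receptor gene row with forced generation ranges
        ar_mu = np.where(ar_pos_mask, 60.0, 0.8)
        ar_row = rng.negative_binomial(nb_n, nb_n / (nb_n + ar_mu))
        ar_row = np.where(ar_pos_mask, np.maximum(ar_row, 5), np.minimum(ar_row, 4))
        counts = np.vstack([counts, ar_row[None, :]])
        out[condition] = CountMatrix(
            counts=pd.DataFrame(counts, index=gene_ids, columns=cells), condition=condition
        )
    return out


def simulate_regulome_and_gwas(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[PeakSet, ChromHmmTable, GwasTable]:
    """Peaks over effect SNPs, multi-tissue chromatin states, planted GWAS hits.

    Every planted-effect SNP is covered by a peak; other SNPs are covered
    with probability ``peak_fraction``. Each SNP gets a dominant chromatin
    category realised in ~``tissue_dominance`` of tissues. Each planted
    SNP receives one GWAS hit (p <= 0.005), placed on the SNP itself or,
    with probability ``gwas_proxy_prob``, on an in-block proxy with
    r^2 >= 0.8 when one exists; background SNPs get non-hit rows plus a
    small hit rate.
    """
    rng = _rng(config, 5)
    meta = genotypes.snp_meta
    effect_snps = [e.snp_id for e in config.effect_table]

    peak_rows = []
    for snp in genotypes.snp_ids:
        if snp in effect_snps or rng.random() < config.peak_fraction:
            pos = int(meta.loc[snp, "pos"])
            # 0-based half-open interval covering the SNP base
            peak_rows.append((meta.loc[snp, "chrom"], pos - 150, pos + 150, "sim_chip"))
    peaks = PeakSet(
        intervals=pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "source"])
    )

    by_cat = {
        TSS_CAT: [s for s in STATE_VOCABULARY if collapse_state(s) == TSS_CAT],
        TRANSCR_CAT: [s for s in STATE_VOCABULARY if collapse_state(s) == TRANSCR_CAT],
        ENHANCER_CAT: [s for s in STATE_VOCABULARY if collapse_state(s) == ENHANCER_CAT],
        REPRESSED_CAT: [s for s in STATE_VOCABULARY if collapse_state(s) == REPRESSED_CAT],
    }
    cats = list(by_cat)
    tissues = [f"tissue{i + 1}" for i in range(config.n_tissues)]
    ch_rows = []
    for snp in genotypes.snp_ids:
        dominant = cats[int(rng.integers(len(cats)))]
        for tissue in tissues:
            cat = dominant if rng.random() < config.tissue_dominance else cats[
                int(rng.integers(len(cats)))
            ]
            state = by_cat[cat][int(rng.integers(len(by_cat[cat])))]
            ch_rows.append((snp, tissue, state))
    chromhmm = ChromHmmTable(table=pd.DataFrame(ch_rows, columns=["snp_id", "tissue", "state"]))

    gwas_rows = []
    block_size = config.ld_block_size
    snp_index = {s: i for i, s in enumerate(genotypes.snp_ids)}
    for snp in genotypes.snp_ids:
        if snp in effect_snps:
            target = snp
            if rng.random() < config.gwas_proxy_prob:
                blk = snp_index[snp] // block_size
                mates = [
                    s for s in genotypes.snp_ids
                    if snp_index[s] // block_size == blk and s != snp
                ]
                proxies = [
                    m for m in mates
                    if ld_r2(
                        genotypes.dosage[snp].to_numpy(float),
                        genotypes.dosage[m].to_numpy(float),
                    ) >= 0.8
                ]
                if proxies:
                    target = proxies[int(rng.integers(len(proxies)))]
            p = float(np.exp(rng.uniform(np.log(1e-8), np.log(0.005))))
            gwas_rows.append(
                (target, meta.loc[target, "chrom"], int(meta.loc[target, "pos"]),
                 p, "synthetic_trait", "SIM_GWAS")
            )
        else:
            hit = rng.random() < config.gwas_background_hit_rate
            p = (
                float(np.exp(rng.uniform(np.log(1e-6), np.log(0.005))))
                if hit
                else float(rng.uniform(0.0051, 1.0))
            )
            gwas_rows.append(
                (snp, meta.loc[snp, "chrom"], int(meta.loc[snp, "pos"]),
                 p, "synthetic_trait", "SIM_GWAS")
            )
    gwas = GwasTable(
        table=pd.DataFrame(
            gwas_rows,
            columns=["snp_id", "chrom", "pos", "p_value", "phenotype", "study"],
        )
    )
    return peaks, chromhmm, gwas


@dataclass
class SimulatedStudy:
    """Everything one study run produces, plus its planted truth."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    gene_models: list[GeneModel]
    counts: dict[str, CountMatrix]
    peaks: PeakSet
    chromhmm: ChromHmmTable
    gwas: GwasTable

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp_id": e.snp_id,
                    "gene_id": e.gene_id,
                    "condition": e.condition,
                    "beta": e.beta,
                    "direction": e.direction,
                }
                for e in self.config.effect_table
            ],
            columns=["snp_id", "gene_id", "condition", "beta", "direction"],
        )


def simulate_study(
    config: SimulationConfig, auto_effects: dict[str, int] | None = None
) -> SimulatedStudy:
    """Full synthetic study; same seed => byte-identical outputs.

    ``auto_effects`` (class -> count) plants effects automatically when the
    config's effect_table is empty; the chosen effects are written back
    into the returned study's config.
    """
    genotypes = simulate_genotypes(config)
    genes = make_gene_models(config, genotypes)
    if auto_effects and not config.effect_table:
        config = replace(
            config,
            effect_table=plant_effects(config, genotypes, genes, auto_effects),
        )
    counts = simulate_counts(genotypes, config)
    peaks, chromhmm, gwas = simulate_regulome_and_gwas(genotypes, config)
    return SimulatedStudy(
        config=config,
        genotypes=genotypes,
        gene_models=genes,
        counts=counts,
        peaks=peaks,
        chromhmm=chromhmm,
        gwas=gwas,
    )
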