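# pgxeqtl

Drug-induced (pharmacogenomic) cis-eQTL discovery for cell-panel studies
of ligand-activated nuclear receptors.

## The problem

Many regulatory variants are silent at baseline and only change a gene's
expression once a transcription factor is pharmacologically activated or
blocked. In an androgen-receptor (AR) setting, a panel of lymphoblastoid
cell lines — half expressing AR, half effectively AR-null — is treated
with vehicle, an AR agonist (DHT), a partial antagonist (enzalutamide),
and both drugs together. A SNP whose genotype predicts the *response*
(log2 fold change over vehicle) rather than baseline expression is a
PGx-eQTL. This package implements that discovery pipeline for anyone
mapping genotype x drug interactions in a small cell panel: genotype QC,
response matrices, an ANOVA cis scan, a three-step specificity cascade,
regulatory annotation, and LD-aware GWAS overlap — plus a synthetic-data
generator with planted ground truth so every stage is testable end to end.

## The model

For each cis SNP-gene pair (SNP within gene body ± 200 kb, same
chromosome) and each drug condition, the per-cell response

    y_j = log2( (CPM_trt,j + c) / (CPM_veh,j + c) )

is tested against genotype class g_j ∈ {0, 1, 2} (minor-allele dosage,
treated as an unordered factor) with a one-way fixed-effects ANOVA:

    F = [ SSB / (k − 1) ] / [ SSW / (n − k) ],   p = P(F_{k−1, n−k} ≥ F)

where k is the number of genotype classes observed among the n cells with
non-missing calls. A per-minor-allele least-squares slope is reported as
the effect size; p ≤ 0.005 is the nominal significance gate, and the
genomic inflation factor λ = median(χ²₁-transform of p) / 0.4549 is the
calibration diagnostic.

Significant pairs from the AR-expressed scan then pass three independent
filters before being reported:

1. **receptor-null exclusion** — the same pair significant in the AR-null
   cells marks the signal AR-independent;
2. **reversibility** — a pair still significant under agonist+antagonist
   dual treatment is treatment-independent or ambiguous;
3. **binding-site overlap** — the SNP must fall inside at least one
   ChIP-seq peak.

Survivors are annotated with multi-tissue ChromHMM consensus categories
(TSS / Transcr / Enhancer / Repressed) and position relative to their gene,
then matched against GWAS hits either exactly or through LD proxies
(r² ≥ 0.8 computed from the study's own genotype panel), grouped into
loci, and tested for enrichment with Fisher's exact test.

Genotype QC mirrors the plink gate appropriate for 15–30 diploids:
MAF ≥ 0.2, missingness ≤ 5 %, and an exact conditional (Wigginton-style)
Hardy-Weinberg test at p > 0.001, evaluated separately per cell subset.

## Worked example

```python
from pgxeqtl import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    seed=11,
    sim=SimulationConfig(n_snps=160, n_genes=120, ld_block_size=4,
                         maf_range=(0.35, 0.5), nb_mean_range=(64, 512)),
    auto_effects={"DHT": 5, "ENZ": 5, "BOTH_NONREVERSIBLE": 1, "AR_INDEPENDENT": 1},
)
res = run_pipeline(cfg, "results/demo")
print(res.scans[("AR_EXPRESSED", "DHT")].summary())
```

prints

```
PGx-eQTL ANOVA scan
===================
condition        : DHT
cell set         : AR_EXPRESSED
cis pairs tested : 2272
untestable pairs : 0
significant (p<=0.005) : 29
genomic inflation lambda : 1.004
top signals:
  snp_id   gene_id  f_stat  p_value  effect_size
rs000037 GENE00034    94.2 4.62e-08         2.27
rs000038 GENE00034    94.2 4.62e-08         2.27
rs000151 GENE00120    81.1 1.07e-07         2.02
rs000090 GENE00062    76.9 1.43e-07        -2.39
rs000091 GENE00062    76.9 1.43e-07        -2.39
```

The scan tested 2,272 cis pairs in the 15 AR-expressed cells; λ ≈ 1.0
says the p-values are calibrated, and the top pairs are the planted
effects recovered at F ≈ 80–95 (adjacent SNPs such as rs000037/rs000038
tie because they sit in the same LD block). Downstream:

```
DHT: 29 significant -> 10 survive the cascade
ENZ: 28 significant -> 9 survive the cascade

   study  a  b  c   d  odds_ratio  p_value
SIM_GWAS  7 12  4 132       19.25 0.000033
```

The cascade removes the AR-independent, non-reversible, and off-peak
pairs; the surviving SNPs overlap the simulated GWAS hits far more often
than the rest of the tested panel (OR 19.3, Fisher p = 3.3e-5).

The same run is available from the shell:

```bash
pgxeqtl run-all --seed 11 --config config.yaml --out results/demo
```

with subcommands (`simulate`, `qc`, `respond`, `map-eqtl`, `filter`,
`annotate`, `gwas`) for stage-by-stage use. All outputs are fixed-schema
TSVs plus a JSON manifest; runs are byte-identical under a fixed seed.

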