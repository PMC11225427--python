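# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical conventions, and the design choices behind `pgxeqtl`. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design the package assumes

A panel of cell lines from genotyped donors, split into a
receptor-expressing half and a receptor-null half (the negative
controls), is profiled by RNA-seq under four conditions: vehicle,
agonist (DHT), partial antagonist (enzalutamide, "ENZ"), and the two
drugs combined ("DUAL"). Because agonist and antagonist compete for the
receptor, a genuinely receptor-driven response to either drug alone
should attenuate under dual treatment; a response that persists is
treatment-independent or ambiguous. Receptor-null cells carry the same
genotypes but no receptor signalling, so any association they reproduce
is receptor-independent. These two contrasts plus a binding-site
requirement form the specificity cascade.

## Expression processing

- **Gene gate.** A gene is excluded when, in at least one condition, at
  least `min_cells` (default 15) cells have raw counts below `min_count`
  (default 32). The gate runs on raw counts, before normalization.
- **Responses.** Counts are normalized to counts-per-million over each
  sample's own library size (computed after the gene gate), and the
  response is `log2((CPM_trt + c)/(CPM_veh + c))` per cell with a
  symmetric pseudocount `c = 0.5`. Plain CPM was chosen over TMM as the
  minimal reading of "normalized to library sizes"; the alternative
  ordering (raw-count ratio, library correction applied after) is a
  config option — the two differ only near zero counts.
- **Receptor status.** A cell is receptor-null iff its receptor-gene raw
  count stays below 5 in every condition (vehicle included; a cell that
  expresses the receptor only at baseline is still receptor-competent).

## Genotype QC

MAF, missingness, and Hardy-Weinberg are computed per SNP on the cell
subset being scanned (receptor-expressing and receptor-null halves are
filtered independently; a config flag switches to whole-panel
evaluation). Missing calls are excluded from the MAF and HWE
denominators (complete-case, the plink convention). The HWE test is the
exact conditional test on genotype counts — at 15–30 diploids the
chi-square approximation is invalid — summing the probabilities of all
heterozygote counts no more probable than the observed one, conditional
on the allele counts; ties are detected with a 1e-12 relative slack to
absorb float rounding. Defaults: MAF ≥ 0.2, missingness ≤ 5 %, HWE
p > 0.001. Note that at 15 cells the 5 % missingness bound removes any
SNP with a single missing call; with an array-grade call rate (~99.8 %,
the generator's default) this removes ~3 % of SNPs per subset and is the
dominant loss channel for otherwise-perfect signals.

## The ANOVA scan

Genotype enters as an unordered factor: dosages 0/1/2 are classes, not a
linear covariate, so dominant and heterotic patterns are detectable.
Classes with zero members are dropped and the degrees of freedom
adjusted; pairs with fewer than two observed classes or fewer than three
cells are reported "untestable" rather than silently omitted. Cells with
a missing call at the SNP are removed from that pair's test only. The
per-minor-allele least-squares slope is reported as the effect size but
never used for the p-value.

Numerical conventions:

- zero total variance → F = 0, p = 1 (guarded with a relative tolerance
  of 100·eps on the response scale so constant vectors survive float
  accumulation);
- zero residual variance with unequal group means (perfect separation) →
  F = ∞ and p clamped to the smallest positive normal double;
- the cis window is the gene body ± 200 kb with *inclusive* boundaries,
  anchored on the transcript extent, not the TSS;
- no multiple-testing correction is applied to the decision rule (the
  design filters biologically at nominal p ≤ 0.005); Benjamini-Hochberg
  FDR is emitted as an extra column for users.

The genomic inflation factor is
λ = median(χ²₁-quantile transform of p) / 0.45494, with the QQ table
pairing sorted observed −log10 p against (i − 0.5)/m expectations.

## Filter cascade

Each filter only *sets a flag* on the significant pairs of one drug
condition; the survivor set is the conjunction, so the three filters
commute by construction:

- `ar_null_hit`: the same (SNP, gene) significant (p ≤ 0.005) in the
  receptor-null scan of the same condition. Matching is exact, not
  LD-expanded — same genotyping panel, same pair universe. Pairs absent
  from the null scan (the SNP failed QC in that subset) are treated as
  not replicated and logged; removing them instead would punish signals
  for control-arm data loss.
- `nonreversible`: significant in the DUAL scan, regardless of effect
  direction (the definition names no direction test; a
  same-direction-only variant is a config flag).
- `in_peak`: the SNP's 1-based position falls inside at least one BED
  interval under half-open semantics — a peak `[start, end)` covers
  positions `start+1 … end`. Chromosome-name mismatches between SNPs and
  peaks raise a warning rather than silently yielding zero overlaps.

The descriptive DHT/ENZ sharing statistic counts pairs significant in
both conditions and concordant in sign of the reported effect size.

## Annotation

The 15 ChromHMM states collapse to four categories: TSS (1_TssA,
2_TssAFlnk), Transcr (3_TxFlnk, 4_Tx, 5_TxWk), Enhancer (6_EnhG, 7_Enh),
Repressed (all others). The per-SNP consensus over tissues is the modal
category; a two-way tie between active categories is reported losslessly
as `<catA>_<catB>_Mixed` in the fixed order TSS < Transcr < Enhancer; an
active/Repressed tie, or a three-way active tie, is `Ambiguous`; a
single-tissue SNP takes that tissue's category. Positional classes are
strand-aware: promoter = [TSS−3000, TSS) in transcription orientation
(checked before "upstream"), UTRs take precedence over coding exon,
which takes precedence over intron; outside the transcript the class is
upstream/downstream by strand-aware side. The classes are mutually
exclusive and exhaustive for any position on the gene's chromosome.

## GWAS overlap and enrichment

LD r² is the squared Pearson correlation of minor-allele dosages over
individuals complete for both SNPs, computed from a user-supplied panel
(the study cells by default) — no remote LD service, so results are
hermetic and seedable. A GWAS hit is a row with p ≤ 0.005 (strict <
available by flag). Matches are exact (same SNP id) or proxy (r² ≥ 0.8
within a 500 kb window — the window is a package choice, configurable).
Matched signals cluster into loci by single linkage with a 1 Mb gap; a
locus's top SNP is its smallest-p member, preferring SNPs inside a
ChIP-seq peak. Enrichment is Fisher's exact test (two-sided
hypergeometric) on the 2×2 table of survivor-SNP status against GWAS-hit
status over the universe of SNPs that entered the scan after QC —
conditioning on testability, the desk-scale analogue of a region-set
enrichment test. The odds ratio is the sample cross ratio with a Haldane
0.5 correction when a cell is zero; degenerate margins give p = 1 and an
undefined OR.

## Synthetic-data generator

The generator emulates the study design with known planted truth.

- **Genotypes.** Within LD blocks of `ld_block_size` SNPs sharing one
  MAF drawn from `maf_range`, each haplotype copies the previous SNP's
  allele with probability √`ld_decay` and otherwise draws fresh
  Bernoulli(MAF), giving adjacent r² ≈ ld_decay and r² ≈ ld_decay^d at
  distance d, with HWE holding by construction (two independent
  haplotypes per cell). Calls go missing at `missing_rate` (default
  0.002, an array-grade call rate). SNPs sit on ≥ 2 synthetic autosomes
  at fixed spacing; gene models are interleaved so cis windows are
  populated.
- **Counts.** Negative binomial with variance μ + μ²·disp
  (disp = 0.05, a typical cell-line dispersion) and gene baselines drawn
  log-uniformly from `nb_mean_range` (default 64–4096). A planted effect
  shifts the log2 mean of its gene by β × dosage in the applicable
  condition(s) and cells; vehicle never carries an effect. Effect
  classes: DHT/ENZ (receptor-expressing cells only, vanish under DUAL),
  BOTH_NONREVERSIBLE (persists under DUAL), AR_INDEPENDENT (appears in
  receptor-null cells too, reversible — so only the null-control filter
  catches it). The receptor gene is an ordinary extra count row with
  forced ranges (≥ 5 in at least one drug condition for expressing
  cells, < 5 everywhere for null cells) so the classifier is exercised
  end to end.
- **Regulome / GWAS.** Every planted-effect SNP is covered by a peak;
  others with probability `peak_fraction`. Each SNP has a dominant
  chromatin category realized in ~`tissue_dominance` of 5 tissues. Each
  planted SNP receives one GWAS hit, placed on the SNP itself or (with
  probability 0.5) on an in-block proxy with r² ≥ 0.8 when one exists;
  background SNPs receive non-hit rows plus a 1 % background hit rate,
  so the enrichment test has a realistic null margin.
- `plant_effects` draws effect SNPs from distinct LD blocks with
  empirical MAF ≥ 0.3 and never reuses a gene: two effects on one gene
  through different SNPs would each act as structured noise for the
  other and the planted β would no longer describe the realized
  separation.

What the generator does **not** emulate: read-level sequencing noise,
sequence content and mappability, population structure and relatedness,
batch effects, trans-regulation, and the composition bias of real
transcriptomes beyond simple library-size variation. Passing tests
therefore demonstrate the pipeline's correctness and calibration under
its own model assumptions, not robustness to those real-data artifacts.

One composition effect *is* present and matters at desk scale: with few
genes, a strongly shifted gene changes its sample's library total, and
CPM normalization then compresses the realized response below the
nominal β. Simulated studies that quantify planted-effect recovery use
enough genes (≥ 60) with bounded baselines (64–512) that a planted
effect perturbs the library total by only a few percent.

## Problem sizes used by tests and the acceptance script

Chosen to keep the suite fast while leaving the measured quantities
well-determined: the null-calibration study uses 4,000 SNPs × 2,000
genes (~170k–225k cis tests across the six scans); the recovery
experiment replicates a 24-SNP × 60-gene study (500 replicates in the
test suite, 150 in the acceptance script); the exhaustive Fisher check
covers all 2×2 tables with total ≤ 30 plus 1,000 random tables with
totals up to 200.

## Known limitations

- The ANOVA p-value is exact only under normal within-class errors;
  log2FC responses of negative-binomial counts are slightly skewed at
  low means, which shows up as a mild (≲ 10 % relative) excess at the
  0.005 tail in very large null scans at low-count settings.
- With 15 cells per scan the minor-allele-homozygote class is often a
  single cell; the test remains valid but power rests on the common
  classes, and `min_class_size` can be raised at a power cost.
- The enrichment universe is the post-QC SNP panel, not the genome;
  odds ratios are therefore conditional on testability.
- LD proxies come from the study panel (n = 30 by default); r² estimates
  at that size are noisy, and the 0.8 threshold is a hard gate on a
  noisy statistic.
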