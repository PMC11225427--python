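"""Regulatory and positional annotation of surviving eQTL SNPs.

The 15 chromatin states of the Roadmap ChromHMM model are collapsed to
four functional categories; a SNP's multi-tissue calls are reduced to a
single consensus label by the modal rule, with explicit handling of ties.
Positional classes place a SNP relative to its eQTL gene's transcript
model (promoter, UTRs, coding exon, intron, upstream/downstream).
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .containers import ChromHmmTable, GeneModel

TSS_CAT = "TSS"
TRANSCR_CAT = "Transcr"
ENHANCER_CAT = "Enhancer"
REPRESSED_CAT = "Repressed"

# canonical order for composing tie labels
ACTIVE_CATEGORIES = (TSS_CAT, TRANSCR_CAT, ENHANCER_CAT)

STATE_VOCABULARY = (
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk", "6_EnhG", "7_Enh",
    "8_ZNF/Rpts", "9_Het", "10_TssBiv", "11_BivFlnk", "12_EnhBiv",
    "13_ReprPC", "14_ReprPCWk", "15_Quies",
)

_STATE_TO_CATEGORY = {
    "1_TssA": TSS_CAT,
    "2_TssAFlnk": TSS_CAT,
    "3_TxFlnk": TRANSCR_CAT,
    "4_Tx": TRANSCR_CAT,
    "5_TxWk": TRANSCR_CAT,
    "6_EnhG": ENHANCER_CAT,
    "7_Enh": ENHANCER_CAT,
}


def collapse_state(state: str) -> str:
    """Map a 15-state label to TSS / Transcr / Enhancer / Repressed."""
    if state not in STATE_VOCABULARY:
        raise ValueError(f"unknown ChromHMM state {state!r}")
    return _STATE_TO_CATEGORY.get(state, REPRESSED_CAT)


def consensus_annotation(categories: list[str]) -> str:
    """Modal category across tissues, with explicit tie labels.

    - unique mode -> that category (a single tissue counts as a mode);
    - exactly two *active* categories tied for the mode ->
      "<catA>_<catB>_Mixed" in the fixed order TSS < Transcr < Enhancer;
    - an active category tied with Repressed, or a three-way active tie ->
      "Ambiguous".
    """
    if not categories:
        raise ValueError("at least one tissue category required")
    counts = Counter(categories)
    top = max(counts.values())
    modal = [c for c in counts if counts[c] == top]
    if len(modal) == 1:
        return modal[0]
    if REPRESSED_CAT in modal:
        return "Ambiguous"
    if len(modal) == 2:
        ordered = sorted(modal, key=ACTIVE_CATEGORIES.index)
        return f"{ordered[0]}_{ordered[1]}_Mixed"
    return "Ambiguous"


def consensus_for_table(
    chromhmm: ChromHmmTable, snp_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-SNP consensus over all tissue rows; SNPs without rows are 'Unannotated'."""
    grouped = {
        snp: [collapse_state(s) for s in df["state"]]
        for snp, df in chromhmm.table.groupby("snp_id")
    }
    if snp_ids is None:
        snp_ids = sorted(grouped)
    rows = [
        (snp, consensus_annotation(grouped[snp]) if snp in grouped else "Unannotated")
        for snp in snp_ids
    ]
    return pd.DataFrame(rows, columns=["snp_id", "consensus_label"])


PROMOTER_SPAN = 3000  # bp upstream of the TSS, strand-aware


def classify_snp_location(snp_pos: int, gene: GeneModel) -> str:
    """Positional class of a SNP relative to one gene's transcript.

    Classes: promoter ([TSS-3000, TSS) in transcription orientation),
    5utr / 3utr, exon_coding (exon minus UTR), intron, upstream /
    downstream (strand-aware side of the gene). Within the transcript the
    precedence is UTR > coding exon > intron; outside it, promoter is
    checked before upstream. Defined for any position on the chromosome.
    """
    p = snp_pos
    if gene.tx_start <= p <= gene.tx_end:
        for lo, hi in gene.utr5:
            if lo <= p <= hi:
                return "5utr"
        for lo, hi in gene.utr3:
            if lo <= p <= hi:
                return "3utr"
        for lo, hi in gene.exons:
            if lo <= p <= hi:
                return "exon_coding"
        return "intron"
    if gene.strand == "+":
        if gene.tss - PROMOTER_SPAN <= p < gene.tss:
            return "promoter"
        return "upstream" if p < gene.tx_start else "downstream"
    # minus strand: promoter flank sits at higher coordinates
    if gene.tss < p <= gene.tss + PROMOTER_SPAN:
        return "promoter"
    return "upstream" if p > gene.tx_end else "downstream"


def distance_to_tss(snp_pos: int, gene: GeneModel) -> int:
    """Signed distance in transcription orientation (positive = downstream)."""
    d = snp_pos - gene.tss
    return d if gene.strand == "+" else -d


def annotate_snps(
    snp_meta: pd.DataFrame,
    snp_gene_pairs: pd.DataFrame,
    gene_models: dict[str, GeneModel],
    chromhmm: ChromHmmTable,
) -> pd.DataFrame:
    """Full annotation table for (snp_id, gene_id) pairs.

    Columns: snp_id, gene_id, consensus_label, location_class,
    distance_to_tss. Pairs whose gene lacks a model are skipped.
    """
    snp_ids = sorted(set(snp_gene_pairs["snp_id"]))
    consensus = consensus_for_table(chromhmm, snp_ids).set_index("snp_id")["consensus_label"]
    rows = []
    for snp, gene_id in zip(snp_gene_pairs["snp_id"], snp_gene_pairs["gene_id"]):
        gene = gene_models.get(gene_id)
        if gene is None:
            continue
        pos = int(snp_meta.loc[snp, "pos"])
        rows.append(
            (
                snp,
                gene_id,
                consensus.get(snp, "Unannotated"),
                classify_snp_location(pos, gene),
                distance_to_tss(pos, gene),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "gene_id", "consensus_label", "location_class", "distance_to_tss"],
    )
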