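"""Overlap of PGx-eQTL SNPs with GWAS hits, directly or through LD proxies,
plus Fisher enrichment of eQTL status among GWAS hit status.

LD is computed from a user-supplied dosage panel (by default the study
cells themselves) as the squared Pearson correlation of minor-allele
dosages, so the whole analysis is hermetic — no remote LD service.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, GwasTable

log = logging.getLogger(__name__)


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation over individuals complete for both SNPs.

    Returns NaN (flagged) when fewer than 3 complete pairs remain or when
    either vector has zero variance.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        return float("nan")
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def match_gwas(
    eqtl_snps: list[str],
    gwas: GwasTable,
    ld_panel: GenotypeMatrix,
    r2_min: float = 0.8,
    proxy_window: int = 500_000,
) -> pd.DataFrame:
    """Match eQTL SNPs to GWAS hits exactly or through LD proxies.

    A match row is (eqtl_snp, gwas_snp, phenotype, study, gwas_p, r2,
    match_type). Exact = same SNP id (r2 reported as 1.0). Proxy = a GWAS
    hit SNP within ``proxy_window`` bp on the same chromosome with
    r^2 >= ``r2_min`` in the panel. eQTL SNPs absent from the panel fall
    back to exact-only matching (logged).
    """
    hits = gwas.hits()
    rows = []
    panel_snps = set(ld_panel.snp_ids)
    hit_by_id: dict[str, list] = {}
    for rec in hits.itertuples():
        hit_by_id.setdefault(rec.snp_id, []).append(rec)
    for snp in eqtl_snps:
        for rec in hit_by_id.get(snp, []):
            rows.append((snp, snp, rec.phenotype, rec.study, rec.p_value, 1.0, "exact"))
        if snp not in panel_snps:
            log.info("eQTL SNP %s absent from LD panel; exact-only matching", snp)
            continue
        meta = ld_panel.snp_meta.loc[snp]
        d_eqtl = ld_panel.dosage[snp].to_numpy(dtype=float)
        near = hits.loc[
            (hits["chrom"].astype(str) == str(meta["chrom"]))
            & ((hits["pos"] - meta["pos"]).abs() <= proxy_window)
            & (hits["snp_id"] != snp)
        ]
        for rec in near.itertuples():
            if rec.snp_id not in panel_snps:
                continue
            r2 = ld_r2(d_eqtl, ld_panel.dosage[rec.snp_id].to_numpy(dtype=float))
            if not np.isnan(r2) and r2 >= r2_min:
                rows.append((snp, rec.snp_id, rec.phenotype, rec.study, rec.p_value, r2, "proxy"))
    return pd.DataFrame(
        rows,
        columns=["eqtl_snp", "gwas_snp", "phenotype", "study", "gwas_p", "r2", "match_type"],
    )


def group_loci(
    matched_signals: pd.DataFrame,
    gap: int = 1_000_000,
) -> pd.DataFrame:
    """Single-linkage clustering of matched SNP-gene signals into loci.

    ``matched_signals`` needs columns snp_id, chrom, pos, gene_id, p_value
    and (optionally) in_peak. Signals on the same chromosome whose
    consecutive SNP positions are within ``gap`` bp join one locus. The
    locus's top SNP is the smallest-p member, preferring SNPs inside a
    binding-site peak when any member is.
    """
    if matched_signals.empty:
        return pd.DataFrame(
            columns=["locus_id", "chrom", "start", "end", "n_snps", "n_genes",
                     "snp_ids", "gene_ids", "top_snp", "top_p"]
        )
    df = matched_signals.sort_values(["chrom", "pos"]).reset_index(drop=True)
    locus_ids = np.zeros(len(df), dtype=int)
    current = 0
    for i in range(1, len(df)):
        same_chrom = df.at[i, "chrom"] == df.at[i - 1, "chrom"]
        close = same_chrom and (df.at[i, "pos"] - df.at[i - 1, "pos"]) <= gap
        if not close:
            current += 1
        locus_ids[i] = current
    df["locus_id"] = locus_ids
    out = []
    for lid, grp in df.groupby("locus_id"):
        if "in_peak" in grp.columns and grp["in_peak"].fillna(False).any():
            cand = grp.loc[grp["in_peak"].fillna(False).astype(bool)]
        else:
            cand = grp
        top = cand.loc[cand["p_value"].idxmin()]
        out.append(
            {
                "locus_id": int(lid),
                "chrom": grp["chrom"].iloc[0],
                "start": int(grp["pos"].min()),
                "end": int(grp["pos"].max()),
                "n_snps": grp["snp_id"].nunique(),
                "n_genes": grp["gene_id"].nunique(),
                "snp_ids": ",".join(sorted(grp["snp_id"].unique())),
                "gene_ids": ",".join(sorted(grp["gene_id"].unique())),
                "top_snp": top["snp_id"],
                "top_p": float(top["p_value"]),
            }
        )
    return pd.DataFrame(out)


@dataclass
class EnrichmentResult:
    a: int  # eQTL+ GWAS+
    b: int  # eQTL+ GWAS-
    c: int  # eQTL- GWAS+
    d: int  # eQTL- GWAS-
    odds_ratio: float
    p_value: float
    defined: bool = True


def enrichment_test(
    eqtl_hit_flags: np.ndarray, gwas_hit_flags: np.ndarray
) -> EnrichmentResult:
    """Fisher's exact test of eQTL status against GWAS-hit status.

    Both flags are defined over the same SNP universe (every SNP that
    entered the eQTL scan after QC). The odds ratio is the sample cross
    ratio with a Haldane 0.5 correction when any cell is zero; the p-value
    is the two-sided exact hypergeometric tail. Degenerate margins (an
    empty eQTL or GWAS class on either side) give p = 1 and an undefined
    result.
    """
    e = np.asarray(eqtl_hit_flags, dtype=bool)
    g = np.asarray(gwas_hit_flags, dtype=bool)
    if e.shape != g.shape:
        raise ValueError("flag vectors must be defined on the same SNP universe")
    a = int((e & g).sum())
    b = int((e & ~g).sum())
    c = int((~e & g).sum())
    d = int((~e & ~g).sum())
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return EnrichmentResult(a, b, c, d, float("nan"), 1.0, defined=False)
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(a, b, c, d, float(orr), float(p))


def circos_locus_table(loci: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (sector, track, value) rows for a circos-style figure."""
    rows = []
    for rec in loci.itertuples():
        sector = f"{rec.chrom}:{rec.start}-{rec.end}"
        rows.append((sector, "n_snps", rec.n_snps))
        rows.append((sector, "n_genes", rec.n_genes))
        rows.append((sector, "top_neglog10_p", -np.log10(max(rec.top_p, 1e-300))))
    return pd.DataFrame(rows, columns=["sector", "track", "value"])
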