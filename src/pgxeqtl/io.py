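"""Readers and writers for the pipeline's on-disk formats.

All tabular outputs are TSV with a single comment header line carrying the
schema version and table name, e.g. ``#pgxeqtl schema=1 table=qc_report``,
so result directories are diff-able and self-describing. Genotypes can be
exchanged either as a dosage TSV or as a minimal GT-only VCF.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GenotypeMatrix, GwasTable, PeakSet, ChromHmmTable, GeneModel

SCHEMA_VERSION = 1

_GT_TO_DOSAGE = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "./.": np.nan}
_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _header(table: str) -> str:
    return f"#pgxeqtl schema={SCHEMA_VERSION} table={table}\n"


def write_table(df: pd.DataFrame, path: str | Path, table: str, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(table))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# -- genotypes ---------------------------------------------------------------

def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV: rows = SNPs with chrom/pos/ref/alt, columns = cells."""
    meta = g.snp_meta.copy()
    dos = g.dosage.T  # SNPs x cells
    out = pd.concat([meta, dos], axis=1)
    out.index.name = "snp_id"
    write_table(out, path, "dosage", index=True)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = read_table(path, index_col="snp_id")
    meta_cols = ["chrom", "pos", "ref", "alt"]
    meta = df[meta_cols]
    dosage = df.drop(columns=meta_cols).T
    dosage.index.name = None
    return GenotypeMatrix(dosage=dosage.astype(float), snp_meta=meta)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Minimal GT-only VCF; missing dosage is emitted as ``./.``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cells = g.cell_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(set(g.snp_meta["chrom"]), key=str):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cells) + "\n")
        order = g.snp_meta.sort_values(["chrom", "pos"]).index
        for snp in order:
            row = g.snp_meta.loc[snp]
            calls = []
            for v in g.dosage[snp].to_numpy():
                calls.append("./." if np.isnan(v) else _DOSAGE_TO_GT[int(v)])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    cells = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        dos = []
        for a0, a1, *_ in var.genotypes:
            dos.append(np.nan if a0 < 0 or a1 < 0 else float(a0 + a1))
        rows.append(dos)
    vcf.close()
    dosage = pd.DataFrame(np.array(rows).T, index=cells, columns=snp_ids)
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}, index=snp_ids
    )
    return GenotypeMatrix(dosage=dosage, snp_meta=meta)


# -- counts / responses ------------------------------------------------------

def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    write_table(out, path, f"counts_{cm.condition}", index=True)


def read_counts(path: str | Path, condition: str) -> CountMatrix:
    df = read_table(path, index_col="gene_id")
    df.index.name = None
    return CountMatrix(counts=df, condition=condition)


# -- peaks / ChromHMM / gene models / GWAS -----------------------------------

def write_bed(peaks: PeakSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["chrom", "start", "end"]
    if "source" in peaks.intervals.columns:
        cols.append("source")
    peaks.intervals[cols].to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def read_bed(path: str | Path) -> PeakSet:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return PeakSet(intervals=pd.DataFrame(columns=["chrom", "start", "end"]))
    df = df.iloc[:, : min(4, df.shape[1])]
    df.columns = ["chrom", "start", "end", "source"][: df.shape[1]]
    return PeakSet(intervals=df)


def write_chromhmm(t: ChromHmmTable, path: str | Path) -> None:
    write_table(t.table, path, "chromhmm")


def read_chromhmm(path: str | Path) -> ChromHmmTable:
    return ChromHmmTable(table=read_table(path))


def write_gwas(g: GwasTable, path: str | Path) -> None:
    write_table(g.table, path, "gwas")


def read_gwas(path: str | Path, hit_threshold: float = 0.005, strict: bool = False) -> GwasTable:
    return GwasTable(table=read_table(path), hit_threshold=hit_threshold, strict=strict)


def _unpack_intervals(s) -> list[tuple[int, int]]:
    if not isinstance(s, str) or not s or s == ".":
        return []
    out = []
    for part in s.split(","):
        lo, hi = part.split("-")
        out.append((int(lo), int(hi)))
    return out


def _pack_intervals(iv: list[tuple[int, int]]) -> str:
    return ",".join(f"{lo}-{hi}" for lo, hi in iv) or "."


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tx_start": g.tx_start,
            "tx_end": g.tx_end,
            "exons": _pack_intervals(g.exons),
            "utr5": _pack_intervals(g.utr5),
            "utr3": _pack_intervals(g.utr3),
        }
        for g in genes
    ]
    write_table(pd.DataFrame(rows), path, "gene_models")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = read_table(path)
    return [
        GeneModel(
            gene_id=r.gene_id,
            chrom=str(r.chrom),
            strand=r.strand,
            tx_start=int(r.tx_start),
            tx_end=int(r.tx_end),
            exons=_unpack_intervals(r.exons),
            utr5=_unpack_intervals(r.utr5),
            utr3=_unpack_intervals(r.utr3),
        )
        for r in df.itertuples()
    ]


def sha256_of(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
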