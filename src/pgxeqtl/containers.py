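"""In-memory containers shared across pipeline stages.

Everything is a thin, validated wrapper around :class:`pandas.DataFrame`
so that stages can be composed in memory or through the TSV interfaces in
:mod:`pgxeqtl.io` interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Treatment condition labels. VEH is the reference; the three others are
# the response conditions (log2 fold change over vehicle).
VEH = "VEH"
DHT = "DHT"
ENZ = "ENZ"
DUAL = "DUAL"
CONDITIONS = (VEH, DHT, ENZ, DUAL)
RESPONSE_CONDITIONS = (DHT, ENZ, DUAL)

AR_EXPRESSED = "AR_EXPRESSED"
AR_NULL = "AR_NULL"


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix (cells x SNPs) plus SNP coordinates.

    ``dosage`` holds values in {0, 1, 2} with ``NaN`` for missing calls;
    rows are cells, columns are SNP ids. ``snp_meta`` is indexed by SNP id
    with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    """

    dosage: pd.DataFrame
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.snp_meta.index.is_unique:
            raise ValueError("snp_ids must be unique")
        missing = [s for s in self.dosage.columns if s not in self.snp_meta.index]
        if missing:
            raise ValueError(f"SNPs without coordinates: {missing[:5]}")
        if (self.snp_meta["pos"] <= 0).any():
            raise ValueError("SNP positions must be strictly positive (1-based)")
        # keep meta aligned to the dosage column order
        self.snp_meta = self.snp_meta.loc[list(self.dosage.columns)]

    @property
    def cell_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_cells(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset_cells(self, cell_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.loc[list(cell_ids)], self.snp_meta.copy())

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        snp_ids = list(snp_ids)
        return GenotypeMatrix(self.dosage[snp_ids], self.snp_meta.loc[snp_ids].copy())


@dataclass
class CountMatrix:
    """Raw RNA-seq gene counts (genes x cells) for one treatment condition."""

    counts: pd.DataFrame
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class ResponseMatrix:
    """Per-cell log2 fold change of a drug condition over vehicle (genes x cells)."""

    log2fc: pd.DataFrame
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in RESPONSE_CONDITIONS:
            raise ValueError(f"response condition must be one of {RESPONSE_CONDITIONS}")
        if not np.isfinite(self.log2fc.to_numpy()).all():
            raise ValueError("log2fc must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.log2fc.columns)

    def subset_cells(self, cell_ids) -> "ResponseMatrix":
        return ResponseMatrix(self.log2fc[list(cell_ids)], self.condition)


@dataclass
class PeakSet:
    """ChIP-seq peak intervals (BED semantics: 0-based start, exclusive end)."""

    intervals: pd.DataFrame  # columns: chrom, start, end[, source]

    def __post_init__(self) -> None:
        df = self.intervals
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("peak intervals require start < end")
        self.intervals = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def chromosomes(self) -> set[str]:
        return set(self.intervals["chrom"].unique())


@dataclass
class ChromHmmTable:
    """Long-format per-SNP, per-tissue chromatin-state calls (15-state labels)."""

    table: pd.DataFrame  # columns: snp_id, tissue, state

    def states_for(self, snp_id: str) -> list[str]:
        return list(self.table.loc[self.table["snp_id"] == snp_id, "state"])


@dataclass
class GwasTable:
    """GWAS summary rows: snp_id, chrom, pos, p_value, phenotype, study."""

    table: pd.DataFrame
    hit_threshold: float = 0.005
    strict: bool = False  # True: hit iff p < threshold; False: p <= threshold

    def __post_init__(self) -> None:
        p = self.table["p_value"].to_numpy()
        if len(p) and ((p <= 0) | (p > 1)).any():
            raise ValueError("GWAS p-values must be in (0, 1]")

    def hits(self) -> pd.DataFrame:
        p = self.table["p_value"]
        mask = (p < self.hit_threshold) if self.strict else (p <= self.hit_threshold)
        return self.table.loc[mask]


@dataclass
class GeneModel:
    """One gene's transcript model with strand-aware TSS.

    Coordinates are 1-based inclusive. ``exons`` include UTR bases; coding
    classification subtracts the UTR intervals.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.tx_start > self.tx_end:
            raise ValueError("tx_start must be <= tx_end")
        for lo, hi in [*self.exons, *self.utr5, *self.utr3]:
            if lo < self.tx_start or hi > self.tx_end:
                raise ValueError("intervals must lie within transcript bounds")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end
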