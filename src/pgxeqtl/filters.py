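"""AR-specificity filter cascade over a raw scan's significant signals.

Three independent predicates are applied to every significant SNP-gene
pair from the AR-expressed scan of one drug condition:

1. AR-null exclusion — the same pair significant in the AR-null scan of
   the same condition marks the signal receptor-independent;
2. reversibility — a pair still significant under agonist+antagonist
   dual treatment is treatment-independent or ambiguous;
3. binding-site overlap — the SNP must fall inside at least one ChIP-seq
   peak.

Each filter only sets its provenance flag; the surviving set is the
conjunction, so the cascade is order-independent by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import GenotypeMatrix, PeakSet
from .eqtl import PgxEqtlResults

log = logging.getLogger(__name__)

_FLAGS = ("ar_null_hit", "nonreversible", "in_peak")


@dataclass
class SignalSet:
    """Significant pairs of one condition with their three filter flags.

    ``table`` columns: snp_id, gene_id, f_stat, p_value, effect_size, plus
    one nullable-boolean column per flag (NA = filter not yet applied).
    """

    condition: str
    table: pd.DataFrame
    applied: set[str] = field(default_factory=set)

    @classmethod
    def from_results(cls, results: PgxEqtlResults) -> "SignalSet":
        sig = results.signals.loc[
            results.signals["significant"],
            ["snp_id", "gene_id", "f_stat", "p_value", "effect_size"],
        ].reset_index(drop=True)
        for flag in _FLAGS:
            sig[flag] = pd.array([pd.NA] * len(sig), dtype="boolean")
        return cls(condition=results.condition, table=sig)

    def survivors(self) -> pd.DataFrame:
        """Pairs passing every *applied* filter (final set once all three ran)."""
        mask = np.ones(len(self.table), dtype=bool)
        for flag in self.applied:
            col = self.table[flag].fillna(False).to_numpy(dtype=bool)
            mask &= ~col if flag in ("ar_null_hit", "nonreversible") else col
        return self.table.loc[mask]

    def pair_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.table[["snp_id", "gene_id"]])

    def _set_flag(self, flag: str, values: np.ndarray) -> "SignalSet":
        if flag in self.applied:
            raise ValueError(f"filter {flag!r} already applied; flags are immutable")
        out = self.table.copy()
        out[flag] = pd.array(values, dtype="boolean")
        return SignalSet(self.condition, out, self.applied | {flag})


def exclude_ar_null(
    signals: SignalSet,
    ar_null_results: PgxEqtlResults,
    p_threshold: float | None = None,
) -> SignalSet:
    """Flag pairs replicated at significance in the AR-null scan.

    Matching is exact on (snp, gene) within the same condition. Pairs absent
    from the AR-null scan (e.g. the SNP failed QC in that cell subset) are
    treated as not replicated and logged.
    """
    if ar_null_results.condition != signals.condition:
        raise ValueError(
            f"condition mismatch: signals={signals.condition} "
            f"vs AR-null scan={ar_null_results.condition}"
        )
    thr = p_threshold if p_threshold is not None else ar_null_results.params.p_threshold
    null_sig = ar_null_results.signals
    null_tested = set(zip(null_sig["snp_id"], null_sig["gene_id"]))
    null_hits = set(
        zip(*(null_sig.loc[null_sig["testable"] & (null_sig["p_value"] <= thr), c]
              for c in ("snp_id", "gene_id")))
    ) if len(null_sig) else set()
    pairs = list(zip(signals.table["snp_id"], signals.table["gene_id"]))
    absent = [p for p in pairs if p not in null_tested]
    if absent:
        log.info("%d pair(s) absent from the AR-null scan; treated as not replicated", len(absent))
    flags = np.array([p in null_hits for p in pairs], dtype=bool)
    return signals._set_flag("ar_null_hit", flags)


def exclude_nonreversible(
    signals: SignalSet,
    dual_results: PgxEqtlResults,
    p_threshold: float | None = None,
    same_direction_only: bool = False,
) -> SignalSet:
    """Flag pairs that remain significant under dual (agonist+antagonist) treatment.

    By default significance alone in the dual scan marks a pair
    non-reversible; ``same_direction_only`` additionally requires the dual
    effect size to share the sign of the single-drug effect.
    """
    if dual_results is None:
        raise ValueError("dual-treatment scan is required for the reversibility filter")
    dsig = dual_results.signals
    thr = p_threshold if p_threshold is not None else dual_results.params.p_threshold
    hits = dsig.loc[dsig["testable"] & (dsig["p_value"] <= thr)]
    hit_map = {
        (s, g): e for s, g, e in zip(hits["snp_id"], hits["gene_id"], hits["effect_size"])
    }
    flags = []
    for s, g, eff in zip(
        signals.table["snp_id"], signals.table["gene_id"], signals.table["effect_size"]
    ):
        key = (s, g)
        if key not in hit_map:
            flags.append(False)
        elif same_direction_only:
            flags.append(bool(np.sign(hit_map[key]) == np.sign(eff)))
        else:
            flags.append(True)
    return signals._set_flag("nonreversible", np.array(flags, dtype=bool))


def snps_in_peaks(snp_meta: pd.DataFrame, peaks: PeakSet) -> pd.Series:
    """Boolean per SNP: does the (1-based) position fall in any BED interval?

    BED is 0-based half-open, so a peak [start, end) covers 1-based
    positions start+1 .. end.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, df in peaks.intervals.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(df["start"], df["end"])
        )
    snp_chroms = set(snp_meta["chrom"].astype(str))
    if len(peaks) and not (snp_chroms & set(trees)):
        warnings.warn(
            "no chromosome names shared between SNPs and peaks "
            f"(snps: {sorted(snp_chroms)[:3]}, peaks: {sorted(trees)[:3]}); "
            "zero overlaps will result",
            stacklevel=2,
        )
    out = []
    for chrom, pos in zip(snp_meta["chrom"].astype(str), snp_meta["pos"]):
        tree = trees.get(chrom)
        out.append(bool(tree is not None and tree.overlaps_point(int(pos) - 1)))
    return pd.Series(out, index=snp_meta.index)


def filter_by_peak(
    signals: SignalSet, peaks: PeakSet, snp_meta: pd.DataFrame
) -> SignalSet:
    """Flag pairs whose SNP lies inside at least one binding-site peak."""
    covered = snps_in_peaks(snp_meta, peaks)
    flags = signals.table["snp_id"].map(covered).fillna(False).to_numpy(dtype=bool)
    return signals._set_flag("in_peak", flags)


def apply_cascade(
    ar_pos_results: PgxEqtlResults,
    ar_null_results: PgxEqtlResults,
    dual_results: PgxEqtlResults,
    peaks: PeakSet,
    genotypes: GenotypeMatrix,
    p_threshold: float | None = None,
) -> SignalSet:
    """All three filters on the significant AR-expressed signals of one condition."""
    s = SignalSet.from_results(ar_pos_results)
    s = exclude_ar_null(s, ar_null_results, p_threshold)
    s = exclude_nonreversible(s, dual_results, p_threshold)
    s = filter_by_peak(s, peaks, genotypes.snp_meta)
    return s


def audit_table(signals: SignalSet) -> pd.DataFrame:
    """Machine-readable cascade audit: every significant pair, its flags, fate."""
    out = signals.table.copy()
    for flag in _FLAGS:
        if flag not in signals.applied:
            out[flag] = pd.NA
    final = np.ones(len(out), dtype=bool)
    for flag in signals.applied:
        col = out[flag].fillna(False).to_numpy(dtype=bool)
        final &= ~col if flag in ("ar_null_hit", "nonreversible") else col
    out["final"] = final
    return out


def direction_concordance(
    signals_a: SignalSet, signals_b: SignalSet
) -> tuple[int, int]:
    """Shared pairs between two conditions and how many agree in effect sign.

    Returns (n_shared, n_same_direction), the descriptive statistic behind
    "shared between DHT and Enz with the same directionalities".
    """
    a = signals_a.table.set_index(["snp_id", "gene_id"])["effect_size"]
    b = signals_b.table.set_index(["snp_id", "gene_id"])["effect_size"]
    shared = a.index.intersection(b.index)
    same = int((np.sign(a.loc[shared]) == np.sign(b.loc[shared])).sum())
    return len(shared), same
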