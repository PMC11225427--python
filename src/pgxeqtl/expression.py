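"""Expression processing: low-count gene filter, CPM log2 fold changes,
and AR-expressed / AR-null classification of the cell panel."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    AR_EXPRESSED,
    AR_NULL,
    CONDITIONS,
    VEH,
    CountMatrix,
    ResponseMatrix,
)


@dataclass
class ExpressionFilterParams:
    """Thresholds for expression-level gene and cell gating.

    min_count/min_cells: a gene is excluded when at least ``min_cells``
    cells fall below ``min_count`` raw counts in any single condition.
    ar_null_max_reads: a cell is AR-null when its receptor-gene raw count
    stays strictly below this bound in every condition.
    pseudocount: symmetric CPM offset protecting the log ratio at zero.
    """

    min_count: int = 32
    min_cells: int = 15
    ar_null_max_reads: int = 5
    pseudocount: float = 0.5
    normalize_before_ratio: bool = True  # False: ratio of raw counts, then CPM-correct

    def __post_init__(self) -> None:
        if min(self.min_count, self.min_cells, self.ar_null_max_reads) <= 0:
            raise ValueError("count thresholds must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def _check_aligned(matrices: dict[str, CountMatrix]) -> None:
    if not matrices:
        raise ValueError("no count matrices supplied")
    ref = next(iter(matrices.values()))
    for cm in matrices.values():
        if cm.gene_ids != ref.gene_ids or cm.cell_ids != ref.cell_ids:
            raise ValueError("count matrices must share gene and cell axes")


def filter_low_count_genes(
    counts_by_condition: dict[str, CountMatrix],
    params: ExpressionFilterParams | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop genes with ``>= min_cells`` cells under ``min_count`` in any condition.

    Returns the retained gene ids (input order) and a per-gene report with
    the worst (highest) low-count cell tally and the condition it came from.
    """
    params = params or ExpressionFilterParams()
    _check_aligned(counts_by_condition)
    ref = next(iter(counts_by_condition.values()))
    low = pd.DataFrame(
        {
            cond: (cm.counts < params.min_count).sum(axis=1)
            for cond, cm in counts_by_condition.items()
        }
    )
    worst_cond = low.idxmax(axis=1)
    worst_n = low.max(axis=1)
    excluded = worst_n >= params.min_cells
    report = pd.DataFrame(
        {
            "gene_id": ref.gene_ids,
            "max_low_count_cells": worst_n.to_numpy(),
            "worst_condition": worst_cond.to_numpy(),
            "kept": (~excluded).to_numpy(),
        }
    )
    retained = [g for g, keep in zip(ref.gene_ids, ~excluded.to_numpy()) if keep]
    return retained, report


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million over the matrix's own library sizes."""
    lib = cm.library_sizes()
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero library size for cells {bad[:5]}")
    return cm.counts / lib * 1e6


def normalize_and_log2fc(
    treated: CountMatrix,
    vehicle: CountMatrix,
    params: ExpressionFilterParams | None = None,
) -> ResponseMatrix:
    """Per-cell, per-gene log2((CPM_trt + pc) / (CPM_veh + pc)).

    With ``normalize_before_ratio=False`` the ratio is taken on raw counts
    and the library-size ratio applied afterwards — algebraically identical
    at pseudocount 0, kept as an option because the two orderings differ
    slightly near zero counts.
    """
    params = params or ExpressionFilterParams()
    if treated.cell_ids != vehicle.cell_ids or treated.gene_ids != vehicle.gene_ids:
        raise ValueError("treated and vehicle matrices must be aligned")
    pc = params.pseudocount
    if params.normalize_before_ratio:
        num = cpm(treated) + pc
        den = cpm(vehicle) + pc
        fc = np.log2(num / den)
    else:
        lib_ratio = vehicle.library_sizes() / treated.library_sizes()
        fc = np.log2((treated.counts + pc) / (vehicle.counts + pc)) + np.log2(lib_ratio)
    return ResponseMatrix(log2fc=fc, condition=treated.condition)


def classify_ar_status(
    ar_counts_by_condition: dict[str, pd.Series],
    params: ExpressionFilterParams | None = None,
) -> pd.DataFrame:
    """Label each cell AR_NULL iff its AR raw count is < threshold in every condition.

    ``ar_counts_by_condition`` maps each condition label (all four expected,
    vehicle included) to a per-cell Series of raw AR-gene counts. Returns a
    table (cell_id, max_ar_count, label).
    """
    params = params or ExpressionFilterParams()
    missing = [c for c in CONDITIONS if c not in ar_counts_by_condition]
    if missing:
        raise ValueError(f"missing condition(s) for AR classification: {missing}")
    df = pd.DataFrame(ar_counts_by_condition)
    # AR-null rule applies to the drug conditions; a vehicle-only signal
    # still implies the receptor can be expressed, so use all conditions.
    max_count = df.max(axis=1)
    label = np.where(max_count < params.ar_null_max_reads, AR_NULL, AR_EXPRESSED)
    return pd.DataFrame(
        {"cell_id": df.index, "max_ar_count": max_count.to_numpy(), "label": label}
    )


def build_responses(
    counts_by_condition: dict[str, CountMatrix],
    params: ExpressionFilterParams | None = None,
    gene_subset: list[str] | None = None,
) -> dict[str, ResponseMatrix]:
    """Low-count-filter, then log2FC of every drug condition over vehicle."""
    params = params or ExpressionFilterParams()
    _check_aligned(counts_by_condition)
    if VEH not in counts_by_condition:
        raise ValueError("vehicle condition required to form responses")
    if gene_subset is None:
        gene_subset, _ = filter_low_count_genes(counts_by_condition, params)
    subset = {
        cond: CountMatrix(cm.counts.loc[gene_subset], cond)
        for cond, cm in counts_by_condition.items()
    }
    veh = subset[VEH]
    return {
        cond: normalize_and_log2fc(cm, veh, params)
        for cond, cm in subset.items()
        if cond != VEH
    }
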