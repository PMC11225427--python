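"""Cis PGx-eQTL mapping: categorical-genotype ANOVA of drug response.

The model asks, for every cis SNP-gene pair, whether a cell's log2
fold-change response to a drug differs by genotype. Genotype enters as an
unordered factor (0/1/2 copies of the minor allele), so the test is a
one-way fixed-effects ANOVA with F on (k-1, n-k) degrees of freedom where
k is the number of genotype classes actually observed. A per-minor-allele
least-squares slope is reported alongside as the effect size but plays no
role in the p-value.

:class:`PgxEqtlModel` holds one response matrix and the aligned genotype
matrix; :meth:`PgxEqtlModel.fit` returns a :class:`PgxEqtlResults` with the
per-pair signal table, the genomic inflation factor, and a summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneModel, GenotypeMatrix, ResponseMatrix

_P_FLOOR = np.finfo(float).tiny
_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549364...


@dataclass
class ScanParams:
    cis_window: int = 200_000
    p_threshold: float = 0.005
    min_class_size: int = 1

    def __post_init__(self) -> None:
        if self.cis_window <= 0 or self.min_class_size <= 0:
            raise ValueError("cis_window and min_class_size must be positive")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")


def enumerate_cis_pairs(
    gene_models: list[GeneModel],
    snp_meta: pd.DataFrame,
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """All same-chromosome SNP-gene pairs within the cis window.

    A SNP pairs with a gene iff its position lies in
    ``[tx_start - window, tx_end + window]``, both boundaries inclusive.
    ``distance`` is bp from the SNP to the nearest gene-body edge, 0 inside.
    Columns: snp_id, gene_id, distance.
    """
    params = params or ScanParams()
    w = params.cis_window
    rows: list[tuple[str, str, int]] = []
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): df.sort_values("pos") for c, df in snp_meta.groupby("chrom")
    }
    for gene in gene_models:
        snps = by_chrom.get(str(gene.chrom))
        if snps is None:
            continue
        pos = snps["pos"].to_numpy()
        lo = np.searchsorted(pos, gene.tx_start - w, side="left")
        hi = np.searchsorted(pos, gene.tx_end + w, side="right")
        for snp_id, p in zip(snps.index[lo:hi], pos[lo:hi]):
            if p < gene.tx_start:
                dist = gene.tx_start - p
            elif p > gene.tx_end:
                dist = p - gene.tx_end
            else:
                dist = 0
            rows.append((snp_id, gene.gene_id, int(dist)))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "distance"])


def _anova_core(y: np.ndarray, d: np.ndarray, min_class_size: int = 1):
    """One-way ANOVA of y on genotype classes in d (NaN-free inputs).

    Returns (f, df_num, df_den, p, slope, group_means, n_per_class,
    testable). group_means / n_per_class are dicts keyed by dosage class.
    """
    classes, inverse = np.unique(d, return_inverse=True)
    counts = np.bincount(inverse)
    if min_class_size > 1:
        keep = counts >= min_class_size
        if not keep.all():
            mask = keep[inverse]
            return _anova_core(y[mask], d[mask], 1) if mask.sum() >= 3 else _untestable(d, y)
    k = classes.size
    n = y.size
    group_means = {int(c): float(y[d == c].mean()) for c in classes}
    n_per_class = {int(c): int(cnt) for c, cnt in zip(classes, counts)}
    if k < 2 or n < 3 or n - k < 1:
        return np.nan, k - 1, n - k, np.nan, np.nan, group_means, n_per_class, False

    grand = y.mean()
    means = np.array([group_means[int(c)] for c in classes])
    ssb = float(np.sum(counts * (means - grand) ** 2))
    sst = float(np.sum((y - grand) ** 2))
    ssw = max(sst - ssb, 0.0)

    # per-minor-allele slope (numeric dosage regression), reported only
    var_d = np.var(d)
    slope = float(np.cov(d, y, bias=True)[0, 1] / var_d) if var_d > 0 else np.nan

    # zero-variance guard must tolerate accumulation error on constant input
    tiny_sst = n * (100 * np.finfo(float).eps * max(1.0, float(np.abs(y).max()))) ** 2
    if sst <= tiny_sst:
        return 0.0, k - 1, n - k, 1.0, slope, group_means, n_per_class, True
    if ssw <= sst * 1e-14:
        # perfect separation: residual variance numerically zero
        return np.inf, k - 1, n - k, _P_FLOOR, slope, group_means, n_per_class, True
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), k - 1, n - k, p, slope, group_means, n_per_class, True


def _untestable(d, y):
    return np.nan, 0, y.size - 1, np.nan, np.nan, {}, {}, False


def anova_eqtl(response: np.ndarray, dosage: np.ndarray, min_class_size: int = 1) -> dict:
    """Test one SNP-gene pair; cells with missing dosage are dropped.

    Returns a dict with keys f_stat, df_num, df_den, p_value, effect_size,
    group_means, n_per_class, testable.
    """
    y = np.asarray(response, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if y.shape != d.shape:
        raise ValueError("response and dosage must have equal length")
    ok = ~np.isnan(d) & ~np.isnan(y)
    y, d = y[ok], d[ok]
    f, dfn, dfd, p, slope, gm, npc, testable = (
        _anova_core(y, d, min_class_size) if y.size else _untestable(d, y)
    )
    return {
        "f_stat": f,
        "df_num": dfn,
        "df_den": dfd,
        "p_value": p,
        "effect_size": slope,
        "group_means": gm,
        "n_per_class": npc,
        "testable": testable,
    }


def qq_lambda(p_values: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Genomic inflation factor and QQ-plot table.

    lambda = median of the chi-square(1 df) quantile transform of the
    p-values divided by the null median 0.4549. The QQ table pairs sorted
    observed -log10 p with uniform-order-statistic expectations (i-0.5)/m.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    chi = stats.chi2.isf(np.clip(p, _P_FLOOR, 1.0), 1)
    lam = float(np.median(chi) / _CHI2_MEDIAN_1DF)
    obs = np.sort(p)
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame(
        {
            "expected_neglog10_p": -np.log10(expected),
            "observed_neglog10_p": -np.log10(np.clip(obs, _P_FLOOR, 1.0)),
        }
    )
    return lam, qq


class PgxEqtlModel:
    """ANOVA genotype-association model for one response matrix.

    Parameters
    ----------
    responses : ResponseMatrix
        Genes x cells log2 fold changes for one drug condition and one
        cell set (AR-expressed or AR-null).
    genotypes : GenotypeMatrix
        Dosages for the same cells (a superset of cells is accepted and
        subset automatically; the cell order of ``responses`` governs).
    pairs : DataFrame
        Cis pairs (snp_id, gene_id[, distance]) — from
        :func:`enumerate_cis_pairs`. Trans pairs are never tested.
    """

    def __init__(
        self,
        responses: ResponseMatrix,
        genotypes: GenotypeMatrix,
        pairs: pd.DataFrame,
        params: ScanParams | None = None,
        cell_set: str = "",
    ) -> None:
        self.params = params or ScanParams()
        cells = responses.cell_ids
        missing = set(cells) - set(genotypes.cell_ids)
        if missing:
            raise ValueError(f"cells without genotypes: {sorted(missing)[:5]}")
        self.responses = responses
        self.genotypes = genotypes.subset_cells(cells)
        known_snps = set(self.genotypes.snp_ids)
        known_genes = set(responses.gene_ids)
        self.pairs = pairs.loc[
            pairs["snp_id"].isin(known_snps) & pairs["gene_id"].isin(known_genes)
        ].reset_index(drop=True)
        self.cell_set = cell_set

    def fit(self) -> "PgxEqtlResults":
        """Run the ANOVA for every testable cis pair (vectorized per SNP)."""
        prm = self.params
        y_all = self.responses.log2fc
        gene_index = {g: i for i, g in enumerate(y_all.index)}
        Y = y_all.to_numpy(dtype=float)
        records: list[tuple] = []

        for snp_id, sub in self.pairs.groupby("snp_id", sort=False):
            d_full = self.genotypes.dosage[snp_id].to_numpy(dtype=float)
            ok = ~np.isnan(d_full)
            d = d_full[ok]
            gidx = [gene_index[g] for g in sub["gene_id"]]
            if d.size == 0:
                for g in sub["gene_id"]:
                    records.append((snp_id, g, np.nan, 0, 0, np.nan, np.nan,
                                    "", "", False))
                continue
            classes, inverse = np.unique(d, return_inverse=True)
            counts = np.bincount(inverse)
            if prm.min_class_size > 1:
                keep = counts >= prm.min_class_size
                cell_keep = keep[inverse]
                d = d[cell_keep]
                classes, inverse = np.unique(d, return_inverse=True)
                counts = np.bincount(inverse)
                ok_idx = np.flatnonzero(ok)[cell_keep]
            else:
                ok_idx = np.flatnonzero(ok)
            k, n = classes.size, d.size
            Ys = Y[np.ix_(gidx, ok_idx)]
            means_str = ";".join(f"{int(c)}:{counts[i]}" for i, c in enumerate(classes))
            if k < 2 or n < 3 or n - k < 1:
                for g in sub["gene_id"]:
                    records.append((snp_id, g, np.nan, k - 1, n - k, np.nan,
                                    np.nan, "", means_str, False))
                continue

            Z = np.zeros((n, k))
            Z[np.arange(n), inverse] = 1.0
            gsum = Ys @ Z                      # genes x classes
            gmean = gsum / counts
            grand = Ys.mean(axis=1)
            ssb = np.sum(counts * (gmean - grand[:, None]) ** 2, axis=1)
            sst = np.sum((Ys - grand[:, None]) ** 2, axis=1)
            ssw = np.maximum(sst - ssb, 0.0)

            var_d = np.var(d)
            slope = (
                (Ys @ (d - d.mean())) / (n * var_d) if var_d > 0 else np.full(len(gidx), np.nan)
            )

            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ssb / (k - 1)) / (ssw / (n - k))
            p = stats.f.sf(f, k - 1, n - k)
            scale = np.maximum(1.0, np.abs(Ys).max(axis=1))
            zero_tot = sst <= n * (100 * np.finfo(float).eps * scale) ** 2
            sep = (ssw <= sst * 1e-14) & ~zero_tot
            f = np.where(zero_tot, 0.0, f)
            p = np.where(zero_tot, 1.0, p)
            p = np.where(sep, _P_FLOOR, p)
            f = np.where(sep, np.inf, f)

            gm_strs = [
                ";".join(f"{int(c)}:{gmean[row, i]:.6g}" for i, c in enumerate(classes))
                for row in range(len(gidx))
            ]
            for row, g in enumerate(sub["gene_id"]):
                records.append(
                    (snp_id, g, f[row], k - 1, n - k, p[row], slope[row],
                     gm_strs[row], means_str, True)
                )

        signals = pd.DataFrame(
            records,
            columns=["snp_id", "gene_id", "f_stat", "df_num", "df_den", "p_value",
                     "effect_size", "group_means", "n_per_class", "testable"],
        )
        signals["significant"] = (
            (signals["p_value"] <= prm.p_threshold) & signals["testable"]
        ).astype(bool)
        tested = signals["testable"].to_numpy()
        fdr = np.full(len(signals), np.nan)
        if tested.any():
            fdr[tested] = _bh_fdr(signals.loc[tested, "p_value"].to_numpy())
        signals["fdr"] = fdr
        return PgxEqtlResults(
            signals=signals,
            condition=self.responses.condition,
            cell_set=self.cell_set,
            params=prm,
            model=self,
        )


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (emitted as an extra column)."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class PgxEqtlResults:
    """Fitted scan: per-pair signals plus inflation diagnostics."""

    signals: pd.DataFrame
    condition: str
    cell_set: str
    params: ScanParams
    model: PgxEqtlModel | None = field(default=None, repr=False)

    @property
    def n_tested(self) -> int:
        return int(self.signals["testable"].sum())

    @property
    def n_significant(self) -> int:
        return int(self.signals["significant"].sum())

    def significant_pairs(self) -> set[tuple[str, str]]:
        sig = self.signals.loc[self.signals["significant"]]
        return set(zip(sig["snp_id"], sig["gene_id"]))

    def lambda_gc(self) -> float:
        p = self.signals.loc[self.signals["testable"], "p_value"].to_numpy()
        lam, _ = qq_lambda(p)
        return lam

    def qq_table(self) -> pd.DataFrame:
        p = self.signals.loc[self.signals["testable"], "p_value"].to_numpy()
        _, qq = qq_lambda(p)
        return qq

    def miami_table(self, snp_meta: pd.DataFrame) -> pd.DataFrame:
        """Plot-ready table: chrom, pos, -log10 p, cell_set (no rendering)."""
        sig = self.signals.loc[self.signals["testable"], ["snp_id", "p_value"]]
        meta = snp_meta.loc[sig["snp_id"], ["chrom", "pos"]].reset_index(drop=True)
        out = meta.assign(
            neglog10_p=-np.log10(np.clip(sig["p_value"].to_numpy(), _P_FLOOR, 1.0)),
            cell_set=self.cell_set,
        )
        return out

    def summary(self) -> str:
        lam = self.lambda_gc() if self.n_tested else float("nan")
        lines = [
            "PGx-eQTL ANOVA scan",
            "===================",
            f"condition        : {self.condition}",
            f"cell set         : {self.cell_set or '(all cells)'}",
            f"cis pairs tested : {self.n_tested}",
            f"untestable pairs : {len(self.signals) - self.n_tested}",
            f"significant (p<={self.params.p_threshold}) : {self.n_significant}",
            f"genomic inflation lambda : {lam:.3f}",
        ]
        top = (
            self.signals.loc[self.signals["testable"]]
            .nsmallest(5, "p_value")[["snp_id", "gene_id", "f_stat", "p_value", "effect_size"]]
        )
        if len(top):
            lines.append("top signals:")
            lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)


def run_scan(
    responses: ResponseMatrix,
    genotypes: GenotypeMatrix,
    pairs: pd.DataFrame,
    params: ScanParams | None = None,
    cell_set: str = "",
) -> PgxEqtlResults:
    """Convenience wrapper: build a :class:`PgxEqtlModel` and fit it."""
    return PgxEqtlModel(responses, genotypes, pairs, params, cell_set).fit()
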