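"""SNP quality control: minor allele frequency, missingness, exact HWE.

The gate mirrors the plink defaults used for small cell panels: MAF >= 0.2,
missingness <= 5%, and an exact conditional Hardy-Weinberg test (the
chi-square approximation is invalid at 15-30 diploids) with p > 0.001.
QC is evaluated on a caller-chosen cell subset so the AR-expressed and
AR-null halves of the panel can be filtered independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


@dataclass
class QcThresholds:
    min_maf: float = 0.2
    max_missing: float = 0.05
    hwe_alpha: float = 0.001

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_missing", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from 0/1/2 dosages; NaN entries are ignored.

    Returns ``min(f, 1 - f)`` where f is the allele-1 frequency among
    non-missing calls, so the result is always the *minor* frequency even
    when allele 1 is the major allele. All-missing input returns NaN.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan")
    f = d.sum() / (2.0 * d.size)
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test (Wigginton-style SNP-HWE).

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed table. Returns 1.0 for zero individuals.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    # possible het counts share the parity of the rare-allele count
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    if het_values.size == 0:
        return 1.0

    # unnormalized log-probabilities of the conditional distribution:
    # P(het) ∝ 2^het * n! / (hom_r! het! hom_c!) with hom_r = (n_rare-het)/2
    from scipy.special import gammaln

    hom_rare = (n_rare - het_values) // 2
    hom_common = n - het_values - hom_rare
    logp = (
        het_values * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(het_values + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[het_values == n_het][0]
    # 1e-12 relative slack guards against ties broken by float rounding
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def filter_genotypes(
    g: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    cell_subset: list[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the MAF / missingness / HWE gate on ``cell_subset``.

    Returns the filtered matrix (all cells retained, failing SNPs dropped,
    input SNP order preserved) and a per-SNP report with columns
    ``maf``, ``missingness``, ``hwe_p``, ``kept``, ``reason``. A SNP's
    ``reason`` names the first failing criterion in the order
    maf < missing < hwe; SNPs with no non-missing call fail as ``all_missing``.
    """
    thresholds = thresholds or QcThresholds()
    if cell_subset is None:
        cell_subset = g.cell_ids
    cell_subset = list(cell_subset)
    if not cell_subset:
        raise ValueError("cell_subset is empty")
    unknown = set(cell_subset) - set(g.cell_ids)
    if unknown:
        raise ValueError(f"cells not in genotype matrix: {sorted(unknown)[:5]}")

    sub = g.dosage.loc[cell_subset]
    records = []
    for snp in g.snp_ids:
        d = sub[snp].to_numpy(dtype=float)
        n_total = d.size
        obs = d[~np.isnan(d)]
        missingness = 1.0 - obs.size / n_total
        if obs.size == 0:
            records.append((snp, np.nan, missingness, np.nan, False, "all_missing"))
            continue
        maf = compute_maf(obs)
        n_het = int((obs == 1).sum())
        n_hom_alt = int((obs == 2).sum())
        n_hom_ref = int((obs == 0).sum())
        # counts are (major, het, minor) — symmetric for the exact test
        hwe_p = hwe_exact_test(n_hom_ref, n_het, n_hom_alt)
        reason = ""
        if maf < thresholds.min_maf:
            reason = "maf"
        elif missingness > thresholds.max_missing:
            reason = "missing"
        elif hwe_p <= thresholds.hwe_alpha:
            reason = "hwe"
        records.append((snp, maf, missingness, hwe_p, reason == "", reason))

    report = pd.DataFrame(
        records, columns=["snp_id", "maf", "missingness", "hwe_p", "kept", "reason"]
    )
    kept = report.loc[report["kept"], "snp_id"].tolist()
    return g.subset_snps(kept), report
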