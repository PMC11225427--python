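"""Filter cascade: coordinate conventions, the three predicates, commutation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pgxeqtl.containers import DHT, DUAL, PeakSet
from pgxeqtl.eqtl import PgxEqtlResults, ScanParams
from pgxeqtl.filters import (
    SignalSet,
    audit_table,
    direction_concordance,
    exclude_ar_null,
    exclude_nonreversible,
    filter_by_peak,
    snps_in_peaks,
)


def _results(rows, condition=DHT, cell_set="AR_EXPRESSED", p_threshold=0.005):
    """Build a PgxEqtlResults from (snp, gene, p[, effect]) tuples."""
    df = pd.DataFrame(
        [
            {
                "snp_id": r[0],
                "gene_id": r[1],
                "f_stat": 1.0,
                "df_num": 2,
                "df_den": 12,
                "p_value": r[2],
                "effect_size": r[3] if len(r) > 3 else 1.0,
                "group_means": "",
                "n_per_class": "",
                "testable": True,
            }
            for r in rows
        ]
    )
    df["significant"] = df["p_value"] <= p_threshold
    df["fdr"] = df["p_value"]
    return PgxEqtlResults(df, condition, cell_set, ScanParams(p_threshold=p_threshold))


def _meta(positions, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"},
        index=[f"s{i}" for i in range(len(positions))],
    )


class TestPeakCoordinates:
    """BED intervals are 0-based half-open; SNP positions are 1-based."""

    def _covered(self, pos, start=100, end=200):
        peaks = PeakSet(pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end]}))
        meta = pd.DataFrame({"chrom": "chr1", "pos": [pos]}, index=["s0"])
        return bool(snps_in_peaks(meta, peaks).iloc[0])

    def test_interior_position_covered(self):
        assert self._covered(150)

    def test_bed_start_is_not_covered_in_one_based_terms(self):
        assert not self._covered(100)

    def test_first_covered_base_is_start_plus_one(self):
        assert self._covered(101)

    def test_bed_end_is_last_covered_base(self):
        assert self._covered(200)

    def test_one_past_end_not_covered(self):
        assert not self._covered(201)

    def test_chromosome_mismatch_warns_not_silent(self):
        peaks = PeakSet(pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200]}))
        meta = pd.DataFrame({"chrom": "chr1", "pos": [150]}, index=["s0"])
        with pytest.warns(UserWarning, match="chromosome"):
            out = snps_in_peaks(meta, peaks)
        assert not out.iloc[0]


class TestArNullExclusion:
    def test_pair_significant_only_in_ar_expressed_is_retained(self):
        pos = _results([("s0", "g0", 0.001)])
        null = _results([("s0", "g0", 0.5)], cell_set="AR_NULL")
        out = exclude_ar_null(SignalSet.from_results(pos), null)
        assert not out.table.loc[0, "ar_null_hit"]
        assert len(out.survivors()) == 1

    def test_replicated_pair_is_removed(self):
        pos = _results([("s0", "g0", 0.001)])
        null = _results([("s0", "g0", 0.004)], cell_set="AR_NULL")
        out = exclude_ar_null(SignalSet.from_results(pos), null)
        assert bool(out.table.loc[0, "ar_null_hit"])
        assert out.survivors().empty

    def test_pair_absent_from_null_scan_is_retained(self):
        pos = _results([("s0", "g0", 0.001)])
        null = _results([("s9", "g9", 0.9)], cell_set="AR_NULL")
        out = exclude_ar_null(SignalSet.from_results(pos), null)
        assert len(out.survivors()) == 1

    def test_condition_mismatch_raises(self):
        pos = _results([("s0", "g0", 0.001)], condition=DHT)
        null = _results([("s0", "g0", 0.001)], condition="ENZ")
        with pytest.raises(ValueError, match="condition"):
            exclude_ar_null(SignalSet.from_results(pos), null)


class TestReversibility:
    def test_reversible_signal_retained(self):
        pos = _results([("s0", "g0", 0.001)])
        dual = _results([("s0", "g0", 0.8)], condition=DUAL)
        out = exclude_nonreversible(SignalSet.from_results(pos), dual)
        assert len(out.survivors()) == 1

    def test_dual_significant_signal_removed_threshold_inclusive(self):
        pos = _results([("s0", "g0", 0.001)])
        dual = _results([("s0", "g0", 0.005)], condition=DUAL)  # boundary: p == 0.005
        out = exclude_nonreversible(SignalSet.from_results(pos), dual)
        assert out.survivors().empty

    def test_missing_dual_scan_raises(self):
        pos = _results([("s0", "g0", 0.001)])
        with pytest.raises(ValueError, match="dual"):
            exclude_nonreversible(SignalSet.from_results(pos), None)

    def test_same_direction_option_spares_opposite_sign(self):
        pos = _results([("s0", "g0", 0.001, +1.0)])
        dual = _results([("s0", "g0", 0.001, -1.0)], condition=DUAL)
        strict = exclude_nonreversible(SignalSet.from_results(pos), dual)
        lenient = exclude_nonreversible(
            SignalSet.from_results(pos), dual, same_direction_only=True
        )
        assert strict.survivors().empty
        assert len(lenient.survivors()) == 1


class TestCascadeProperties:
    def _random_fixture(self, rng):
        n = 12
        snps = [f"s{i}" for i in range(n)]
        rows = [(s, f"g{i % 4}", rng.uniform(0, 0.01)) for i, s in enumerate(snps)]
        pos = _results(rows)
        null = _results(
            [(s, g, rng.uniform(0, 0.05)) for s, g, _ in rows], cell_set="AR_NULL"
        )
        dual = _results(
            [(s, g, rng.uniform(0, 0.05)) for s, g, _ in rows], condition=DUAL
        )
        meta = _meta(list(rng.integers(1_000, 100_000, size=n)))
        meta.index = snps
        covered = rng.random(n) < 0.5
        peaks = PeakSet(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": [int(meta.loc[s, "pos"]) - 1 for s, c in zip(snps, covered) if c],
                    "end": [int(meta.loc[s, "pos"]) for s, c in zip(snps, covered) if c],
                }
            )
        )
        return pos, null, dual, peaks, meta

    def test_filters_commute(self):
        """The three predicates are independent: any application order agrees."""
        rng = np.random.default_rng(10)
        for _ in range(100):
            pos, null, dual, peaks, meta = self._random_fixture(rng)
            steps = {
                "null": lambda s: exclude_ar_null(s, null),
                "dual": lambda s: exclude_nonreversible(s, dual),
                "peak": lambda s: filter_by_peak(s, peaks, meta),
            }
            outcomes = []
            for order in itertools.permutations(steps):
                s = SignalSet.from_results(pos)
                for name in order:
                    s = steps[name](s)
                outcomes.append(
                    set(zip(s.survivors()["snp_id"], s.survivors()["gene_id"]))
                )
            assert all(o == outcomes[0] for o in outcomes)

    def test_survivors_shrink_and_grow_monotonically_with_peaks(self):
        rng = np.random.default_rng(11)
        pos, null, dual, peaks, meta = self._random_fixture(rng)
        base = SignalSet.from_results(pos)
        base = exclude_ar_null(base, null)
        base = exclude_nonreversible(base, dual)
        small = filter_by_peak(base, peaks, meta)
        # grow the peak set to cover everything
        grown = PeakSet(
            pd.DataFrame(
                {"chrom": "chr1", "start": meta["pos"] - 1, "end": meta["pos"] + 1}
            )
        )
        large = filter_by_peak(base, grown, meta)
        assert len(small.survivors()) <= len(large.survivors())
        assert len(large.survivors()) <= len(pos.signals)

    def test_flags_are_immutable_once_set(self):
        pos = _results([("s0", "g0", 0.001)])
        null = _results([("s0", "g0", 0.9)], cell_set="AR_NULL")
        s = exclude_ar_null(SignalSet.from_results(pos), null)
        with pytest.raises(ValueError, match="already applied"):
            exclude_ar_null(s, null)

    def test_audit_table_reports_final_status(self):
        pos = _results([("s0", "g0", 0.001), ("s1", "g1", 0.002)])
        null = _results([("s0", "g0", 0.001), ("s1", "g1", 0.9)], cell_set="AR_NULL")
        dual = _results([("s0", "g0", 0.9), ("s1", "g1", 0.9)], condition=DUAL)
        meta = _meta([150, 150_000])
        peaks = PeakSet(pd.DataFrame({"chrom": ["chr1"] * 2, "start": [100, 149_900],
                                      "end": [200, 150_100]}))
        s = exclude_ar_null(SignalSet.from_results(pos), null)
        s = exclude_nonreversible(s, dual)
        s = filter_by_peak(s, peaks, meta)
        audit = audit_table(s)
        assert list(audit["final"]) == [False, True]


def test_direction_concordance_counts_sign_agreement():
    a = _results([("s0", "g0", 0.001, +1.0), ("s1", "g1", 0.001, -1.0)])
    b = _results([("s0", "g0", 0.002, +0.5), ("s1", "g1", 0.002, +0.5)], condition="ENZ")
    shared, same = direction_concordance(
        SignalSet.from_results(a), SignalSet.from_results(b)
    )
    assert (shared, same) == (2, 1)
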