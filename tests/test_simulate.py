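"""Synthetic-study generator: determinism, genotype law, planted truth."""

import numpy as np
import pandas as pd
import pytest

from pgxeqtl.containers import DHT, DUAL, ENZ, VEH
from pgxeqtl.expression import classify_ar_status
from pgxeqtl.genotype_qc import hwe_exact_test
from pgxeqtl.gwas import ld_r2
from pgxeqtl.simulate import (
    AR_GENE,
    PlantedEffect,
    SimulationConfig,
    make_gene_models,
    plant_effects,
    simulate_counts,
    simulate_genotypes,
    simulate_regulome_and_gwas,
    simulate_study,
)


class TestGenotypes:
    def test_same_seed_identical_outputs(self):
        cfg = SimulationConfig(n_snps=30, n_genes=10, seed=5)
        g1, g2 = simulate_genotypes(cfg), simulate_genotypes(cfg)
        pd.testing.assert_frame_equal(g1.dosage, g2.dosage)
        pd.testing.assert_frame_equal(g1.snp_meta, g2.snp_meta)

    def test_forced_maf_half_recovered_within_binomial_noise(self):
        cfg = SimulationConfig(
            n_snps=200, n_genes=10, n_cells_ar_pos=100, n_cells_ar_null=100,
            maf_range=(0.5, 0.5), ld_decay=0.0, missing_rate=0.0, seed=6,
        )
        g = simulate_genotypes(cfg)
        freqs = g.dosage.to_numpy().mean(axis=0) / 2
        n_alleles = 2 * 200
        sd = np.sqrt(0.5 * 0.5 / n_alleles)
        assert (np.abs(freqs - 0.5) < 3 * sd + 0.0).mean() > 0.95

    def test_full_ld_makes_block_copies(self):
        cfg = SimulationConfig(
            n_snps=10, n_genes=5, ld_block_size=5, ld_decay=1.0,
            missing_rate=0.0, seed=7,
        )
        g = simulate_genotypes(cfg)
        d = g.dosage.to_numpy()
        for j in range(1, 5):  # first block: all columns identical
            assert np.array_equal(d[:, 0], d[:, j])
            assert ld_r2(d[:, 0], d[:, j]) == pytest.approx(1.0)

    def test_zero_ld_mean_r2_matches_null_expectation(self):
        """Independent SNPs: E[r^2] ~ 1/(n-1) for n individuals."""
        n_cells = 50
        cfg = SimulationConfig(
            n_snps=200, n_genes=5, n_cells_ar_pos=25, n_cells_ar_null=25,
            ld_decay=0.0, ld_block_size=200, missing_rate=0.0,
            maf_range=(0.3, 0.5), seed=8,
        )
        d = simulate_genotypes(cfg).dosage.to_numpy()
        rng = np.random.default_rng(0)
        r2s = []
        for _ in range(2000):
            i, j = rng.choice(200, 2, replace=False)
            r2s.append(ld_r2(d[:, i], d[:, j]))
        # Monte-Carlo oracle for the null mean of r^2 of independent binomials
        oracle = []
        for _ in range(2000):
            a = rng.binomial(2, 0.4, n_cells).astype(float)
            b = rng.binomial(2, 0.4, n_cells).astype(float)
            if a.var() and b.var():
                oracle.append(ld_r2(a, b))
        assert np.nanmean(r2s) == pytest.approx(np.mean(oracle), abs=0.01)
        assert np.nanmean(r2s) == pytest.approx(1 / (n_cells - 1), abs=0.01)

    def test_adjacent_r2_tracks_ld_decay(self):
        cfg = SimulationConfig(
            n_snps=400, n_genes=5, n_cells_ar_pos=150, n_cells_ar_null=150,
            ld_block_size=4, ld_decay=0.8, missing_rate=0.0, seed=9,
        )
        d = simulate_genotypes(cfg).dosage.to_numpy()
        adj = [
            ld_r2(d[:, j], d[:, j + 1])
            for j in range(399)
            if j // 4 == (j + 1) // 4
        ]
        assert np.nanmean(adj) == pytest.approx(0.8, abs=0.05)

    def test_hwe_holds_at_generated_sites(self):
        """Exact-test rejections at alpha=0.001 stay within the null bound."""
        cfg = SimulationConfig(
            n_snps=2000, n_genes=5, ld_decay=0.0, ld_block_size=1,
            missing_rate=0.0, seed=10,
        )
        d = simulate_genotypes(cfg).dosage.to_numpy()
        rejected = 0
        for j in range(2000):
            col = d[:, j]
            p = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                               int((col == 2).sum()))
            rejected += p <= 0.001
        assert rejected / 2000 <= 0.002

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_snps=0)
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))

    def test_at_least_two_autosomes(self):
        cfg = SimulationConfig(n_snps=30, n_genes=10, seed=11)
        assert simulate_genotypes(cfg).snp_meta["chrom"].nunique() >= 2


class TestCounts:
    def _cfg(self, effects=(), **kw):
        kw.setdefault("n_snps", 24)
        kw.setdefault("n_genes", 60)
        kw.setdefault("ld_block_size", 3)
        kw.setdefault("maf_range", (0.35, 0.5))
        kw.setdefault("nb_mean_range", (64, 512))
        kw.setdefault("seed", 12)
        return SimulationConfig(effect_table=list(effects), **kw)

    def test_empty_effect_table_gives_null_fold_changes(self):
        cfg = self._cfg()
        g = simulate_genotypes(cfg)
        counts = simulate_counts(g, cfg)
        fc = np.log2(
            (counts[DHT].counts.to_numpy()[:-1] + 0.5)
            / (counts[VEH].counts.to_numpy()[:-1] + 0.5)
        )
        assert abs(fc.mean()) < 0.1

    def test_planted_effect_shifts_log2fc_by_beta_times_dosage(self):
        """Dosage-2 minus dosage-0 mean response ~ 2*beta in the effect condition."""
        cfg = self._cfg(
            n_cells_ar_pos=150, n_cells_ar_null=10, missing_rate=0.0, seed=13
        )
        g = simulate_genotypes(cfg)
        genes = make_gene_models(cfg, g)
        effects = plant_effects(cfg, g, genes, {"DHT": 1}, beta=2.0)
        cfg = self._cfg(
            effects, n_cells_ar_pos=150, n_cells_ar_null=10, missing_rate=0.0, seed=13
        )
        counts = simulate_counts(g, cfg)
        eff = effects[0]
        fc = np.log2(
            (counts[DHT].counts.loc[eff.gene_id] + 0.5)
            / (counts[VEH].counts.loc[eff.gene_id] + 0.5)
        )
        dos = g.dosage[eff.snp_id]
        pos_cells = cfg.ar_pos_cells
        m2 = fc[pos_cells][dos[pos_cells] == 2].mean()
        m0 = fc[pos_cells][dos[pos_cells] == 0].mean()
        assert (m2 - m0) * eff.direction == pytest.approx(4.0, abs=0.6)

    def test_effects_absent_from_vehicle_and_from_ar_null_cells(self):
        cfg0 = self._cfg(missing_rate=0.0, seed=14)
        g = simulate_genotypes(cfg0)
        genes = make_gene_models(cfg0, g)
        effects = plant_effects(cfg0, g, genes, {"DHT": 1}, beta=3.0)
        cfg = self._cfg(effects, missing_rate=0.0, seed=14)
        counts = simulate_counts(g, cfg)
        eff = effects[0]
        null_cells = cfg.ar_null_cells
        fc_null = np.log2(
            (counts[DHT].counts.loc[eff.gene_id, null_cells] + 0.5)
            / (counts[VEH].counts.loc[eff.gene_id, null_cells] + 0.5)
        )
        dos = g.dosage[eff.snp_id][null_cells]
        if (dos == 2).any() and (dos == 0).any():
            gap = fc_null[dos == 2].mean() - fc_null[dos == 0].mean()
            assert abs(gap) < 2.0  # far below the planted 6-unit separation

    def test_ar_gene_classification_is_forced_by_construction(self):
        cfg = self._cfg(seed=15)
        g = simulate_genotypes(cfg)
        counts = simulate_counts(g, cfg)
        status = classify_ar_status(
            {cond: cm.counts.loc[AR_GENE] for cond, cm in counts.items()}
        )
        labels = dict(zip(status["cell_id"], status["label"]))
        assert all(labels[c] == "AR_EXPRESSED" for c in cfg.ar_pos_cells)
        assert all(labels[c] == "AR_NULL" for c in cfg.ar_null_cells)

    def test_unknown_effect_ids_rejected(self):
        cfg = self._cfg([PlantedEffect("rs999999", "GENE00001", "DHT")])
        g = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="unknown SNP"):
            simulate_counts(g, cfg)


class TestRegulomeAndGwas:
    def test_zero_peak_fraction_covers_only_effect_snps(self):
        cfg = SimulationConfig(
            n_snps=24, n_genes=60, ld_block_size=3, maf_range=(0.35, 0.5),
            peak_fraction=0.0, seed=16,
        )
        g = simulate_genotypes(cfg)
        genes = make_gene_models(cfg, g)
        effects = plant_effects(cfg, g, genes, {"DHT": 1, "ENZ": 1})
        cfg.effect_table.extend(effects)
        peaks, _, _ = simulate_regulome_and_gwas(g, cfg)
        assert len(peaks) == 2
        covered_pos = set(peaks.intervals["start"] + 150)
        assert covered_pos == {int(g.snp_meta.loc[e.snp_id, "pos"]) for e in effects}

    def test_gwas_hits_on_planted_snps_or_high_ld_proxies(self):
        study = simulate_study(
            SimulationConfig(
                n_snps=24, n_genes=60, ld_block_size=3, maf_range=(0.35, 0.5), seed=17
            ),
            auto_effects={"DHT": 2, "ENZ": 2},
        )
        hits = study.gwas.hits()
        for eff in study.config.effect_table:
            linked = []
            for hit_snp in hits["snp_id"]:
                r2 = ld_r2(
                    study.genotypes.dosage[eff.snp_id].to_numpy(float),
                    study.genotypes.dosage[hit_snp].to_numpy(float),
                )
                linked.append(hit_snp == eff.snp_id or (not np.isnan(r2) and r2 >= 0.8))
            assert any(linked)

    def test_dominant_chromhmm_category_wins_consensus(self):
        from pgxeqtl.annotation import collapse_state, consensus_annotation

        cfg = SimulationConfig(
            n_snps=30, n_genes=10, n_tissues=9, tissue_dominance=1.0, seed=18
        )
        g = simulate_genotypes(cfg)
        _, chromhmm, _ = simulate_regulome_and_gwas(g, cfg)
        for snp, df in chromhmm.table.groupby("snp_id"):
            cats = [collapse_state(s) for s in df["state"]]
            assert len(set(cats)) == 1
            assert consensus_annotation(cats) == cats[0]


def test_study_level_determinism(small_study):
    cfg = small_study.config
    again = simulate_study(cfg)  # effect table already resolved in cfg
    pd.testing.assert_frame_equal(
        small_study.genotypes.dosage, again.genotypes.dosage
    )
    for cond in (VEH, DHT, ENZ, DUAL):
        pd.testing.assert_frame_equal(
            small_study.counts[cond].counts, again.counts[cond].counts
        )
    pd.testing.assert_frame_equal(small_study.gwas.table, again.gwas.table)
    pd.testing.assert_frame_equal(
        small_study.chromhmm.table, again.chromhmm.table
    )
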