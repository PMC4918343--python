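"""Synthetic cohort generator: LD structure, effect calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from neutroqtl import (
    SimulationConfig,
    make_annotations,
    make_catalog_fixture,
    simulate_dataset,
    simulate_expression,
    simulate_genotypes,
)


def fitted_r2(g, y):
    mask = ~np.isnan(g)
    return np.corrcoef(g[mask], y[mask])[0, 1] ** 2


class TestGenotypes:
    def test_values_and_missingness(self, small_dataset):
        genotypes, _, _ = small_dataset
        vals = genotypes.genotypes.to_numpy()
        assert np.isin(vals[~np.isnan(vals)], [0, 1, 2]).all()
        frac = np.isnan(vals).mean()
        assert 0.005 < frac < 0.05  # around the configured 2%

    def test_no_missing_when_rate_zero(self):
        cfg = SimulationConfig(n_samples=40, n_snps=20, n_probes=2, missing_rate=0.0, seed=1)
        panel = simulate_genotypes(cfg)
        assert panel.genotypes.notna().all().all()

    def test_ld_decay_zero_gives_independence(self):
        cfg = SimulationConfig(n_samples=500, n_snps=20, n_probes=2,
                               ld_decay=0.0, missing_rate=0.0, seed=2)
        panel = simulate_genotypes(cfg)
        corr = panel.genotypes.corr().to_numpy()
        off = corr[np.triu_indices_from(corr, k=1)]
        assert np.abs(off).mean() < 0.1

    def test_ld_decays_within_block(self):
        cfg = SimulationConfig(n_samples=1000, n_snps=10, n_probes=2, ld_block_size=10,
                               ld_decay=0.95, missing_rate=0.0, seed=3)
        G = simulate_genotypes(cfg).genotypes.to_numpy()
        r2_adjacent = np.corrcoef(G[:, 0], G[:, 1])[0, 1] ** 2
        r2_ends = np.corrcoef(G[:, 0], G[:, 9])[0, 1] ** 2
        assert r2_adjacent > r2_ends

    def test_blocks_are_independent(self):
        cfg = SimulationConfig(n_samples=1500, n_snps=20, n_probes=2, ld_block_size=10,
                               ld_decay=0.95, missing_rate=0.0, seed=4)
        G = simulate_genotypes(cfg).genotypes.to_numpy()
        # last SNP of block 1 vs first SNP of block 2
        r2_across = np.corrcoef(G[:, 9], G[:, 10])[0, 1] ** 2
        assert r2_across < 0.05

    def test_hardy_weinberg_at_large_n(self):
        cfg = SimulationConfig(n_samples=5000, n_snps=5, n_probes=2,
                               missing_rate=0.0, ld_decay=0.0, seed=5)
        panel = simulate_genotypes(cfg)
        for snp in panel.snp_ids:
            g = panel.genotypes[snp].to_numpy()
            q = g.mean() / 2.0  # minor-allele frequency estimate
            expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
            observed = np.array([(g == k).mean() for k in (0, 1, 2)])
            sd = np.sqrt(expected * (1 - expected) / g.size)
            assert (np.abs(observed - expected) < 4 * sd + 0.005).all()

    def test_maf_within_configured_range(self):
        cfg = SimulationConfig(n_samples=500, n_snps=30, n_probes=2,
                               maf_range=(0.1, 0.4), missing_rate=0.0, seed=6)
        maf = simulate_genotypes(cfg).maf()
        assert (maf > 0.1 - 0.06).all() and (maf < 0.4 + 0.06).all()

    def test_positions_strictly_increasing(self, small_dataset):
        genotypes, _, _ = small_dataset
        assert (np.diff(genotypes.snps["pos"].to_numpy()) > 0).all()

    def test_determinism(self, small_config):
        a = simulate_genotypes(small_config).genotypes.to_numpy()
        b = simulate_genotypes(small_config).genotypes.to_numpy()
        assert np.array_equal(a, b, equal_nan=True)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 1},
            {"n_snps": 0},
            {"maf_range": (0.0, 0.3)},
            {"maf_range": (0.3, 0.6)},
            {"maf_range": (0.4, 0.2)},
            {"missing_rate": 1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestExpression:
    def test_null_probes_uncorrelated(self):
        cfg = SimulationConfig(n_samples=500, n_snps=10, n_probes=5,
                               missing_rate=0.0, seed=8)
        genotypes, expression, truth = simulate_dataset(cfg)
        assert truth.records.empty
        log2 = np.log2(expression.values.to_numpy())
        for j in range(cfg.n_probes):
            for snp in genotypes.snp_ids:
                r2 = fitted_r2(genotypes.genotypes[snp].to_numpy(), log2[:, j])
                assert r2 < 0.05

    def test_noiseless_effect_is_perfect_fit(self):
        cfg = SimulationConfig(n_samples=50, n_snps=10, n_probes=2, noise_sd=0.0,
                               missing_rate=0.0, seed=9,
                               effect_table=[("probe0001", "snp00003", 0.5)])
        genotypes, expression, _ = simulate_dataset(cfg)
        g = genotypes.genotypes["snp00003"].to_numpy()
        y = np.log2(expression.values["probe0001"].to_numpy())
        assert fitted_r2(g, y) == pytest.approx(1.0, abs=1e-12)

    def test_effect_calibration_converges(self):
        cfg = SimulationConfig(n_samples=5000, n_snps=10, n_probes=2,
                               missing_rate=0.0, seed=10,
                               effect_table=[("probe0000", "snp00002", 0.3)])
        genotypes, expression, _ = simulate_dataset(cfg)
        g = genotypes.genotypes["snp00002"].to_numpy()
        y = np.log2(expression.values["probe0000"].to_numpy())
        assert fitted_r2(g, y) == pytest.approx(0.3, abs=0.02)

    def test_truth_table_matches_effects(self, small_dataset, small_config):
        _, _, truth = small_dataset
        assert len(truth.records) == len(small_config.effect_table)
        assert truth.effect_probes() == {e.probe_id for e in small_config.effect_table}
        assert (truth.records["variance_explained"] < 1).all()

    def test_unknown_effect_ids_rejected(self):
        with pytest.raises(ValueError, match="unknown SNP"):
            SimulationConfig(n_snps=5, n_probes=2,
                             effect_table=[("probe0000", "snp99999", 0.5)])
        with pytest.raises(ValueError, match="unknown probe"):
            SimulationConfig(n_snps=5, n_probes=2,
                             effect_table=[("probe9999", "snp00001", 0.5)])

    def test_variance_explained_bounds(self):
        with pytest.raises(ValueError, match="variance_explained"):
            SimulationConfig(effect_table=[("probe0000", "snp00000", 1.0)])

    def test_determinism(self, small_config):
        genotypes = simulate_genotypes(small_config)
        a, _ = simulate_expression(genotypes, small_config)
        b, _ = simulate_expression(genotypes, small_config)
        assert np.array_equal(a.values.to_numpy(), b.values.to_numpy())


class TestAnnotations:
    def test_row_counts(self, small_config):
        snp_ann, probe_ann = make_annotations(small_config)
        assert len(snp_ann) == small_config.n_snps
        assert len(probe_ann) == small_config.n_probes

    def test_single_snp_single_probe_in_window(self):
        cfg = SimulationConfig(n_samples=10, n_snps=1, n_probes=1, seed=0)
        snp_ann, probe_ann = make_annotations(cfg)
        dist = abs(int(snp_ann["pos"].iloc[0]) - int(probe_ann["midpoint"].iloc[0]))
        assert dist <= 250_000

    def test_every_probe_has_cis_snp(self, small_config):
        from neutroqtl import cis_pairs

        snp_ann, probe_ann = make_annotations(small_config)
        pairs = cis_pairs(snp_ann, probe_ann)
        assert set(pairs["probe_id"]) == set(probe_ann.index)

    def test_effect_probe_anchored_on_its_snp(self, small_config):
        snp_ann, probe_ann = make_annotations(small_config)
        for eff in small_config.effect_table:
            dist = abs(int(snp_ann.at[eff.snp_id, "pos"]) -
                       int(probe_ann.at[eff.probe_id, "midpoint"]))
            assert dist <= 250_000


class TestCatalogFixture:
    def test_single_record(self):
        cat = make_catalog_fixture(["rs1"], ["asthma"], seed=1)
        assert len(cat) == 1
        assert set(cat.columns) == {"snp_id", "trait", "p_value"}

    def test_full_cross_count(self):
        cat = make_catalog_fixture([f"rs{i}" for i in range(10)],
                                   ["a", "b", "c"], seed=1)
        assert len(cat) == 30

    def test_deterministic(self):
        a = make_catalog_fixture(["rs1", "rs2"], ["t"], seed=3)
        b = make_catalog_fixture(["rs1", "rs2"], ["t"], seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_snp_list_rejected(self):
        with pytest.raises(ValueError):
            make_catalog_fixture([], ["t"], seed=1)


class TestRoundTrips:
    def test_genotype_tsv_round_trip(self, small_dataset, tmp_path):
        genotypes, _, _ = small_dataset
        genotypes.to_tsv(tmp_path / "g.tsv", tmp_path / "a.tsv")
        from neutroqtl import GenotypePanel

        back = GenotypePanel.from_tsv(tmp_path / "g.tsv", tmp_path / "a.tsv")
        assert np.array_equal(
            back.genotypes.to_numpy(), genotypes.genotypes.to_numpy(), equal_nan=True
        )
        assert list(back.snps.index) == list(genotypes.snps.index)

    def test_expression_tsv_round_trip(self, small_dataset, tmp_path):
        _, expression, _ = small_dataset
        expression.to_tsv(tmp_path / "e.tsv", tmp_path / "p.tsv")
        from neutroqtl import ExpressionPanel

        back = ExpressionPanel.from_tsv(tmp_path / "e.tsv", tmp_path / "p.tsv")
        np.testing.assert_allclose(
            back.values.to_numpy(), expression.values.to_numpy(), rtol=1e-9
        )

    def test_vcf_export_readable(self, small_dataset, tmp_path):
        genotypes, _, _ = small_dataset
        path = tmp_path / "g.vcf"
        genotypes.to_vcf(path)
        cyvcf2 = pytest.importorskip("cyvcf2")
        variants = list(cyvcf2.VCF(str(path)))
        assert len(variants) == genotypes.n_snps
        v0 = variants[0]
        expected = genotypes.genotypes[v0.ID].to_numpy()
        alt_counts = np.array([
            sum(1 for a in gt[:2] if a == 1) if gt[0] != -1 else np.nan
            for gt in v0.genotypes
        ], dtype=float)
        assert np.array_equal(alt_counts, expected, equal_nan=True)
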