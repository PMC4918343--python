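"""Genotypic LD, proxy expansion, sharing partition, enrichment, homologs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neutroqtl import (
    LdMatrix,
    OverlapReport,
    expand_by_ld,
    gwas_intersect,
    hypergeom_enrichment,
    hypergeom_log10,
    ld_r2,
    map_homologs,
    percent,
    share_across_datasets,
)


def ld_from_frame(values: dict[str, dict[str, float]]) -> LdMatrix:
    ids = list(values)
    mat = pd.DataFrame(1.0, index=ids, columns=ids)
    for a, row in values.items():
        for b, v in row.items():
            mat.loc[a, b] = v
            mat.loc[b, a] = v
    return LdMatrix(mat)


class TestLdR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_allele_flip_invariance(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        g1 = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        g2 = np.array([0, 1, 1, 2, 2, 2], dtype=float)
        expected = np.corrcoef(g1, g2)[0, 1] ** 2  # direct correlation oracle
        assert ld_r2(g1, g2) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.binomial(2, 0.4, 30).astype(float)
        b = rng.binomial(2, 0.3, 30).astype(float)
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            return
        v = ld_r2(a, b)
        assert ld_r2(b, a) == pytest.approx(v, rel=1e-12)
        assert ld_r2(2 - a, b) == pytest.approx(v, rel=1e-12)

    def test_pairwise_complete_and_constant(self):
        a = np.array([0, 1, 2, np.nan, 1], dtype=float)
        b = np.array([0, 1, 2, 1, np.nan], dtype=float)
        assert ld_r2(a, b) == pytest.approx(1.0)  # complete pairs are identical
        assert np.isnan(ld_r2(np.array([1.0, 1.0, 1.0, 1.0]), np.array([0.0, 1, 2, 1])))
        with pytest.raises(ValueError, match="fewer than 3"):
            ld_r2(np.array([0.0, np.nan, 1]), np.array([1.0, 2, np.nan]))


class TestExpandByLd:
    def test_strict_threshold_one_only_perfect_proxies(self):
        ld = ld_from_frame({"a": {"b": 1.0, "c": 0.99}, "b": {"c": 0.5}, "c": {}})
        assert expand_by_ld({"a"}, ld, threshold=1.0, inclusive=True) == {"a", "b"}
        assert expand_by_ld({"a"}, ld, threshold=1.0) == {"a"}

    def test_empty_seed_set(self):
        ld = ld_from_frame({"a": {}, "b": {}})
        assert expand_by_ld(set(), ld) == set()

    def test_no_transitive_closure(self):
        ld = ld_from_frame({"a": {"b": 0.9, "c": 0.5}, "b": {"c": 0.9}, "c": {}})
        assert expand_by_ld({"a"}, ld, threshold=0.8) == {"a", "b"}

    def test_unknown_seed_rejected(self):
        ld = ld_from_frame({"a": {}})
        with pytest.raises(KeyError):
            expand_by_ld({"zzz"}, ld)

    def test_from_genotypes_matches_ld_r2(self, small_dataset):
        genotypes, _, _ = small_dataset
        ld = LdMatrix.from_genotypes(genotypes)
        a, b = genotypes.snp_ids[0], genotypes.snp_ids[1]
        direct = ld_r2(genotypes.genotypes[a], genotypes.genotypes[b])
        assert ld.value(a, b) == pytest.approx(direct, rel=1e-10)


class TestShareAcrossDatasets:
    def _ours(self):
        return pd.DataFrame(
            {
                "probe_id": ["p0", "p1", "p2"],
                "gene_symbol": ["G0", "G1", "G2"],
                "snp_id": ["a", "b", "c"],
            }
        )

    def _identity_ld(self):
        return ld_from_frame({"a": {"b": 0.0, "c": 0.0}, "b": {"c": 0.0}, "c": {}})

    def test_verbatim_datasets_all_shared(self):
        ours = self._ours()
        ext = ours[["gene_symbol", "snp_id"]]
        report = share_across_datasets(ours, ext, ext, self._identity_ld())
        assert report.counts == {
            "all_three": 3, "with_monocytes_only": 0, "with_bcells_only": 0, "unique": 0,
        }

    def test_empty_externals_all_unique(self):
        ours = self._ours()
        empty = pd.DataFrame(columns=["gene_symbol", "snp_id"])
        report = share_across_datasets(ours, empty, empty, self._identity_ld())
        assert report.counts["unique"] == 3
        assert report.percentages["unique"] == 100.0

    def test_ld_proxy_counts_as_shared(self):
        ours = self._ours()
        # monocyte dataset tags gene G0 with SNP b, which is in LD with a
        ld = ld_from_frame({"a": {"b": 0.85, "c": 0.0}, "b": {"c": 0.0}, "c": {}})
        mono = pd.DataFrame({"gene_symbol": ["G0"], "snp_id": ["b"]})
        empty = pd.DataFrame(columns=["gene_symbol", "snp_id"])
        report = share_across_datasets(ours, mono, empty, ld, threshold=0.8)
        assert report.counts["with_monocytes_only"] == 1
        # below threshold: not shared
        low = ld_from_frame({"a": {"b": 0.5, "c": 0.0}, "b": {"c": 0.0}, "c": {}})
        report = share_across_datasets(ours, mono, empty, low, threshold=0.8)
        assert report.counts["with_monocytes_only"] == 0

    def test_partition_conserves_total(self):
        ours = self._ours()
        mono = pd.DataFrame({"gene_symbol": ["G0", "G1"], "snp_id": ["a", "b"]})
        bc = pd.DataFrame({"gene_symbol": ["G0"], "snp_id": ["a"]})
        report = share_across_datasets(ours, mono, bc, self._identity_ld())
        assert sum(report.counts.values()) == report.total == 3
        assert report.shared_count("monocytes") == 2
        assert report.shared_count("bcells") == 1


class TestOverlapReport:
    def test_published_partition_percentages(self):
        report = OverlapReport(
            counts={
                "all_three": 248,
                "with_monocytes_only": 159,
                "with_bcells_only": 28,
                "unique": 536,
            },
            total=971,
        )
        assert report.percentages == {
            "all_three": 25.54,
            "with_monocytes_only": 16.37,
            "with_bcells_only": 2.88,
            "unique": 55.2,
        }

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            OverlapReport(counts={"all_three": 1, "unique": 1}, total=3)

    def test_percent_rounding_half_even(self):
        assert percent(1, 8) == 12.5
        assert percent(84, 818, ndigits=1) == 10.3


class TestHypergeom:
    def test_zero_overlap_is_one(self):
        assert hypergeom_enrichment(0, 5, 5, 20) == 1.0

    def test_five_of_five_from_ten(self):
        assert hypergeom_enrichment(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_exact_enumeration_spot(self):
        from math import comb

        N, K, n, k = 25, 9, 7, 4
        exact = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
        assert hypergeom_enrichment(k, K, n, N) == pytest.approx(exact / comb(N, n), rel=1e-10)

    def test_log10_tracks_linear(self):
        p = hypergeom_enrichment(8, 10, 10, 40)
        assert hypergeom_log10(8, 10, 10, 40) == pytest.approx(np.log10(p), rel=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_enrichment(2, 5, 15, 10)


class TestGwasIntersect:
    def _catalog(self):
        rows = []
        for i in range(20):
            rows.append((f"rs{i}", "crohn" if i < 8 else "asthma", 1e-8))
        rows += [(f"rs{i}", "psoriasis", 1e-9) for i in range(4, 10)]
        return pd.DataFrame(rows, columns=["snp_id", "trait", "p_value"])

    def test_empty_expansion_zero_traits(self):
        assert gwas_intersect(set(), self._catalog()).empty

    def test_full_containment_reports_every_trait(self):
        catalog = self._catalog()
        table = gwas_intersect(set(catalog["snp_id"]), catalog)
        assert set(table["trait"]) == {"crohn", "asthma", "psoriasis"}

    def test_counts_match_hand_enumeration(self):
        catalog = self._catalog()
        expanded = {f"rs{i}" for i in range(6)} | {"rs15"}
        table = gwas_intersect(expanded, catalog).set_index("trait")
        # crohn = rs0-7, psoriasis = rs4-9, asthma = rs8-19
        assert table.at["crohn", "n_overlap"] == 6
        assert table.at["psoriasis", "n_overlap"] == 2
        assert table.at["asthma", "n_overlap"] == 1
        k, K, n, N = 6, 7, 8, 20
        assert table.at["crohn", "p_enrichment"] == pytest.approx(
            hypergeom_enrichment(k, K, n, N), rel=1e-12
        )

    def test_malformed_rows_skipped(self, caplog):
        catalog = self._catalog()
        catalog.loc[0, "snp_id"] = None
        with caplog.at_level("WARNING"):
            table = gwas_intersect({"rs1"}, catalog)
        assert "malformed" in caplog.text
        assert table.at[0, "n_overlap"] == 1


class TestMapHomologs:
    def test_identity_mapping(self):
        table = pd.DataFrame({"mouse": ["Il18rap", "Nod2"], "human": ["IL18RAP", "NOD2"]})
        result = map_homologs(["Il18rap", "Nod2"], table)
        assert result.mapped == {"Il18rap": "IL18RAP", "Nod2": "NOD2"}
        assert result.unmapped == []

    def test_empty_table_all_unmapped(self):
        table = pd.DataFrame({"a": [], "b": []})
        result = map_homologs(["X", "Y"], table)
        assert result.mapped == {}
        assert result.unmapped == ["X", "Y"]

    def test_conflicting_duplicates_named(self):
        table = pd.DataFrame({"a": ["G1", "G1"], "b": ["H1", "H2"]})
        with pytest.raises(ValueError, match="G1"):
            map_homologs(["G1"], table)
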