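"""LD proxy expansion, cross-dataset sharing and catalog intersection.

Computes genotypic r^2 from the cohort, expands significant SNPs through
one-hop LD (r^2 > 0.8), partitions probes by sharing with two external
eQTL lists (a Venn over "found in monocytes" / "found in B cells"), and
intersects the expanded SNP set with a GWAS-style catalog.
"""

import pandas as pd

from neutroqtl import (
    LdMatrix,
    SimulationConfig,
    expand_by_ld,
    gwas_intersect,
    hypergeom_enrichment,
    make_catalog_fixture,
    map_cis_eqtls,
    quantile_normalize_log2,
    share_across_datasets,
    simulate_dataset,
)

config = SimulationConfig(
    n_samples=114, n_snps=100, n_probes=20, missing_rate=0.01,
    effect_table=[(f"probe{i:04d}", f"snp{12 * i + 5:05d}", 0.55) for i in range(4)],
    seed=23,
)
genotypes, expression, truth = simulate_dataset(config)
table, _ = map_cis_eqtls(
    genotypes, quantile_normalize_log2(expression), n_perm=500, alpha=0.005, seed=2
)
sig = table[table["significant"]]
our = sig.merge(expression.probes["gene_symbol"], left_on="probe_id",
                right_index=True)[["probe_id", "gene_symbol", "snp_id"]]

ld = LdMatrix.from_genotypes(genotypes)
expanded = expand_by_ld(set(sig["snp_id"]), ld, threshold=0.8)
print(f"significant SNPs: {sig['snp_id'].nunique()}; after one-hop LD expansion "
      f"(r^2 > 0.8): {len(expanded)}")

# external stand-ins: the monocyte list shares 2 of our genes, B cells 1
genes = our.drop_duplicates("probe_id")
monocytes = genes.head(2)[["gene_symbol", "snp_id"]]
bcells = genes.head(1)[["gene_symbol", "snp_id"]]
report = share_across_datasets(our, monocytes, bcells, ld, threshold=0.8,
                               universe=config.n_probes)
print("sharing partition:", report.counts)
print("as percentages of our probes:", report.percentages)
print("monocyte-sharing enrichment P:",
      f"{report.enrichment['monocytes']['p']:.3g}")

# an enriched trait (tagged by our eQTL SNPs) next to an unrelated one
enriched = make_catalog_fixture(sorted(expanded)[:6], ["Crohn disease"], seed=5)
background = make_catalog_fixture(
    [f"rs_bg{i}" for i in range(30)] + sorted(expanded)[:1], ["height"], seed=6
)
catalog = pd.concat([enriched, background], ignore_index=True)
hits = gwas_intersect(expanded, catalog)
print("\nGWAS-catalog intersection (per trait, hypergeometric enrichment):")
print(hits.to_string(index=False))

print("\nworked enrichment example: drawing all 5 of a 5-SNP trait from a "
      f"10-SNP universe has P = {hypergeom_enrichment(5, 5, 5, 10):.6f} (= 1/252)")
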