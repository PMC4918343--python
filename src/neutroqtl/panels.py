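"""Sample-by-marker data containers shared across the pipeline.

Two thin wrappers around :class:`pandas.DataFrame` carry the cohort data:
:class:`GenotypePanel` (samples x SNPs, allele counts 0/1/2 with NaN for
missing calls) and :class:`ExpressionPanel` (samples x probes, microarray
intensities, raw or quantile-normalized/log2). Marker annotations ride
alongside the matrix and stay index-aligned with its columns.

On disk the matrices follow the array-study convention of markers as rows
and samples as columns (TSV, ``NA`` for missing); annotations are plain
TSVs with 1-based coordinates. A minimal VCF writer is provided for
genotype interchange.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "ExpressionPanel"]

_SNP_ANNOTATION_COLS = ["chrom", "pos", "ref", "alt"]
_PROBE_ANNOTATION_COLS = ["chrom", "midpoint", "gene_symbol", "has_common_snp"]


def _check_ids_match(matrix: pd.DataFrame, annotation: pd.DataFrame, what: str) -> None:
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].tolist()
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")
    if not matrix.columns.equals(annotation.index):
        raise ValueError(f"{what} annotation index must equal matrix columns (same order)")


@dataclass
class GenotypePanel:
    """Allele-count genotypes (samples x SNPs) with SNP annotations.

    Parameters
    ----------
    genotypes
        Float matrix of values in {0, 1, 2, NaN}; rows are samples,
        columns are SNP ids. NaN marks a missing (no-call) genotype.
    snps
        Annotation indexed by SNP id with columns ``chrom`` (label),
        ``pos`` (1-based bp), ``ref``, ``alt``.
    """

    genotypes: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.genotypes.to_numpy(dtype=float, copy=False)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0) | (vals == 2.0)
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"genotype values must be 0/1/2/NaN; saw {bad[:5]}")
        _check_ids_match(self.genotypes, self.snps, "SNP")
        missing_cols = [c for c in ("chrom", "pos") if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"SNP annotation lacks columns {missing_cols}")
        if (self.snps["pos"].to_numpy() < 0).any():
            raise ValueError("SNP positions must be non-negative")

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per SNP."""
        return self.genotypes.notna().mean(axis=0)

    def maf(self) -> pd.Series:
        """Empirical minor-allele frequency per SNP (non-missing calls)."""
        freq = self.genotypes.mean(axis=0, skipna=True) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def select_snps(self, snp_ids) -> "GenotypePanel":
        ids = list(snp_ids)
        return GenotypePanel(self.genotypes[ids], self.snps.loc[ids])

    def select_samples(self, sample_ids) -> "GenotypePanel":
        return GenotypePanel(self.genotypes.loc[list(sample_ids)], self.snps)

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, genotype_path, annotation_path) -> None:
        """Write the matrix (SNPs as rows, ``NA`` for missing) and annotation."""
        out = self.genotypes.T
        out.index.name = "snp_id"
        out.to_csv(genotype_path, sep="\t", na_rep="NA", float_format="%.10g")
        ann = self.snps.copy()
        ann.index.name = "snp_id"
        ann.to_csv(annotation_path, sep="\t")

    @classmethod
    def from_tsv(cls, genotype_path, annotation_path) -> "GenotypePanel":
        mat = pd.read_csv(genotype_path, sep="\t", index_col=0, na_values=["NA"])
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype={"chrom": str})
        return cls(mat.T.astype(float), ann.loc[mat.index])

    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 with GT calls derived from allele counts."""
        samples = self.sample_ids
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        order = self.snps.sort_values(["chrom", "pos"]).index
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom in pd.unique(self.snps.loc[order, "chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
            for snp_id in order:
                row = self.snps.loc[snp_id]
                calls = self.genotypes[snp_id]
                gts = "\t".join("./." if pd.isna(v) else gt_map[float(v)] for v in calls)
                fh.write(
                    f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\t"
                    f"{row.get('ref', 'A')}\t{row.get('alt', 'G')}\t.\t.\t.\tGT\t{gts}\n"
                )


@dataclass
class ExpressionPanel:
    """Expression intensities (samples x probes) with probe annotations.

    ``state`` tracks the normalization status: ``"raw"`` for intensities as
    measured, ``"quantile_log2"`` after quantile normalization across
    samples followed by a log2 transform (the analysis space).

    The probe annotation carries ``chrom``, ``midpoint`` (1-based bp),
    ``gene_symbol`` and ``has_common_snp`` (probe sequence overlaps a
    common variant and should be dropped before association testing); an
    optional ``detected_fraction`` column records per-probe detection.
    """

    values: pd.DataFrame
    probes: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "quantile_log2"):
            raise ValueError(f"unknown normalization state {self.state!r}")
        _check_ids_match(self.values, self.probes, "probe")
        missing_cols = [c for c in ("chrom", "midpoint") if c not in self.probes.columns]
        if missing_cols:
            raise ValueError(f"probe annotation lacks columns {missing_cols}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    def select_probes(self, probe_ids) -> "ExpressionPanel":
        ids = list(probe_ids)
        return ExpressionPanel(self.values[ids], self.probes.loc[ids], self.state)

    def select_samples(self, sample_ids) -> "ExpressionPanel":
        return ExpressionPanel(self.values.loc[list(sample_ids)], self.probes, self.state)

    def with_values(self, values: pd.DataFrame, state: str) -> "ExpressionPanel":
        return replace(self, values=values, state=state)

    def to_tsv(self, values_path, annotation_path) -> None:
        out = self.values.T
        out.index.name = "probe_id"
        out.to_csv(values_path, sep="\t", float_format="%.10g")
        ann = self.probes.copy()
        ann.index.name = "probe_id"
        ann.to_csv(annotation_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, annotation_path, state: str = "raw") -> "ExpressionPanel":
        mat = pd.read_csv(values_path, sep="\t", index_col=0)
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype={"chrom": str})
        if "has_common_snp" in ann.columns:
            ann["has_common_snp"] = ann["has_common_snp"].astype(bool)
        return cls(mat.T.astype(float), ann.loc[mat.index], state)
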