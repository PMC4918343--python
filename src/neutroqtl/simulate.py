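"""Synthetic cohort generator with known ground truth.

Emulates the structure of an array-genotyped expression cohort: ~114
samples, a flat MAF spectrum, block LD, array-like genotype missingness,
and log-normal microarray intensities carrying additive cis effects of
prescribed variance explained. Every downstream stage (QC, normalization,
cis association, LD expansion, catalog intersection) can therefore be
exercised against a :class:`TruthTable` without any external download.

LD model
--------
Genotypes are drawn from a latent-Gaussian copula: per haplotype, a
standard-normal AR(1) process within each block (correlation
``ld_decay**distance-in-SNPs``) is thresholded at the normal quantile of
the SNP's allele frequency, and the two haplotype indicators are summed.
This yields Hardy-Weinberg genotype frequencies per SNP and a tunable,
monotonically decaying genotypic r^2 within blocks; blocks are mutually
independent. Haplotype phase, recombination maps and population structure
are deliberately not modelled.

Expression model
----------------
The signal is additive on the log2 scale: for an effect record
(probe, SNP, v) the probe's log2 expression is
``baseline + beta * genotype + N(0, noise_sd)`` with ``beta`` calibrated
so that ``beta^2 Var(g) / (beta^2 Var(g) + noise_sd^2) = v`` using the
empirical genotype variance. Probes without an effect are pure noise.
Exported intensities are ``2**signal`` (log-normal, state ``"raw"``) so
that the quantile-normalize + log2 stage is exercised; ``log2`` of the
raw panel recovers the signal exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panels import ExpressionPanel, GenotypePanel

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "TruthTable",
    "make_annotations",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_dataset",
    "make_detection_calls",
    "make_catalog_fixture",
    "write_dataset",
]

CIS_WINDOW = 250_000  # bp each side of the probe midpoint

# distinct deterministic sub-streams of the user seed
_STREAM_GENOTYPES = 0x47
_STREAM_EXPRESSION = 0x58
_STREAM_CATALOG = 0x43


@dataclass(frozen=True)
class EffectSpec:
    """One simulated cis effect: probe, causal SNP and target variance explained."""

    probe_id: str
    snp_id: str
    variance_explained: float


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions being emulated: 114 samples,
    MAF drawn uniformly in (0.05, 0.5), LD blocks of 10 SNPs with an
    adjacent-SNP latent correlation of 0.9, 1% missing genotype calls
    and unit Gaussian noise on the log2 expression scale.
    """

    n_samples: int = 114
    n_snps: int = 200
    n_probes: int = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_decay: float = 0.9
    missing_rate: float = 0.01
    effect_table: list[EffectSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0
    snp_spacing: int = 5_000
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.effect_table = [
            e if isinstance(e, EffectSpec) else EffectSpec(*e) for e in self.effect_table
        ]
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_snps < 1 or self.n_probes < 1:
            raise ValueError("dimensions must be positive (n_samples >= 2)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.ld_decay <= 1.0):
            raise ValueError("ld_decay must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        snp_ids = set(self.snp_ids())
        probe_ids = set(self.probe_ids())
        for eff in self.effect_table:
            if not (0.0 <= eff.variance_explained < 1.0):
                raise ValueError(
                    f"variance_explained must lie in [0, 1); got {eff.variance_explained}"
                )
            if eff.snp_id not in snp_ids:
                raise ValueError(f"effect references unknown SNP {eff.snp_id!r}")
            if eff.probe_id not in probe_ids:
                raise ValueError(f"effect references unknown probe {eff.probe_id!r}")

    # deterministic id/coordinate scheme shared by all generator stages
    def snp_ids(self) -> list[str]:
        return [f"snp{i:05d}" for i in range(self.n_snps)]

    def probe_ids(self) -> list[str]:
        return [f"probe{i:04d}" for i in range(self.n_probes)]

    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]

    def snp_positions(self) -> np.ndarray:
        """1-based, strictly increasing positions on ``chrom``."""
        return 10_001 + self.snp_spacing * np.arange(self.n_snps)


@dataclass
class TruthTable:
    """Ground truth of the simulated effects (one record per effect)."""

    records: pd.DataFrame  # probe_id, snp_id, true_beta, variance_explained

    def __post_init__(self) -> None:
        if (self.records["variance_explained"] >= 1.0).any():
            raise ValueError("variance_explained must be < 1")

    def effect_probes(self) -> set[str]:
        return set(self.records["probe_id"])


def make_annotations(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build SNP and probe annotations for the configured cohort.

    Probe midpoints are anchored on SNP positions (effect probes sit on
    their causal SNP) so every probe has at least one SNP within the
    +/-250 kbp cis window. Coordinates are 1-based; a single autosome is
    used by default.
    """
    positions = config.snp_positions()
    snp_ann = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(config.snp_ids(), name="snp_id"),
    )

    snp_index = {s: i for i, s in enumerate(config.snp_ids())}
    anchor_for: dict[str, int] = {}
    for eff in config.effect_table:
        anchor_for.setdefault(eff.probe_id, snp_index[eff.snp_id])
    stride = max(1, config.n_snps // config.n_probes)
    midpoints = []
    for i, probe_id in enumerate(config.probe_ids()):
        anchor = anchor_for.get(probe_id, (i * stride) % config.n_snps)
        midpoints.append(int(positions[anchor]))
    probe_ann = pd.DataFrame(
        {
            "chrom": config.chrom,
            "midpoint": midpoints,
            "gene_symbol": [f"GENE{i:04d}" for i in range(config.n_probes)],
            "has_common_snp": False,
        },
        index=pd.Index(config.probe_ids(), name="probe_id"),
    )
    return snp_ann, probe_ann


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Draw an allele-count genotype matrix under the block-LD copula.

    Reproducible: identical config (including seed) gives bit-identical
    output. Missing calls are masked uniformly at random (MCAR) at
    ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_GENOTYPES])
    n, m = config.n_samples, config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)

    rho = config.ld_decay
    eps = rng.standard_normal((2, n, m))
    z = np.empty_like(eps)
    z[..., 0] = eps[..., 0]
    carry = math.sqrt(max(0.0, 1.0 - rho * rho))
    for j in range(1, m):
        if j % config.ld_block_size == 0:  # block boundary: restart the chain
            z[..., j] = eps[..., j]
        else:
            z[..., j] = rho * z[..., j - 1] + carry * eps[..., j]

    alleles = z < thresholds  # per-haplotype minor-allele indicators
    geno = alleles.sum(axis=0).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        geno[mask] = np.nan

    genotypes = pd.DataFrame(geno, index=config.sample_ids(), columns=config.snp_ids())
    snp_ann, _ = make_annotations(config)
    return GenotypePanel(genotypes, snp_ann)


def simulate_expression(
    genotypes: GenotypePanel, config: SimulationConfig
) -> tuple[ExpressionPanel, TruthTable]:
    """Generate raw (log-normal) intensities carrying the configured cis effects.

    The per-effect slope ``beta`` is calibrated against the empirical
    genotype variance so the realized variance explained converges to the
    target as the cohort grows. Missing genotype calls are mean-filled
    when building the signal (the sample's phenotype exists regardless of
    whether the array call succeeded).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_EXPRESSION])
    n, p = config.n_samples, config.n_probes
    probe_ids = config.probe_ids()

    baselines = rng.uniform(6.0, 10.0, size=p)  # typical log2 array intensities
    signal = baselines + rng.standard_normal((n, p)) * config.noise_sd

    col = {pid: j for j, pid in enumerate(probe_ids)}
    truth_rows = []
    for eff in config.effect_table:
        g = genotypes.genotypes[eff.snp_id].to_numpy(dtype=float)
        g = np.where(np.isnan(g), np.nanmean(g), g)
        sd_g = g.std()
        if sd_g == 0:
            raise ValueError(f"effect SNP {eff.snp_id!r} is monomorphic in this cohort")
        ve = eff.variance_explained
        scale = config.noise_sd if config.noise_sd > 0 else 1.0
        beta = scale * math.sqrt(ve / (1.0 - ve)) / sd_g
        signal[:, col[eff.probe_id]] += beta * g
        truth_rows.append((eff.probe_id, eff.snp_id, beta, ve))

    values = pd.DataFrame(
        np.exp2(signal), index=config.sample_ids(), columns=probe_ids
    )
    _, probe_ann = make_annotations(config)
    truth = TruthTable(
        pd.DataFrame(
            truth_rows, columns=["probe_id", "snp_id", "true_beta", "variance_explained"]
        )
    )
    return ExpressionPanel(values, probe_ann, state="raw"), truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypePanel, ExpressionPanel, TruthTable]:
    """Convenience: genotypes + expression + truth in one call."""
    genotypes = simulate_genotypes(config)
    expression, truth = simulate_expression(genotypes, config)
    return genotypes, expression, truth


def make_detection_calls(
    expression: ExpressionPanel,
    floor_quantile: float = 0.05,
    dark_probes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Fabricate boolean detection calls for the flagging stage.

    A probe is "detected" in a sample when its intensity exceeds the
    global ``floor_quantile`` of the panel; probes listed in
    ``dark_probes`` are forced undetected everywhere (to exercise the
    low-detection flag). The real platform's detection p-value machinery
    is out of scope, so calls are an input downstream.
    """
    floor = float(np.quantile(expression.values.to_numpy(), floor_quantile))
    calls = expression.values > floor
    for probe in dark_probes:
        calls[probe] = False
    return calls


def make_catalog_fixture(snp_ids, traits, seed: int) -> pd.DataFrame:
    """Deterministic GWAS-catalog-style table (snp_id, trait, p_value).

    Full cross of SNPs x traits with log-uniform association p-values; a
    stand-in for a published-associations catalog in tests and demos.
    """
    snp_ids = list(snp_ids)
    traits = list(traits)
    if not snp_ids:
        raise ValueError("snp_ids must be non-empty")
    rng = np.random.default_rng([seed, _STREAM_CATALOG])
    rows = [(s, t) for s in snp_ids for t in traits]
    pvals = 10.0 ** rng.uniform(-12, -5, size=len(rows))
    return pd.DataFrame(
        {
            "snp_id": [r[0] for r in rows],
            "trait": [r[1] for r in rows],
            "p_value": pvals,
        }
    )


def write_dataset(
    out_dir,
    genotypes: GenotypePanel,
    expression: ExpressionPanel,
    truth: TruthTable | None = None,
    vcf: bool = False,
) -> dict[str, Path]:
    """Write the cohort as the pipeline's TSV interchange files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "snp_annotation": out / "snp_annotation.tsv",
        "expression": out / "expression_raw.tsv",
        "probe_annotation": out / "probe_annotation.tsv",
    }
    genotypes.to_tsv(paths["genotypes"], paths["snp_annotation"])
    expression.to_tsv(paths["expression"], paths["probe_annotation"])
    if truth is not None:
        paths["truth"] = out / "truth_table.tsv"
        truth.records.to_csv(paths["truth"], sep="\t", index=False)
    if vcf:
        paths["vcf"] = out / "genotypes.vcf"
        genotypes.to_vcf(paths["vcf"])
    return paths
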