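"""End-to-end orchestration: simulate -> QC -> normalize -> cis scan -> overlap.

A run is fully described by a :class:`RunConfig` (serializable to YAML),
writes every stage artifact into one directory, logs a record-count
ledger per stage, and is reproducible: the same config yields identical
output tables. The external comparison lists and the GWAS-style catalog
used by the overlap stages are deterministic fixtures subsampled from the
run's own significant eQTLs (stand-ins for published datasets, which are
out of scope here).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cis import map_cis_eqtls
from .ld import LdMatrix, expand_by_ld, gwas_intersect, share_across_datasets
from .preprocess import (
    detect_duplicates,
    filter_probes,
    filter_snps,
    flag_low_detection,
    quantile_normalize_log2,
)
from .simulate import (
    SimulationConfig,
    make_catalog_fixture,
    make_detection_calls,
    simulate_dataset,
    write_dataset,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

# sharing rates of the deterministic external-list fixtures (fractions of
# our significant records sampled into the monocyte / B-cell stand-ins,
# mirroring the sharing observed between myeloid-origin vs lymphoid subsets)
_MONOCYTE_SHARE = 0.42
_BCELL_SHARE = 0.28
_STREAM_EXTERNAL = 0x0E


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the analysis constants of the emulated study:
    call rate 0.95, detection fraction 0.05, duplicate r^2 0.98, cis
    window 250 kbp, 10,000 permutations at the 0.001 tail, LD 0.8. The
    single ``seed`` drives the simulation, the permutation streams and
    the fixture subsampling.
    """

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    min_call_rate: float = 0.95
    min_detection: float = 0.05
    dup_r2: float = 0.98
    window: int = 250_000
    n_perm: int = 10_000
    alpha: float = 0.001
    ld_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_call_rate <= 1 and 0 <= self.min_detection <= 1):
            raise ValueError("rates must lie in (0, 1]")
        if not (0 < self.alpha <= 1 and 0 <= self.ld_threshold <= 1 and 0 < self.dup_r2 <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.window < 0 or self.n_perm < 1:
            raise ValueError("window must be >= 0 and n_perm >= 1")
        self.sim.seed = self.seed  # one seed reproduces the whole run

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["effect_table"] = [list(dataclasses.astuple(e)) for e in self.sim.effect_table]
        d["sim"]["maf_range"] = list(self.sim.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        d["sim"] = SimulationConfig(**sim)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute every stage into ``out_dir`` and return that directory.

    Artifacts: the simulated cohort TSVs, QC report (JSON), normalized
    expression, the eQTL table with per-probe thresholds, the sharing
    (Venn) report, the GWAS-catalog intersection table, a run log and a
    manifest with versions, seed and per-stage record counts. A stage
    failure aborts with the stage named in the raised error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("neutroqtl")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    counts: dict[str, int] = {}
    stage = "setup"

    def _stage(name: str) -> str:
        logger.info("stage %s", name)
        return name

    try:
        stage = _stage("simulate")
        genotypes, expression, truth = simulate_dataset(config.sim)
        write_dataset(out, genotypes, expression, truth)
        counts["snps_simulated"] = genotypes.n_snps
        counts["probes_simulated"] = expression.n_probes
        counts["samples_simulated"] = genotypes.n_samples
        logger.info(
            "simulated %d samples x %d SNPs, %d probes, %d true effects",
            genotypes.n_samples, genotypes.n_snps, expression.n_probes, len(truth.records),
        )

        stage = _stage("preprocess")
        genotypes, snp_report = filter_snps(genotypes, min_call_rate=config.min_call_rate)
        expression, probe_report = filter_probes(expression)
        calls = make_detection_calls(expression)
        flagged, fractions = flag_low_detection(expression, calls, config.min_detection)
        probe_report.flagged_probes = flagged
        expression.probes["detected_fraction"] = fractions
        dup_pairs = detect_duplicates(expression, r2_threshold=config.dup_r2)
        probe_report.duplicate_pairs = dup_pairs
        drop = sorted({b for _, b, _ in dup_pairs})
        if drop:
            keep = [s for s in expression.sample_ids if s not in drop]
            expression = expression.select_samples(keep)
            genotypes = genotypes.select_samples(keep)
            logger.info("removed %d duplicate samples: %s", len(drop), drop)
        expression = quantile_normalize_log2(expression)
        expression.to_tsv(out / "expression_norm.tsv", out / "probe_annotation_qc.tsv")
        with open(out / "qc_report.json", "w") as fh:
            json.dump(
                {"snps": snp_report.to_dict(), "probes": probe_report.to_dict()},
                fh, indent=2,
            )
        for rep in (snp_report, probe_report):
            logger.info(
                "ledger %s: in=%d retained=%d removed=%s",
                rep.stage, rep.n_input, rep.n_retained, rep.removed,
            )
            assert rep.n_input == rep.n_retained + sum(rep.removed.values())
        counts["snps_retained"] = genotypes.n_snps
        counts["probes_retained"] = expression.n_probes
        counts["samples_retained"] = genotypes.n_samples

        stage = _stage("map-eqtl")
        table, summary = map_cis_eqtls(
            genotypes, expression,
            window=config.window, n_perm=config.n_perm,
            alpha=config.alpha, seed=config.seed,
        )
        table.to_csv(out / "eqtl_table.tsv", sep="\t", index=False, float_format="%.6g")
        counts.update({f"eqtl_{k}": v for k, v in summary.items()})
        logger.info("eqtl summary: %s", summary)

        stage = _stage("overlap")
        sig = table[table["significant"]]
        our = sig.merge(
            expression.probes["gene_symbol"], left_on="probe_id", right_index=True
        )[["probe_id", "gene_symbol", "snp_id"]].drop_duplicates()
        rng = np.random.default_rng([config.seed, _STREAM_EXTERNAL])
        ext_cols = ["gene_symbol", "snp_id"]

        def subsample(frac: float) -> pd.DataFrame:
            if our.empty:
                return pd.DataFrame(columns=ext_cols)
            n = int(round(frac * len(our)))
            idx = rng.choice(len(our), size=n, replace=False)
            return our.iloc[sorted(idx)][ext_cols].reset_index(drop=True)

        monocytes = subsample(_MONOCYTE_SHARE)
        bcells = subsample(_BCELL_SHARE)
        monocytes.to_csv(out / "external_monocytes.tsv", sep="\t", index=False)
        bcells.to_csv(out / "external_bcells.tsv", sep="\t", index=False)
        ld = LdMatrix.from_genotypes(genotypes)
        report = share_across_datasets(
            our, monocytes, bcells, ld,
            threshold=config.ld_threshold,
            universe=counts["probes_retained"],
        )
        report.to_json(out / "overlap_report.json")
        counts["overlap_total_probes"] = report.total
        logger.info("overlap partition: %s (%s)", report.counts, report.percentages)

        stage = _stage("gwas")
        sig_snps = set(sig["snp_id"])
        expanded = expand_by_ld(sig_snps, ld, threshold=config.ld_threshold)
        catalog_snps = sorted(expanded)[:10] + [
            s for s in genotypes.snp_ids if s not in expanded
        ][:20]
        if catalog_snps:
            catalog = make_catalog_fixture(
                catalog_snps,
                ["Crohn disease", "psoriasis", "asthma"],
                seed=config.seed,
            )
            catalog.to_csv(out / "gwas_catalog_fixture.tsv", sep="\t", index=False)
            gwas_table = gwas_intersect(expanded, catalog)
        else:
            gwas_table = pd.DataFrame()
        gwas_table.to_csv(out / "gwas_overlap.tsv", sep="\t", index=False)
        counts["ld_expanded_snps"] = len(expanded)
        counts["gwas_traits_hit"] = int(len(gwas_table))
        logger.info("gwas: %d expanded SNPs, %d traits hit", len(expanded), len(gwas_table))

        manifest = {
            "package": "neutroqtl",
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "counts": counts,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        config.to_yaml(out / "config_used.yaml")
    except Exception as exc:
        logger.exception("pipeline aborted in stage %s", stage)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
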