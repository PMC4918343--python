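"""SNP and probe quality control and expression normalization.

Filters mirror standard array-cohort practice: autosome-only SNPs with
call rate >= 95% and at least two observed genotype classes; autosome-only
probes with no common variant under the probe sequence; probes detected in
fewer than 5% of samples are flagged but retained; expression is quantile
normalized across samples and log2 transformed before association testing;
duplicated samples are detected by near-perfect expression correlation.

Exclusion rules are applied in a fixed precedence order (non-autosome,
then call rate, then monomorphic) so a marker failing several rules is
counted exactly once and QC reports are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import ExpressionPanel, GenotypePanel

__all__ = [
    "DEFAULT_AUTOSOMES",
    "QcReport",
    "filter_snps",
    "filter_probes",
    "flag_low_detection",
    "quantile_normalize_log2",
    "detect_duplicates",
]

DEFAULT_AUTOSOMES = frozenset(
    {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}
)


@dataclass
class QcReport:
    """Per-rule removal counts for one filtering stage.

    Invariant: ``n_input == n_retained + sum(removed.values())`` — every
    input marker is either retained or counted under exactly one rule.
    """

    stage: str
    n_input: int
    n_retained: int
    removed: dict[str, int]
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    flagged_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + sum(self.removed.values()):
            raise ValueError(
                f"QC ledger violated in stage {self.stage!r}: "
                f"{self.n_input} != {self.n_retained} + {sum(self.removed.values())}"
            )

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed": self.removed,
            "removed_ids": self.removed_ids,
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            "flagged_probes": self.flagged_probes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def filter_snps(
    panel: GenotypePanel,
    min_call_rate: float = 0.95,
    autosomes: frozenset[str] | set[str] = DEFAULT_AUTOSOMES,
) -> tuple[GenotypePanel, QcReport]:
    """Drop non-autosomal, low-call-rate and monomorphic SNPs.

    A SNP is retained when its chromosome label is autosomal, its call
    rate is >= ``min_call_rate`` (the boundary itself is retained) and at
    least two genotype classes are observed among non-missing calls.
    """
    if panel.n_snps == 0:
        raise ValueError("empty genotype panel")
    chroms = panel.snps["chrom"].astype(str)
    non_autosomal = ~chroms.isin(autosomes)
    call_rate = panel.call_rate()
    low_call = call_rate < min_call_rate
    n_classes = panel.genotypes.nunique(axis=0, dropna=True)
    monomorphic = n_classes <= 1

    removed_ids: dict[str, list[str]] = {}
    reason = pd.Series("", index=panel.genotypes.columns)
    for rule, mask in (
        ("non_autosome", non_autosomal.to_numpy()),
        ("call_rate", low_call.to_numpy()),
        ("monomorphic", monomorphic.to_numpy()),
    ):
        hit = (reason == "") & mask
        reason[hit] = rule
        removed_ids[rule] = list(reason.index[hit])

    keep = reason == ""
    filtered = panel.select_snps(reason.index[keep])
    report = QcReport(
        stage="filter_snps",
        n_input=panel.n_snps,
        n_retained=int(keep.sum()),
        removed={rule: len(ids) for rule, ids in removed_ids.items()},
        removed_ids=removed_ids,
    )
    return filtered, report


def filter_probes(
    panel: ExpressionPanel,
    autosomes: frozenset[str] | set[str] = DEFAULT_AUTOSOMES,
    drop_snp_in_probe: bool = True,
) -> tuple[ExpressionPanel, QcReport]:
    """Keep autosomal probes, optionally dropping probes that contain a common SNP."""
    if panel.n_probes == 0:
        raise ValueError("empty expression panel")
    chroms = panel.probes["chrom"].astype(str)
    non_autosomal = ~chroms.isin(autosomes)
    if drop_snp_in_probe and "has_common_snp" in panel.probes.columns:
        snp_in_probe = panel.probes["has_common_snp"].astype(bool)
    else:
        snp_in_probe = pd.Series(False, index=panel.probes.index)

    removed_ids: dict[str, list[str]] = {}
    reason = pd.Series("", index=panel.probes.index)
    for rule, mask in (
        ("non_autosome", non_autosomal.to_numpy()),
        ("snp_in_probe", snp_in_probe.to_numpy()),
    ):
        hit = (reason == "") & mask
        reason[hit] = rule
        removed_ids[rule] = list(reason.index[hit])

    keep = reason == ""
    filtered = panel.select_probes(reason.index[keep])
    report = QcReport(
        stage="filter_probes",
        n_input=panel.n_probes,
        n_retained=int(keep.sum()),
        removed={rule: len(ids) for rule, ids in removed_ids.items()},
        removed_ids=removed_ids,
    )
    return filtered, report


def flag_low_detection(
    panel: ExpressionPanel,
    detection_calls: pd.DataFrame,
    min_fraction: float = 0.05,
) -> tuple[list[str], pd.Series]:
    """Flag probes detected in fewer than ``min_fraction`` of samples.

    Flagged probes are *not* removed — selective loss of expression can be
    biologically meaningful — so only the flag set and the per-probe
    detected fractions are returned; the panel is untouched.
    """
    if detection_calls.shape != panel.values.shape:
        raise ValueError(
            f"detection calls shape {detection_calls.shape} does not match "
            f"panel shape {panel.values.shape}"
        )
    calls = detection_calls.loc[panel.values.index, panel.values.columns]
    fractions = calls.astype(bool).mean(axis=0)
    flagged = list(fractions.index[fractions < min_fraction])
    return flagged, fractions


def quantile_normalize_log2(panel: ExpressionPanel) -> ExpressionPanel:
    """Quantile normalize across samples, then log2 transform.

    Each sample's rank-k value is replaced by the mean of the rank-k
    values across samples; tied values within a sample receive the mean
    of the reference values at their tied ranks. After the transform every
    sample shares one sorted value vector by construction.
    """
    if panel.state != "raw":
        raise ValueError(f"expected a raw panel, got state {panel.state!r}")
    X = panel.values.to_numpy(dtype=float)
    if not (X > 0).all():
        raise ValueError("quantile_normalize_log2 requires strictly positive intensities")

    order = np.argsort(X, axis=1, kind="stable")
    reference = np.take_along_axis(X, order, axis=1).mean(axis=0)
    out = np.empty_like(X)
    np.put_along_axis(out, order, np.broadcast_to(reference, X.shape), axis=1)
    for i in range(X.shape[0]):  # ties: mean of the tied ranks' reference values
        row = pd.Series(X[i])
        if row.duplicated().any():
            out[i] = pd.Series(out[i]).groupby(row).transform("mean").to_numpy()

    values = pd.DataFrame(np.log2(out), index=panel.values.index, columns=panel.values.columns)
    return panel.with_values(values, state="quantile_log2")


def detect_duplicates(
    panel: ExpressionPanel, r2_threshold: float = 0.98
) -> list[tuple[str, str, float]]:
    """Report sample pairs whose expression profiles are near-identical.

    Returns unordered pairs with squared Pearson correlation across probes
    at or above ``r2_threshold`` (so ``r2_threshold=1.0`` reports exactly
    the bit-identical pairs).
    """
    if panel.n_samples < 2:
        raise ValueError("duplicate detection needs at least 2 samples")
    X = panel.values.to_numpy(dtype=float)
    r2 = np.corrcoef(X) ** 2
    samples = panel.sample_ids
    pairs = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if r2[i, j] >= r2_threshold:
                pairs.append((samples[i], samples[j], float(r2[i, j])))
    return pairs
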