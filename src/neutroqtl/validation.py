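"""Genotype-stratified stimulation-response statistics.

Covers the qPCR arithmetic (dCt, 2^-dCt, treated-vs-mock fold change)
and the nonparametric battery used to compare response distributions
between genotype groups: a two-sided Mann-Whitney U test for two groups
(exact by enumeration in the small-sample regime, normal approximation
with tie correction otherwise), Kruskal-Wallis for three or more, and
Dunn's pairwise z-tests with Bonferroni adjustment as the post hoc.

The exact Mann-Whitney p is the symmetric-tail probability
P(|U - n1*n2/2| >= |u_obs - n1*n2/2|) over all equally likely label
assignments of the pooled observations, computed with mid-ranks so tied
and identical groups behave sensibly (identical groups give p = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrRecord",
    "ResponseRecord",
    "delta_ct",
    "linear_expression",
    "fold_change",
    "fold_changes_from_table",
    "mannwhitney_exact",
    "dunn_posthoc",
    "compare_genotypes",
    "GenotypeComparison",
]

EXACT_MAX_N = 20  # combined group size up to which the exact U null is enumerated


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR measurement: cycle thresholds for a gene and its endogenous control."""

    sample_id: str
    genotype: str
    condition: str  # "mock" or "treated"
    gene: str
    ct_goi: float
    ct_endctl: float

    def __post_init__(self) -> None:
        if self.ct_goi <= 0 or self.ct_endctl <= 0:
            raise ValueError("Ct values must be positive")


@dataclass(frozen=True)
class ResponseRecord:
    """Treated-vs-mock fold change of one gene in one donor."""

    sample_id: str
    genotype: str
    gene: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


def delta_ct(record: QpcrRecord) -> float:
    """dCt = Ct(gene of interest) - Ct(endogenous control); may be negative."""
    return record.ct_goi - record.ct_endctl


def linear_expression(dct: float) -> float:
    """Linear-scale relative expression 2^(-dCt)."""
    return 2.0 ** (-dct)


def fold_change(treated: QpcrRecord, mock: QpcrRecord) -> ResponseRecord:
    """Fold change of treated over mock: 2^(dCt_mock - dCt_treated)."""
    if treated.sample_id != mock.sample_id or treated.gene != mock.gene:
        raise ValueError("treated and mock records must share sample and gene")
    fc = 2.0 ** (delta_ct(mock) - delta_ct(treated))
    return ResponseRecord(treated.sample_id, treated.genotype, treated.gene, fc)


def fold_changes_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Pair treated/mock rows of a qPCR table into per-donor fold changes.

    Expects columns sample_id, genotype, condition (mock/treated), gene,
    ct_goi, ct_endctl; returns sample_id, genotype, gene, fold_change.
    """
    needed = {"sample_id", "genotype", "condition", "gene", "ct_goi", "ct_endctl"}
    if not needed <= set(table.columns):
        raise ValueError(f"qPCR table must have columns {sorted(needed)}")
    rows = []
    for (sample, gene), sub in table.groupby(["sample_id", "gene"], sort=True):
        by_cond = {c: r for c, r in zip(sub["condition"], sub.itertuples())}
        if "mock" not in by_cond or "treated" not in by_cond:
            raise ValueError(f"sample {sample!r}, gene {gene!r}: need one mock and one treated row")
        t, m = by_cond["treated"], by_cond["mock"]
        rec = fold_change(
            QpcrRecord(sample, t.genotype, "treated", gene, t.ct_goi, t.ct_endctl),
            QpcrRecord(sample, m.genotype, "mock", gene, m.ct_goi, m.ct_endctl),
        )
        rows.append((rec.sample_id, rec.genotype, rec.gene, rec.fold_change))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "gene", "fold_change"])


def _u_statistic_from_ranks(ranks: np.ndarray, idx: tuple[int, ...], n1: int) -> float:
    return float(sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2.0)


def mannwhitney_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled mid-ranks and
    returns (U of the first group, symmetric-tail p). Handles ties via
    mid-ranks; identical groups give p = 1 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic_from_ranks(ranks, tuple(range(n1)), n1)
    mid = n1 * n2 / 2.0
    dev = abs(u_obs - mid)
    total = math.comb(n1 + n2, n1)
    count = 0
    for idx in combinations(range(n1 + n2), n1):
        u = _u_statistic_from_ranks(ranks, idx, n1)
        if abs(u - mid) >= dev - 1e-12:
            count += 1
    return u_obs, count / total


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's pairwise rank z-tests after an omnibus Kruskal-Wallis.

    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups of the pooled mid-ranks.
    ``adjust`` is ``"bonferroni"`` (default, m = number of pairs) or
    ``"none"``.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    sizes = [d.size for d in data]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs = list(combinations(range(len(names)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se = math.sqrt(sigma2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append((names[i], names[j], z, p, p_adj))
    return pd.DataFrame(rows, columns=["group1", "group2", "z", "p_unadjusted", "p_adjusted"])


@dataclass
class GenotypeComparison:
    """Result of the between-genotype response comparison."""

    test: str  # "mann-whitney" or "kruskal-wallis"
    method: str  # "exact" or "asymptotic"
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    pairwise: pd.DataFrame | None = None  # Dunn table for >= 3 groups


def compare_genotypes(
    groups: Mapping[str, Sequence[float]],
    exact_max_n: int = EXACT_MAX_N,
    adjust: str = "bonferroni",
) -> GenotypeComparison:
    """Compare response distributions across genotype classes.

    Two groups: two-sided Mann-Whitney U, exact by enumeration when the
    combined size is <= ``exact_max_n`` (the regime of typical validation
    cohorts, 7-9 donors per genotype), otherwise the tie-corrected normal
    approximation. Three or more groups: Kruskal-Wallis chi-square
    approximation with tie correction, followed by Dunn's pairwise
    z-tests (Bonferroni-adjusted by default).
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least 2 genotype groups")
    for name, d in zip(names, data):
        if d.size == 0:
            raise ValueError(f"genotype group {name!r} has no observations")
    sizes = {name: int(d.size) for name, d in zip(names, data)}

    if len(names) == 2:
        x, y = data
        if x.size + y.size <= exact_max_n:
            u, p = mannwhitney_exact(x, y)
            return GenotypeComparison("mann-whitney", "exact", u, p, sizes)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return GenotypeComparison(
            "mann-whitney", "asymptotic", float(res.statistic), float(res.pvalue), sizes
        )

    stat, p = stats.kruskal(*data)
    pairwise = dunn_posthoc(groups, adjust=adjust)
    return GenotypeComparison("kruskal-wallis", "asymptotic", float(stat), float(p), sizes, pairwise)
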