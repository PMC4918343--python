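"""Cis association engine.

Pairs each expression probe with the SNPs inside a +/-250 kbp window
around its midpoint, fits an additive ordinary-least-squares model of
(log2) expression on allele count per pair, and calibrates per-probe
significance with Churchill/Stranger-style phenotype permutations: the
expression vector is label-swapped, the minimum nominal P across the
probe's cis SNPs is recorded for each permutation, and a pair is called
significant when its nominal P falls strictly below the ``alpha`` lower
tail of that min-P distribution. The same permutation is shared by all
cis SNPs of a probe within one iteration, preserving their LD; samples
with a missing genotype are excluded pairwise, both in the observed fit
and under permutation.

P-values come from the two-sided t test on the slope (``n_used - 2``
degrees of freedom) evaluated through the survival function, so extreme
associations underflow gracefully instead of printing zero.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "DEFAULT_WINDOW",
    "AssocRecord",
    "ProbeThreshold",
    "cis_pairs",
    "linreg_assoc",
    "permute_probe",
    "call_eqtls",
    "map_cis_eqtls",
    "probe_rng",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 250_000
_P_FLOOR = 1e-300  # keep p strictly positive even for numerically perfect fits


@dataclass(frozen=True)
class AssocRecord:
    """OLS association of one SNP-probe pair on the pairwise-complete samples."""

    probe_id: str
    snp_id: str
    n_used: int
    beta: float
    r2: float
    p_nominal: float


@dataclass
class ProbeThreshold:
    """Permutation significance threshold for one probe.

    ``p_threshold`` is the k-th smallest of the ``n_perm`` permutation
    min-P values with ``k = ceil(alpha * n_perm)`` (no interpolation);
    at ``alpha=0.001`` and 10,000 permutations this is the 10th order
    statistic. The full vector of minima is kept for inspection.
    """

    probe_id: str
    n_perm: int
    alpha: float
    p_threshold: float
    minima: np.ndarray = field(repr=False, default=None)

    def summary(self) -> dict[str, float]:
        qs = (0.001, 0.01, 0.05, 0.5, 1.0)
        return {f"q{q:g}": float(np.quantile(self.minima, q)) for q in qs}


def _order_statistic_index(alpha: float, n_perm: int) -> int:
    # guard against float round-up: 0.001 * 10000 must give k=10, not 11
    k = math.ceil(alpha * n_perm - 1e-9)
    return min(max(k, 1), n_perm)


def cis_pairs(
    snp_annotation: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Enumerate SNP-probe pairs within ``window`` bp of the probe midpoint.

    Bounds are inclusive: a SNP exactly ``window`` bp from the midpoint is
    tested. Returns a frame with columns ``probe_id``, ``snp_id`` and the
    signed ``distance`` (SNP position minus probe midpoint).
    """
    rows: list[tuple[str, str, int]] = []
    by_chrom = {
        str(chrom): sub.sort_values("pos")
        for chrom, sub in snp_annotation.groupby(snp_annotation["chrom"].astype(str))
    }
    for probe_id, probe in probe_annotation.iterrows():
        sub = by_chrom.get(str(probe["chrom"]))
        if sub is None:
            continue
        mid = int(probe["midpoint"])
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, mid - window, side="left")
        hi = np.searchsorted(pos, mid + window, side="right")
        for snp_id, snp_pos in zip(sub.index[lo:hi], pos[lo:hi]):
            rows.append((probe_id, snp_id, int(snp_pos) - mid))
    return pd.DataFrame(rows, columns=["probe_id", "snp_id", "distance"])


def _t_sf_two_sided(t2: np.ndarray, df: np.ndarray | int) -> np.ndarray:
    """Two-sided p from squared t statistics via the survival function."""
    p = 2.0 * special.stdtr(df, -np.sqrt(t2))
    return np.clip(p, _P_FLOOR, 1.0)


def _assoc_complete(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, r^2 and two-sided p for complete vectors (>=3 obs, g non-constant)."""
    n = g.size
    gd = g - g.mean()
    yd = y - y.mean()
    sxx = float(gd @ gd)
    syy = float(yd @ yd)
    sxy = float(gd @ yd)
    beta = sxy / sxx
    if syy == 0.0:  # constant expression: slope 0, no evidence
        return beta, 0.0, 1.0
    r2 = min((sxy * sxy) / (sxx * syy), 1.0)
    df = n - 2
    if r2 >= 1.0:
        return beta, 1.0, _P_FLOOR
    t2 = df * r2 / (1.0 - r2)
    return beta, r2, float(_t_sf_two_sided(np.asarray(t2), df))


def linreg_assoc(
    genotype, expression, probe_id: str = "", snp_id: str = ""
) -> AssocRecord:
    """Additive OLS of expression on allele count for one pair.

    Samples with a missing genotype are dropped pairwise. Requires at
    least 3 complete samples and 2 distinct genotype classes; otherwise
    the association is undefined and a ``ValueError`` is raised (callers
    skip and log such pairs).
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(expression, dtype=float)
    if g.shape != y.shape:
        raise ValueError("genotype and expression vectors differ in length")
    mask = ~np.isnan(g) & ~np.isnan(y)
    g, y = g[mask], y[mask]
    if g.size < 3:
        raise ValueError(f"pair ({probe_id}, {snp_id}): fewer than 3 complete samples")
    if np.unique(g).size < 2:
        raise ValueError(f"pair ({probe_id}, {snp_id}): constant genotype after deletion")
    beta, r2, p = _assoc_complete(g, y)
    return AssocRecord(probe_id, snp_id, int(g.size), beta, r2, p)


def permute_probe(
    expression,
    cis_genotypes: pd.DataFrame,
    n_perm: int = 10_000,
    alpha: float = 0.001,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    probe_id: str = "",
) -> ProbeThreshold:
    """Permutation min-P threshold for one probe.

    Each permutation label-swaps the expression vector once, tests it
    against every cis SNP of the probe (pairwise deletion per SNP, as in
    the unpermuted analysis), and records the minimum nominal P across
    SNPs. The threshold is the ``alpha`` lower-tail order statistic of
    those minima. Deterministic given ``seed`` (or an explicit ``rng``).
    """
    if cis_genotypes.shape[1] == 0:
        raise ValueError(f"probe {probe_id!r} has no cis SNPs")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    y = np.asarray(expression, dtype=float)
    n = y.size
    perm_idx = rng.permuted(
        np.broadcast_to(np.arange(n), (n_perm, n)).copy(), axis=1
    )
    Y = y[perm_idx]  # n_perm x n, one shared label swap per iteration

    minima = np.ones(n_perm)
    for snp_id in cis_genotypes.columns:
        g = cis_genotypes[snp_id].to_numpy(dtype=float)
        mask = ~np.isnan(g)
        gs = g[mask]
        if gs.size < 3 or np.unique(gs).size < 2:
            continue  # undefined pair: skipped here as in the observed fit
        Ys = Y[:, mask]
        p = _bulk_p(gs, Ys)
        np.minimum(minima, p, out=minima)

    k = _order_statistic_index(alpha, n_perm)
    p_threshold = float(np.partition(minima, k - 1)[k - 1])
    return ProbeThreshold(probe_id, n_perm, alpha, p_threshold, minima)


def _bulk_p(g: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Two-sided OLS slope p-values of each row of Y against g (complete data)."""
    n = g.size
    gd = g - g.mean()
    sxx = float(gd @ gd)
    Yd = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", Yd, Yd)
    sxy = Yd @ gd
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (sxy * sxy) / (sxx * syy)
    r2 = np.where(syy == 0.0, 0.0, r2)
    r2 = np.clip(r2, 0.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t2 = df * r2 / (1.0 - r2)
    p = _t_sf_two_sided(np.where(np.isfinite(t2), t2, np.inf), df)
    return np.where(r2 >= 1.0, _P_FLOOR, p)


def probe_rng(seed: int, probe_id: str) -> np.random.Generator:
    """Deterministic per-probe random stream derived from (seed, probe id).

    Serial and parallel traversals of the probe list therefore produce
    identical permutation thresholds.
    """
    digest = hashlib.blake2b(probe_id.encode(), digest_size=8).digest()
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, int.from_bytes(digest, "big")])


def call_eqtls(
    assocs: pd.DataFrame,
    thresholds: dict[str, ProbeThreshold],
    gene_symbols: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Flag significant pairs against their probe's permutation threshold.

    Significance is the strict inequality ``p_nominal < p_threshold`` (a
    pair exactly at the threshold is not called). The summary counts
    significant pairs, distinct significant probes and — when
    ``gene_symbols`` maps probe ids to symbols — distinct genes.
    """
    missing = set(assocs["probe_id"]) - set(thresholds)
    if missing:
        raise KeyError(f"no permutation threshold for probes {sorted(missing)[:5]}")
    out = assocs.copy()
    out["p_threshold"] = out["probe_id"].map(lambda p: thresholds[p].p_threshold)
    out["significant"] = out["p_nominal"] < out["p_threshold"]
    sig = out[out["significant"]]
    summary = {
        "n_pairs_tested": int(len(out)),
        "n_significant_pairs": int(len(sig)),
        "n_significant_probes": int(sig["probe_id"].nunique()),
    }
    if gene_symbols is not None:
        summary["n_significant_genes"] = int(
            sig["probe_id"].map(gene_symbols).nunique()
        )
    return out, summary


def map_cis_eqtls(
    genotypes,
    expression,
    window: int = DEFAULT_WINDOW,
    n_perm: int = 10_000,
    alpha: float = 0.001,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full cis scan: pairing, OLS per pair, per-probe permutation calling.

    ``genotypes`` is a :class:`~neutroqtl.panels.GenotypePanel`;
    ``expression`` a :class:`~neutroqtl.panels.ExpressionPanel` whose
    values are analyzed as-is (normalize and log2 first; a warning is
    logged for a raw panel). Probes with no cis SNP yield no pairs and no
    threshold. Returns the eQTL table (one row per tested pair) and a
    summary dict.
    """
    if getattr(expression, "state", None) == "raw":
        logger.warning("expression panel is in raw state; expected quantile_log2")

    pairs = cis_pairs(genotypes.snps, expression.probes, window=window)
    records: list[dict] = []
    thresholds: dict[str, ProbeThreshold] = {}
    n_skipped = 0

    for pid, sub in pairs.groupby("probe_id", sort=True):
        y = expression.values[pid].to_numpy(dtype=float)
        G = genotypes.genotypes[list(sub["snp_id"])]
        probe_records = []
        for snp_id, dist in zip(sub["snp_id"], sub["distance"]):
            try:
                rec = linreg_assoc(G[snp_id], y, probe_id=pid, snp_id=snp_id)
            except ValueError as exc:
                logger.info("skipping undefined pair: %s", exc)
                n_skipped += 1
                continue
            probe_records.append(
                {
                    "probe_id": pid,
                    "snp_id": snp_id,
                    "chrom": genotypes.snps.at[snp_id, "chrom"],
                    "pos": int(genotypes.snps.at[snp_id, "pos"]),
                    "distance": int(dist),
                    "n_used": rec.n_used,
                    "beta": rec.beta,
                    "r2": rec.r2,
                    "p_nominal": rec.p_nominal,
                }
            )
        if not probe_records:
            continue
        thresholds[pid] = permute_probe(
            y,
            G,
            n_perm=n_perm,
            alpha=alpha,
            rng=probe_rng(seed, pid),
            probe_id=pid,
        )
        records.extend(probe_records)

    assocs = pd.DataFrame(
        records,
        columns=[
            "probe_id", "snp_id", "chrom", "pos", "distance",
            "n_used", "beta", "r2", "p_nominal",
        ],
    )
    if assocs.empty:
        return assocs.assign(p_threshold=[], significant=[]), {
            "n_pairs_tested": 0,
            "n_significant_pairs": 0,
            "n_significant_probes": 0,
            "n_pairs_skipped": n_skipped,
        }
    gene_symbols = (
        expression.probes["gene_symbol"]
        if "gene_symbol" in expression.probes.columns
        else None
    )
    table, summary = call_eqtls(assocs, thresholds, gene_symbols=gene_symbols)
    summary["n_pairs_skipped"] = n_skipped
    summary["n_probes_tested"] = int(table["probe_id"].nunique())
    return table, summary
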