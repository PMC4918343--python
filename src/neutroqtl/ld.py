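"""Linkage disequilibrium, cross-dataset eQTL sharing and enrichment.

LD is measured as genotypic (composite) r^2: the squared Pearson
correlation of allele-count vectors over pairwise-complete samples, the
standard unphased proxy for haplotype r^2. On top of it sit one-hop
tagSNP expansion, the Venn partition of eQTL probes across external
datasets, hypergeometric overlap enrichment (log-space, so astronomically
small P-values survive), a GWAS-catalog intersection and a homolog-table
gene-symbol join.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LdMatrix",
    "OverlapReport",
    "ld_r2",
    "expand_by_ld",
    "share_across_datasets",
    "hypergeom_enrichment",
    "hypergeom_log10",
    "gwas_intersect",
    "map_homologs",
    "HomologMapping",
    "percent",
]

logger = logging.getLogger(__name__)


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage of ``count`` in ``total``, round-half-even to ``ndigits``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def ld_r2(g1, g2) -> float:
    """Genotypic r^2 between two allele-count vectors.

    Pairwise-complete samples only; needs >= 3 of them. A vector constant
    on the complete set makes r^2 undefined — returned as NaN, which
    compares below any threshold. Invariant under allele-label flips
    (g -> 2 - g) on either argument.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 pairwise-complete samples")
    a, b = a[mask], b[mask]
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LdMatrix:
    """Symmetric matrix of pairwise genotypic r^2 for a SNP set."""

    r2: pd.DataFrame  # square, index == columns == snp ids

    def __post_init__(self) -> None:
        if not self.r2.index.equals(self.r2.columns):
            raise ValueError("LD matrix must have identical row and column ids")

    @classmethod
    def from_genotypes(cls, genotypes: pd.DataFrame, snp_ids=None) -> "LdMatrix":
        """Pairwise-complete r^2 from a samples x SNPs allele-count frame.

        Accepts a :class:`~neutroqtl.panels.GenotypePanel` or its matrix.
        Constant SNPs give NaN rows/columns (below any threshold).
        """
        mat = getattr(genotypes, "genotypes", genotypes)
        if snp_ids is not None:
            mat = mat[list(snp_ids)]
        corr = mat.corr(method="pearson", min_periods=3)
        r2 = corr * corr
        np.fill_diagonal(r2.to_numpy(), 1.0)
        return cls(r2)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.r2.index)

    def value(self, a: str, b: str) -> float:
        return float(self.r2.at[a, b])

    def proxies(self, snp_id: str, threshold: float, inclusive: bool = False) -> set[str]:
        """SNPs linked to ``snp_id`` at r^2 > threshold (>= when inclusive)."""
        if snp_id not in self.r2.index:
            raise KeyError(f"SNP {snp_id!r} absent from LD matrix")
        row = self.r2.loc[snp_id].drop(snp_id)
        hit = row >= threshold if inclusive else row > threshold
        return set(row.index[hit.fillna(False)])

    def linked(self, a: str, b: str, threshold: float, inclusive: bool = True) -> bool:
        """Identity or LD link between two SNPs (missing r^2 never links)."""
        if a == b:
            return True
        if a not in self.r2.index or b not in self.r2.index:
            return False
        v = self.r2.at[a, b]
        if pd.isna(v):
            return False
        return v >= threshold if inclusive else v > threshold


def expand_by_ld(
    seed_snps: Iterable[str],
    ld: LdMatrix,
    threshold: float = 0.8,
    inclusive: bool = False,
) -> set[str]:
    """Seed SNPs plus every SNP in LD (r^2 > threshold) with >= 1 seed.

    Single hop only — proxies of proxies are not pulled in — matching
    tagSNP usage. The default comparison is strict (linked SNPs must
    *exceed* the threshold); pass ``inclusive=True`` for >=.
    """
    seeds = set(seed_snps)
    out = set(seeds)
    for snp in seeds:
        out |= ld.proxies(snp, threshold, inclusive=inclusive)
    return out


@dataclass
class OverlapReport:
    """Venn partition of eQTL probes across two external datasets.

    ``counts`` holds the four disjoint classes (``all_three``,
    ``with_monocytes_only``, ``with_bcells_only``, ``unique``); they must
    sum to ``total``. Percentages are round-half-even to 2 decimals.
    """

    counts: dict[str, int]
    total: int
    enrichment: dict[str, dict] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError(
                f"partition counts {self.counts} do not sum to total {self.total}"
            )

    @property
    def percentages(self) -> dict[str, float]:
        return {k: percent(v, self.total) for k, v in self.counts.items()}

    def shared_count(self, dataset: str) -> int:
        """Probes validated in one dataset = all_three + that dataset's exclusive class."""
        return self.counts["all_three"] + self.counts[f"with_{dataset}_only"]

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "total": self.total,
            "percentages": self.percentages,
            "enrichment": self.enrichment,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _dataset_index(records: pd.DataFrame, key: str) -> dict[str, set[str]]:
    return {
        k: set(sub["snp_id"]) for k, sub in records.groupby(records[key].astype(str))
    }


def share_across_datasets(
    our_eqtls: pd.DataFrame,
    monocytes: pd.DataFrame,
    bcells: pd.DataFrame,
    ld: LdMatrix,
    threshold: float = 0.8,
    inclusive: bool = True,
    match_on: str = "gene_symbol",
    universe: int | None = None,
) -> OverlapReport:
    """Partition our eQTL probes by sharing with two external eQTL lists.

    A probe is shared with a dataset when the dataset has an eQTL for the
    same matching key (gene symbol by default, or ``probe_id``) whose SNP
    is identical to — or in LD at ``r^2 >= threshold`` with — one of the
    probe's significant SNPs. Identifier schemes must be pre-harmonized.

    When ``universe`` is given, a hypergeometric enrichment P is attached
    for each dataset (overlap k = probes shared, K = our total probes,
    n = dataset's distinct matching keys, N = universe).
    """
    for frame, name in ((our_eqtls, "our_eqtls"), (monocytes, "monocytes"), (bcells, "bcells")):
        needed = {match_on, "snp_id"} if frame is not our_eqtls else {"probe_id", match_on, "snp_id"}
        if not needed <= set(frame.columns):
            raise ValueError(f"{name} must have columns {sorted(needed)}")

    mono_idx = _dataset_index(monocytes, match_on)
    bcell_idx = _dataset_index(bcells, match_on)

    def shared_with(idx: Mapping[str, set[str]], key: str, snps: set[str]) -> bool:
        ext = idx.get(key)
        if not ext:
            return False
        for ours in snps:
            for theirs in ext:
                if ld.linked(ours, theirs, threshold, inclusive=inclusive):
                    return True
        return False

    classes: dict[str, list[str]] = {
        "all_three": [], "with_monocytes_only": [], "with_bcells_only": [], "unique": [],
    }
    probes = our_eqtls.groupby("probe_id", sort=True)
    for probe_id, sub in probes:
        key = str(sub[match_on].iloc[0])
        snps = set(sub["snp_id"])
        in_mono = shared_with(mono_idx, key, snps)
        in_b = shared_with(bcell_idx, key, snps)
        if in_mono and in_b:
            classes["all_three"].append(probe_id)
        elif in_mono:
            classes["with_monocytes_only"].append(probe_id)
        elif in_b:
            classes["with_bcells_only"].append(probe_id)
        else:
            classes["unique"].append(probe_id)

    total = sum(len(v) for v in classes.values())
    report = OverlapReport(
        counts={k: len(v) for k, v in classes.items()},
        total=total,
        members=classes,
    )
    if universe is not None:
        for name, idx in (("monocytes", mono_idx), ("bcells", bcell_idx)):
            k = report.shared_count(name)
            n_ext = len(idx)
            report.enrichment[name] = {
                "overlap": k,
                "set_a": total,
                "set_b": n_ext,
                "universe": universe,
                "p": hypergeom_enrichment(k, total, n_ext, universe),
                "log10_p": hypergeom_log10(k, total, n_ext, universe),
            }
    return report


def _check_hypergeom_args(overlap: int, set_a: int, set_b: int, universe: int) -> None:
    if not (0 <= overlap <= min(set_a, set_b) <= universe):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, sets=({set_a}, {set_b}), "
            f"universe={universe}"
        )
    if max(set_a, set_b) > universe:
        raise ValueError("set sizes cannot exceed the universe")


def hypergeom_enrichment(overlap: int, set_a: int, set_b: int, universe: int) -> float:
    """Upper-tail P(X >= overlap), X ~ Hypergeometric(universe, set_a, set_b).

    The probability that two sets of the given sizes, drawn without
    replacement from a common universe, share at least ``overlap``
    members. Evaluated in log space; ``overlap=0`` gives exactly 1.
    """
    _check_hypergeom_args(overlap, set_a, set_b, universe)
    if overlap == 0:
        return 1.0
    return float(np.exp(stats.hypergeom.logsf(overlap - 1, universe, set_a, set_b)))


def hypergeom_log10(overlap: int, set_a: int, set_b: int, universe: int) -> float:
    """log10 of the upper-tail enrichment P (usable far below float underflow)."""
    _check_hypergeom_args(overlap, set_a, set_b, universe)
    if overlap == 0:
        return 0.0
    return float(stats.hypergeom.logsf(overlap - 1, universe, set_a, set_b) / np.log(10.0))


def gwas_intersect(
    expanded_snps: Iterable[str],
    catalog: pd.DataFrame,
    universe: int | None = None,
) -> pd.DataFrame:
    """Intersect an LD-expanded eQTL SNP set with a GWAS-style catalog.

    ``catalog`` needs columns ``snp_id`` and ``trait`` (extra columns are
    ignored; malformed rows are skipped with a warning). For every trait
    with at least one catalog SNP in the expanded set, the overlap and its
    hypergeometric enrichment against the catalog universe (distinct
    catalog SNPs by default) are reported, sorted by enrichment P.
    """
    expanded = set(expanded_snps)
    if not {"snp_id", "trait"} <= set(catalog.columns):
        raise ValueError("catalog must have columns snp_id and trait")
    clean = catalog.dropna(subset=["snp_id", "trait"])
    n_bad = len(catalog) - len(clean)
    if n_bad:
        logger.warning("skipped %d malformed catalog rows", n_bad)

    catalog_snps = set(clean["snp_id"].astype(str))
    n_universe = universe if universe is not None else len(catalog_snps)
    eqtl_in_catalog = expanded & catalog_snps

    rows = []
    for trait, sub in clean.groupby(clean["trait"].astype(str)):
        trait_snps = set(sub["snp_id"].astype(str))
        hits = sorted(trait_snps & expanded)
        if not hits:
            continue
        p = hypergeom_enrichment(
            len(hits), len(eqtl_in_catalog), len(trait_snps), n_universe
        )
        rows.append(
            {
                "trait": trait,
                "n_trait_snps": len(trait_snps),
                "n_overlap": len(hits),
                "overlap_snps": ",".join(hits),
                "p_enrichment": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["trait", "n_trait_snps", "n_overlap", "overlap_snps", "p_enrichment"]
    )
    return out.sort_values(["p_enrichment", "trait"], ignore_index=True) if len(out) else out


class HomologMapping(NamedTuple):
    mapped: dict[str, str]
    unmapped: list[str]


def map_homologs(gene_symbols: Iterable[str], homolog_table: pd.DataFrame) -> HomologMapping:
    """Join gene symbols through a two-column homolog table.

    The first table column is the source symbol, the second the target.
    Conflicting duplicate mappings raise an error naming the symbol;
    symbols absent from the table are listed as unmapped.
    """
    if homolog_table.shape[1] < 2:
        raise ValueError("homolog table needs two columns (source, target)")
    src_col, tgt_col = homolog_table.columns[:2]
    table = homolog_table[[src_col, tgt_col]].drop_duplicates()
    dup = table[src_col][table[src_col].duplicated()]
    if len(dup):
        raise ValueError(f"conflicting homolog mappings for {sorted(set(dup))[:5]}")
    lookup = dict(zip(table[src_col], table[tgt_col]))
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for sym in gene_symbols:
        if sym in lookup:
            mapped[sym] = lookup[sym]
        else:
            unmapped.append(sym)
    return HomologMapping(mapped, sorted(unmapped))
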