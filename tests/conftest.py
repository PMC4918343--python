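import numpy as np
import pandas as pd
import pytest

from neutroqtl import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A cohort small enough for fast tests but with realistic structure."""
    return SimulationConfig(
        n_samples=120,
        n_snps=60,
        n_probes=12,
        ld_block_size=10,
        ld_decay=0.9,
        missing_rate=0.02,
        effect_table=[
            ("probe0002", "snp00010", 0.5),
            ("probe0005", "snp00030", 0.6),
            ("probe0008", "snp00050", 0.4),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def genotype_vectors():
    rng = np.random.default_rng(5)
    g = rng.binomial(2, 0.3, size=50).astype(float)
    y = rng.standard_normal(50)
    return g, y


def make_genotype_panel(matrix, chroms=None, positions=None, sample_prefix="S"):
    """Hand-build a GenotypePanel from a samples x SNPs array."""
    from neutroqtl import GenotypePanel

    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    snp_ids = [f"s{i}" for i in range(m)]
    ann = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else 1000 * (np.arange(m) + 1),
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    frame = pd.DataFrame(matrix, index=[f"{sample_prefix}{i}" for i in range(n)], columns=snp_ids)
    return GenotypePanel(frame, ann)


def make_expression_panel(matrix, chroms=None, has_common_snp=None, state="raw"):
    """Hand-build an ExpressionPanel from a samples x probes array."""
    from neutroqtl import ExpressionPanel

    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    probe_ids = [f"p{i}" for i in range(p)]
    ann = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["1"] * p,
            "midpoint": 10_000 * (np.arange(p) + 1),
            "gene_symbol": [f"G{i}" for i in range(p)],
            "has_common_snp": has_common_snp if has_common_snp is not None else [False] * p,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    frame = pd.DataFrame(matrix, index=[f"S{i}" for i in range(n)], columns=probe_ids)
    return ExpressionPanel(frame, ann, state=state)
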