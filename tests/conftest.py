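import numpy as np
import pandas as pd
import pytest

from polycomorb import synthetic_cohort as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic study reused by read-only tests."""
    cfg = sc.SimConfig(
        n_samples=500,
        n_snps=120,
        n_blocks=30,
        within_block_r=0.7,
        maf_range=(0.05, 0.5),
        n_discovery=100_000,
        prop_causal=0.5,
        gamma=0.2,
        missing_rate=0.01,
        seed=99,
    )
    return sc.simulate_cohort(cfg)


@pytest.fixture
def toy_sumstats():
    return pd.DataFrame(
        {
            "id": ["v1", "v2", "v3"],
            "chrom": [1, 1, 2],
            "pos": [1000, 2000, 1000],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "beta": [0.5, -0.2, 0.1],
            "pvalue": [0.001, 0.04, 0.6],
        }
    )
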