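import numpy as np
import pandas as pd
import pytest

from tftri.config import SimConfig
from tftri import simulate as sim


SMALL = dict(
    n_genes=80,
    genome_size=800_000,
    lib_size_mean=300_000.0,
    noise_peaks_per_sample=5,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_bundle(small_cfg) -> sim.SimBundle:
    return sim.simulate_all(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture()
def tiny_annotation() -> pd.DataFrame:
    """Four genes on two contigs, both strands."""
    rows = [
        ("gA", "chr1", 10_000, 12_000, "+", 10_000),
        ("gB", "chr1", 50_000, 52_000, "-", 51_999),
        ("gC", "chr2", 10_000, 12_000, "+", 10_000),
        ("gD", "chr2", 80_000, 82_000, "-", 81_999),
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])
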