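import numpy as np
import pandas as pd
import pytest

from cobind3d import contacts
from cobind3d.intervals import PeakSet
from cobind3d.synth import SimulationConfig, simulate_contact_reads


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_genes():
    """Six genes on two chromosomes with mixed strands."""
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(6)],
            "chrom": ["chr1"] * 4 + ["chr2"] * 2,
            "strand": ["+", "-", "+", "+", "-", "+"],
            "tss": [10_000, 52_000, 120_000, 300_000, 40_000, 90_000],
            "tx_start": [10_000, 45_000, 120_000, 300_000, 33_000, 90_000],
            "tx_end": [18_000, 52_000, 126_000, 309_000, 40_000, 97_000],
        }
    )


def random_peakset(rng, name, n, chrom="chr1", span=1_000_000, width=200):
    starts = rng.integers(0, span - width, size=n)
    return PeakSet(
        name,
        pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width}),
    )


@pytest.fixture
def make_peaks():
    return random_peakset


@pytest.fixture(scope="session")
def clean_sim():
    """Depth-1e6 contact simulation with no planted structure, plus its
    binned matrix and fitted background (shared across test modules)."""
    config = SimulationConfig(
        seed=101, chrom_length=10_000_000, bin_size=25_000, depth=1_000_000
    )
    pairs, _ = simulate_contact_reads(config)
    mats, summary = contacts.bin_pairs(pairs["cond1"], config.bin_size, config.chrom_sizes)
    matrix = mats["chr1"]
    return {
        "config": config,
        "pairs": pairs,
        "matrix": matrix,
        "background": contacts.fit_background(matrix),
        "summary": summary,
    }
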