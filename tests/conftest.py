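import numpy as np
import pandas as pd
import pytest

from pgxeqtl.containers import GenotypeMatrix
from pgxeqtl.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One deterministic small study with all four planted effect classes."""
    cfg = SimulationConfig(
        n_snps=24, n_genes=60, ld_block_size=3, maf_range=(0.35, 0.5),
        nb_mean_range=(64, 512), seed=42,
    )
    return simulate_study(
        cfg, auto_effects={"DHT": 2, "ENZ": 2, "BOTH_NONREVERSIBLE": 1, "AR_INDEPENDENT": 1}
    )


@pytest.fixture
def toy_genotypes():
    """Six cells x four SNPs with one missing call, hand-built."""
    dosage = pd.DataFrame(
        np.array(
            [
                [0, 1, 2, 0],
                [1, 1, 2, 0],
                [2, 0, 2, 1],
                [0, np.nan, 2, 1],
                [1, 1, 2, 2],
                [2, 0, 2, 2],
            ],
            dtype=float,
        ),
        index=[f"c{i}" for i in range(6)],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [100, 200, 300, 100],
            "ref": "A",
            "alt": "G",
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return GenotypeMatrix(dosage=dosage, snp_meta=meta)
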