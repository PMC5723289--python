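import numpy as np
import pandas as pd
import pytest

import binmap as bm
from binmap.core import MISSING, GenotypeMatrix


def make_matrix(codes, chrom="1", bin_size=100_000, lines=None):
    """Build a GenotypeMatrix from a 2-D int array of codes on one or more chromosomes.

    ``codes`` may be a dict chrom -> array for multi-chromosome matrices.
    Bins tile each chromosome from 0 in ``bin_size`` steps.
    """
    if not isinstance(codes, dict):
        codes = {chrom: np.asarray(codes)}
    blocks, markers = [], []
    n_lines = next(iter(codes.values())).shape[0]
    for c, arr in codes.items():
        arr = np.asarray(arr, dtype=np.int8)
        blocks.append(arr)
        for j in range(arr.shape[1]):
            s, e = j * bin_size, (j + 1) * bin_size
            markers.append(
                {
                    "name": f"RSM_{c}_{(s + e) / 2e6:.2f}",
                    "chrom": c,
                    "start_bp": s,
                    "end_bp": e,
                    "midpoint_mb": (s + e) / 2e6,
                    "n_snps": 2,
                }
            )
    lines = lines or [f"RIL_{i + 1:03d}" for i in range(n_lines)]
    frame = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(lines, name="line"), columns=[m["name"] for m in markers]
    ).astype(np.int8)
    return GenotypeMatrix(frame, pd.DataFrame(markers))


@pytest.fixture(scope="session")
def small_genome():
    """Two small chromosomes without centromere SNP thinning."""
    return bm.SimGenome(
        (
            bm.SimChromosome("1", 5_000_000, 20.0, 2_500_000, 0),
            bm.SimChromosome("2", 3_000_000, 12.0, 1_500_000, 0),
        )
    )


@pytest.fixture(scope="session")
def noiseless_population(small_genome):
    """Truth + noiseless dense SNP calls for oracle-equivalence tests."""
    config = bm.SimConfig(
        n_lines=60, error_prob=0.0, dropout_prob=0.0, snps_per_100kbp=25.0, seed=11
    )
    truth = bm.simulate_ril_genotypes(small_genome, config)
    calls, sites = bm.simulate_snp_calls(truth, small_genome, config)
    return truth, calls, sites, config


@pytest.fixture(scope="session")
def default_genome():
    return bm.default_genome()
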