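import numpy as np
import pandas as pd
import pytest

from recmap.io_formats import MISSING, GenotypeDataset, PedigreeTable
from recmap.synthetic import SimConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One simulated study under the default conditions, shared read-only."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture
def trio_pedigree():
    records = pd.DataFrame(
        [
            ("SIRE", "", "", "M", 2009),
            ("DAM", "", "", "F", 2009),
            ("PUP1", "SIRE", "DAM", "M", 2011),
            ("PUP2", "SIRE", "DAM", "F", 2011),
        ],
        columns=["dog_id", "sire_id", "dam_id", "sex", "birth_year"],
    )
    return PedigreeTable(records)


def make_dataset(calls, phenotypes, chrom="1", start=100, spacing=100):
    """Small GenotypeDataset from an explicit call matrix."""
    calls = np.asarray(calls, dtype=np.int16)
    n_samples, n_snps = calls.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"S{j}" for j in range(n_snps)],
            "chrom": chrom,
            "pos": [start + j * spacing for j in range(n_snps)],
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"I{i}" for i in range(n_samples)]
    return GenotypeDataset(samples, list(phenotypes), snps, calls)
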