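import numpy as np
import pytest

from pyrotraits.simulate import SimConfig, generate_lab_dataset


@pytest.fixture(scope="session")
def lab_seed1():
    """Default-condition lab dataset, seed 1 (shared; treat as read-only)."""
    return generate_lab_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def lab_tables_seed1(lab_seed1):
    return {
        "dna_t24h": lab_seed1.dna_t24h,
        "rna_t24h": lab_seed1.rna_t24h,
        "dna_t5wk": lab_seed1.dna_t5wk,
        "dna_t6mo": lab_seed1.dna_t6mo,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
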