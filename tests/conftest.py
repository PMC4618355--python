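import numpy as np
import pandas as pd
import pytest

from xenoflux.seqprops import codon_frequencies
from xenoflux.synthetic_data import gen_strain_table


@pytest.fixture(scope="session")
def ala_skewed_table():
    """Usage table with Ala codons GCG x2, GCA x1 plus single-codon families."""
    return codon_frequencies("ATG" + "GCG" * 2 + "GCA" + "TGG")


@pytest.fixture(scope="session")
def clean_strain_table():
    """Noiseless, barrier-free table generated from a=0.6, b=1.0."""
    table, truth = gen_strain_table(n_barrier=0, noise_sd=0.0, seed=7, a=0.6, b=1.0)
    return table, truth


@pytest.fixture(scope="session")
def barrier_strain_table():
    """Default study-like conditions: 35 strains, 6 with an abundance barrier."""
    table, truth = gen_strain_table(seed=11)
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def two_point_table():
    """Three exact landscape points with closed-form solution a=0.6, b=1.0."""
    return pd.DataFrame(
        {
            "strain_id": ["s0", "s1", "s3"],
            "kcat_over_km": [1.0, 1.0, 1.0],
            "abundance_total_naive": [0.0, 1.0, 3.0],
            "growth_rate_naive": [0.0, 0.3, 0.45],
        }
    )
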