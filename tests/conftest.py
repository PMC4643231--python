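import numpy as np
import pytest

import paleo16s as p
from paleo16s.datasets import load_primer_pairs


@pytest.fixture(scope="session")
def v3_pair():
    return load_primer_pairs()["U341F/534R"]


@pytest.fixture(scope="session")
def v4_pair():
    return load_primer_pairs()["515F/806R"]


@pytest.fixture(scope="session")
def three_clade_db(v3_pair):
    """Canonical three-clade synthetic database (planted x = 151/169/194)."""
    spec = p.three_clade_spec(divergence=0.02, n_otus=3)
    return spec, p.generate_reference_db(spec, v3_pair)


@pytest.fixture(scope="session")
def uniform_profile():
    return p.normalize_profile(
        {"Methanobrevibacter": 1.0, "Anaerolineae G-1": 1.0, "Streptococcus": 1.0}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20151116)
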