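import numpy as np
import pytest

from mdcontact import integrin_domain_map, make_lattice_protein


@pytest.fixture(scope="session")
def integrin_map():
    return integrin_domain_map()


@pytest.fixture()
def small_protein():
    """10-residue lattice protein with two 5-residue domains."""
    return make_lattice_protein(
        10, spacing_A=8.0, domain_splits={"D1": [[1, 5]], "D2": [[6, 10]]}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
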