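import numpy as np
import pytest

import radcon as rc
from radcon.codon_core import CodonFrequencyTable


@pytest.fixture(scope="session")
def my_scheme():
    return rc.builtin_scheme("MY")


@pytest.fixture(scope="session")
def charge_scheme():
    return rc.builtin_scheme("charge")


@pytest.fixture(scope="session")
def polarity_scheme():
    return rc.builtin_scheme("polarity")


@pytest.fixture(scope="session")
def all_schemes(my_scheme, charge_scheme, polarity_scheme):
    return (charge_scheme, polarity_scheme, my_scheme)


@pytest.fixture(scope="session")
def uniform_table():
    return CodonFrequencyTable.from_array(np.full(61, 1.0 / 61.0))


@pytest.fixture(scope="session")
def gc51_table():
    from radcon.synthetic_data import make_frequency_table

    return make_frequency_table(0.51)
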