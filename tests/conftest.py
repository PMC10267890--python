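import pandas as pd
import pytest

from migscreen import synthdata as sd
from migscreen.refdata import load_migrant_list


@pytest.fixture(scope="session")
def migrants() -> pd.DataFrame:
    """The bundled recycled-HDPE migrant reference list (83 compounds with
    printed measured precursor m/z, adduct and formula)."""
    return load_migrant_list()


@pytest.fixture(scope="session")
def synth_library():
    return sd.make_library(8, seed=11)


@pytest.fixture()
def batch_roles():
    return sd.default_roles(n_samples=6, n_blanks=3, n_qc=3)
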