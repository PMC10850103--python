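import numpy as np
import pytest

from splicescope.spectra import MockSpectrumPredictor
from splicescope.splice_space import Substrate


@pytest.fixture(scope="session")
def predictor():
    return MockSpectrumPredictor()


@pytest.fixture()
def toy_substrate():
    # all-distinct residues (I omitted so nothing collides with L under
    # the I/L equivalence): peptides map uniquely, which keeps expected
    # locations unambiguous in the mapping tests
    return Substrate("toy", "ACDEFGHKLMNPQRSTVWY")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
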