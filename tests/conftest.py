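import numpy as np
import pytest

from spermnet import build_speract_model
from spermnet.fixtures import make_cycle_network, make_identity_network, make_ternary_toggle


@pytest.fixture(scope="session")
def speract_model():
    return build_speract_model()


@pytest.fixture(scope="session")
def toy_fixtures():
    return [
        make_identity_network(3),
        make_cycle_network(2),
        make_cycle_network(3),
        make_cycle_network(5),
        make_ternary_toggle(),
    ]
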