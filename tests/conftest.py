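import numpy as np
import pytest

from stereoddi.chemio import build_graph, generate_conformer
from stereoddi.synthbench import SynthSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def benzene_graph():
    return build_graph("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def ethanol_conformer():
    return generate_conformer("CCO", seed=7, drug_id="ethanol")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small rule-labelled dataset shared by trainer-level tests."""
    spec = SynthSpec(n_drugs=16, stereo_fraction=0.25, label_noise=0.0, seed=5)
    return make_dataset(spec)
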