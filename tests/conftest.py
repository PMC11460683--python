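import json

import pytest

from exopath.network import standardize
from exopath.synth import make_toy_community, make_toy_network


@pytest.fixture(scope="session")
def toy_net():
    return make_toy_network()


@pytest.fixture(scope="session")
def toy_std(toy_net):
    return standardize(toy_net)


@pytest.fixture(scope="session")
def toy_community():
    return make_toy_community(seed=0)


@pytest.fixture()
def minimal_json_model(tmp_path):
    """Hand-written two-metabolite chain model in the JSON CBM dialect."""
    doc = {
        "metabolites": [
            {"id": "A", "compartment": "e"},
            {"id": "B", "compartment": "e"},
        ],
        "reactions": [
            {"id": "b1", "metabolites": {"A": 1}, "lower_bound": 0, "upper_bound": 10},
            {"id": "r1", "metabolites": {"A": -1, "B": 1}, "lower_bound": 0, "upper_bound": 10},
            {"id": "b2", "metabolites": {"B": -1}, "lower_bound": 0, "upper_bound": 10},
        ],
        "biomass": "b2",
    }
    path = tmp_path / "chain.json"
    path.write_text(json.dumps(doc))
    return path
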