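import numpy as np
import pandas as pd
import pytest

from alsim.circuit_model import NeuronRoster, build_weight_matrix
from alsim.fixtures import (
    FIXTURE_SEED,
    fixture_door_matrix,
    fixture_protocol,
    fixture_spec,
    _assign_polarities,
)
from alsim.synthetic import generate_connectome


@pytest.fixture(scope="session")
def fixture_parts():
    """Roster, counts, and volumes of the reference synthetic circuit."""
    roster, counts, volumes = generate_connectome(fixture_spec(), seed=FIXTURE_SEED)
    roster, counts = _assign_polarities(roster, counts, FIXTURE_SEED)
    return roster, counts, volumes


@pytest.fixture(scope="session")
def fixture_weights(fixture_parts):
    roster, counts, _ = fixture_parts
    return build_weight_matrix(roster, counts)


@pytest.fixture(scope="session")
def door():
    return fixture_door_matrix(FIXTURE_SEED)


@pytest.fixture(scope="session")
def protocol():
    return fixture_protocol()


def toy_roster(records):
    """Roster from (id, cell_class, glomerulus, polarity) tuples."""
    return NeuronRoster(
        pd.DataFrame(records, columns=["id", "cell_class", "glomerulus", "polarity"])
    )


@pytest.fixture()
def three_neuron_circuit():
    """One ORN -> one uPN plus one iLN -> the same uPN."""
    roster = toy_roster(
        [
            ("orn1", "ORN", "DA1", 1.0),
            ("pn1", "uPN", "DA1", 1.0),
            ("ln1", "LN", None, -1.0),
        ]
    )
    counts = np.zeros((3, 3))
    counts[0, 1] = 10.0  # ORN -> PN
    counts[2, 1] = 5.0   # iLN -> PN
    return roster, counts
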